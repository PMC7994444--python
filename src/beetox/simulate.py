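"""Synthetic acute-oral bioassay generator.

Emulates the statistical structure the analysis pipeline assumes: a probit
tolerance model in which each bee carries a single latent tolerance
quantile ``u``.  At assessment time ``t`` a bee at dose ``d`` is dead from
treatment iff

    u < Phi( slope * (log10 d - log10 LD50(t)) )

with LD50(t) non-increasing in time, so a bee's death status never reverts
and the cumulative mortality at each time follows the cross-sectional
probit law exactly — the generator is the generating law the probit module
estimates.  Mixture arms divide LD50(t) by a true synergism ratio
``sr_true``; control, solvent and fungicide-only arms have no treatment
effect.  Background mortality strikes independently in each inter-
assessment interval with a small per-interval probability, before the
treatment check (ties resolve to death either way, since both produce an
event).  Deaths are recorded at the first assessment time at which the bee
is found dead; survivors are right-censored at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from beetox.io import (
    BeeRecord,
    SPECIES_REGISTRY,
    SpeciesProfile,
    StudyDesign,
    default_design,
)


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterisation of a synthetic bioassay.

    ``time_shape`` holds the multipliers g(t) >= 1, aligned with the
    design's assessment times, with g(horizon) = 1 and g non-increasing;
    the true LD50 at time t is ``ld50_96 * g(t)``.
    """

    design: StudyDesign
    species: SpeciesProfile
    ld50_96: float
    slope: float
    time_shape: tuple
    sr_true: float = 1.0
    control_hazard: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(float(g) for g in self.time_shape)
        object.__setattr__(self, "time_shape", shape)
        if self.ld50_96 <= 0:
            raise ValueError("ld50_96 must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if len(shape) != len(self.design.assessment_times):
            raise ValueError(
                "time_shape must align with the design's assessment times"
            )
        if any(g < 1 for g in shape) or abs(shape[-1] - 1.0) > 1e-12:
            raise ValueError("time_shape must be >= 1 with g(horizon) = 1")
        if any(g2 > g1 for g1, g2 in zip(shape, shape[1:])):
            raise ValueError("time_shape must be non-increasing")
        if self.sr_true <= 0:
            raise ValueError("sr_true must be positive")
        if not 0 <= self.control_hazard <= 0.05:
            raise ValueError("control_hazard must lie in [0, 0.05]")

    def ld50_at(self, time: float) -> float:
        """True insecticide-alone LD50 (ng/bee) at an assessment time."""
        times = self.design.assessment_times
        for t, g in zip(times, self.time_shape):
            if abs(t - time) < 1e-9:
                return self.ld50_96 * g
        raise ValueError(f"time {time} not on the assessment grid")


def _treatment_probs(scenario: SimulationScenario, dose: float, mixture: bool):
    """Cumulative treatment-death probability at each assessment time."""
    times = scenario.design.assessment_times
    if dose <= 0:
        return np.zeros(len(times))
    ld = np.array([scenario.ld50_at(t) for t in times])
    if mixture:
        ld = ld / scenario.sr_true
    return stats.norm.cdf(scenario.slope * (np.log10(dose) - np.log10(ld)))


def _simulate_group(
    scenario: SimulationScenario,
    arm: str,
    sul_dose: float,
    flu_dose: float,
    rng: np.random.Generator,
) -> list:
    design = scenario.design
    times = np.asarray(design.assessment_times)
    n = design.n_per_group
    k = len(times)
    p = _treatment_probs(scenario, sul_dose, mixture=(arm == "SUL_FLU"))
    u = rng.uniform(size=n)
    background = rng.uniform(size=(n, k)) < scenario.control_hazard
    # cumulative treatment death status at each time; monotone in time
    treated = u[:, None] < p[None, :]
    dead = background | treated
    any_death = dead.any(axis=1)
    first = np.where(any_death, dead.argmax(axis=1), k - 1)
    records = []
    for i in range(n):
        if any_death[i]:
            last_time, event = float(times[first[i]]), 1
        else:
            last_time, event = float(times[-1]), 0
        records.append(
            BeeRecord(
                bee_id=f"{scenario.species.label}_{arm}_{sul_dose:g}_{i}",
                species=scenario.species.label,
                arm=arm,
                sul_dose=sul_dose,
                flu_dose=flu_dose,
                last_time=last_time,
                event=event,
            )
        )
    return records


def simulate_bioassay(scenario: SimulationScenario) -> list:
    """Generate one full bioassay dataset; deterministic given the seed.

    Arms: CONTROL, SOLVENT, FLU (fungicide only), one SUL arm per dose
    and one SUL_FLU arm per dose, each of size ``design.n_per_group``.
    """
    rng = np.random.default_rng(scenario.seed)
    design = scenario.design
    records = []
    records += _simulate_group(scenario, "CONTROL", 0.0, 0.0, rng)
    records += _simulate_group(scenario, "SOLVENT", 0.0, 0.0, rng)
    records += _simulate_group(scenario, "FLU", 0.0, design.flu_codose, rng)
    for dose in design.sul_doses:
        records += _simulate_group(scenario, "SUL", dose, 0.0, rng)
    for dose in design.sul_doses:
        records += _simulate_group(
            scenario, "SUL_FLU", dose, design.flu_codose, rng
        )
    return records


# per-species defaults: LD50 at the 96 h horizon, its time decay (ratios of
# the earlier-time LD50s to the final one), probit slope, and a fixed seed
_REFERENCE_PARAMS = {
    # most sensitive species; strong early-time decay of the LD50
    "osmia": dict(
        ld50_96=5.9,
        time_shape=(13.76, 2.29, 1.54, 1.22, 1.0),
        slope=2.5,
        seed=1003,
    ),
    # least sensitive per bee; mortality plateaus after 24 h
    "bumblebee": dict(
        ld50_96=83.5,
        time_shape=(2.07, 1.0, 1.0, 1.0, 1.0),
        slope=4.0,
        seed=1002,
    ),
    # intermediate sensitivity with a shallow slope, so late-time fits
    # can lose significance at moderate group sizes
    "honeybee": dict(
        ld50_96=30.0,
        time_shape=(4.85, 1.85, 1.3, 1.1, 1.0),
        slope=1.0,
        seed=1001,
    ),
}


def reference_scenario(species_label: str, **overrides) -> SimulationScenario:
    """Packaged per-species default scenario (osmia/bumblebee/honeybee).

    Keyword overrides replace any scenario field, e.g.
    ``reference_scenario("osmia", sr_true=1.4, seed=7)``.
    """
    if species_label not in _REFERENCE_PARAMS:
        raise ValueError(
            f"unknown species {species_label!r}; "
            f"expected one of {sorted(_REFERENCE_PARAMS)}"
        )
    params = dict(_REFERENCE_PARAMS[species_label])
    n_per_group = overrides.pop("n_per_group", None)
    design = overrides.pop("design", default_design())
    if n_per_group is not None:
        design = default_design(n_per_group=n_per_group)
    species = overrides.pop("species", SPECIES_REGISTRY[species_label])
    params.update(overrides)
    return SimulationScenario(design=design, species=species, **params)
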