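"""Synergism summaries downstream of LD50s: SR, toxic units and MDR.

Three complementary summaries of insecticide-fungicide interaction:

* the **synergism ratio** SR = LD50(insecticide alone) / LD50(in mixture),
  with a normal-theory ratio-test confidence interval on the log10 scale;
  SR > 1 with the CI excluding 1 indicates synergism;
* **toxic units** under the concentration-addition reference model:
  TU_FLU is the fixed fungicide co-dose divided by the fungicide's own
  LD50, TU_SUL the mixture LD50 divided by the insecticide-alone LD50, and
  TU_total their sum;
* the **model deviation ratio** MDR = 1 / TU_total, classified as
  synergism (> 1.25), antagonism (< 0.83) or additivity (between).

Also provided: the interspecies sensitivity ratio (ratio of the lowest
per-gram LD50s of two species) and a nectar exposure-dose calculator
(mg a.i./kg nectar x mg nectar consumed = ng ingested).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from beetox.probit import LD50Estimate, ProbitFit, ld50

#: Acute oral LD50 of fluxapyroxad in the honey bee (ug/bee), the anchor
#: for the fungicide toxic unit (no species-specific value exists).
DEFAULT_FLU_LD50_UG = 110.9

#: Fungicide co-exposure dose (ug/bee) used throughout the mixture arms.
DEFAULT_FLU_DOSE_UG = 1.2

#: MDR classification thresholds; boundary values count as additivity.
MDR_SYNERGISM_THRESHOLD = 1.25
MDR_ANTAGONISM_THRESHOLD = 0.83


@dataclass(frozen=True)
class SynergismRatio:
    """LD50 ratio (alone / mixture) with its ratio-test 95% CI."""

    sr: float
    ci_low: float
    ci_high: float
    significant: bool  # synergism: sr > 1 and ci_low > 1
    antagonistic: bool  # sr < 1 and ci_high < 1


@dataclass(frozen=True)
class ToxicUnits:
    """Toxic units of the mixture components under concentration addition."""

    tu_sul: float
    tu_flu: float

    @property
    def tu_total(self) -> float:
        return self.tu_sul + self.tu_flu


@dataclass(frozen=True)
class MDRResult:
    """Model deviation ratio and its interaction classification."""

    mdr: float
    classification: str  # "synergism" | "additivity" | "antagonism"


@dataclass(frozen=True)
class ExposureDose:
    """Ingested dose from contaminated nectar, with optional lethality flag."""

    dose_ng: float
    lethal: bool | None = None


def toxic_unit_fixed(dose: float, ld50_ref: float) -> float:
    """TU of a component dosed at a fixed level: dose / reference LD50.

    Both arguments must be positive and share units.
    """
    if dose <= 0 or ld50_ref <= 0:
        raise ValueError("dose and reference LD50 must be positive")
    return dose / ld50_ref


def toxic_units_mixture(
    ld50_alone: float, ld50_mix: float, tu_flu: float
) -> ToxicUnits:
    """Toxic units of the binary mixture at its LD50.

    ``tu_sul = ld50_mix / ld50_alone``: the insecticide's contribution is
    the fraction of its solo LD50 present in the mixture at the mixture's
    LD50 (a mixture needing *less* insecticide than the solo LD50 yields
    TU_SUL < 1).
    """
    if ld50_alone <= 0 or ld50_mix <= 0:
        raise ValueError("LD50s must be positive")
    if tu_flu < 0:
        raise ValueError("tu_flu must be >= 0")
    return ToxicUnits(tu_sul=ld50_mix / ld50_alone, tu_flu=tu_flu)


def mdr(tu: ToxicUnits) -> MDRResult:
    """Model deviation ratio 1/TU_total with threshold classification."""
    if tu.tu_total <= 0:
        raise ValueError("total toxic units must be positive")
    value = 1.0 / tu.tu_total
    if value > MDR_SYNERGISM_THRESHOLD:
        cls = "synergism"
    elif value < MDR_ANTAGONISM_THRESHOLD:
        cls = "antagonism"
    else:
        cls = "additivity"
    return MDRResult(mdr=value, classification=cls)


def synergism_ratio_point(ld50_alone: float, ld50_mix: float) -> float:
    """Point synergism ratio LD50_alone / LD50_mixture."""
    if ld50_alone <= 0 or ld50_mix <= 0:
        raise ValueError("LD50s must be positive")
    return ld50_alone / ld50_mix


def synergism_ratio_test(
    fit_alone: ProbitFit,
    fit_mix: ProbitFit,
    alpha_level: float = 0.05,
) -> SynergismRatio | None:
    """Ratio test comparing the solo and mixture LD50s.

    The CI is normal-theory on the log10 scale:
    ``log10 SR +/- z * sqrt(se_alone^2 + se_mix^2)``.  Each
    ``se(log10 LD50)`` is taken as the half-width of the fit's Fieller
    interval divided by its critical value, which reflects the
    heterogeneity-inflated covariance and retains Fieller's finite-sample
    widening; the plain delta-method SE is the fallback.  Returns ``None``
    when either LD50 is non-determinable.
    """
    est_a = ld50(fit_alone, alpha_level)
    est_m = ld50(fit_mix, alpha_level)
    if not (est_a.determinable and est_m.determinable):
        return None
    sr = est_a.ld50_ng_per_bee / est_m.ld50_ng_per_bee

    def _se(est, fit):
        if est.ci_low is not None and est.ci_high is not None:
            half = (np.log10(est.ci_high) - np.log10(est.ci_low)) / 2
            return half / fit.critical_value(alpha_level)
        return est.se_log10

    se = float(np.hypot(_se(est_a, fit_alone), _se(est_m, fit_mix)))
    z = float(stats.norm.ppf(1 - alpha_level / 2))
    log_sr = np.log10(sr)
    lo, hi = 10 ** (log_sr - z * se), 10 ** (log_sr + z * se)
    return SynergismRatio(
        sr=float(sr),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(sr > 1 and lo > 1),
        antagonistic=bool(sr < 1 and hi < 1),
    )


def interspecies_sensitivity_ratio(
    ld50_frame: pd.DataFrame,
    species_a: str,
    species_b: str,
    treatment: str = "SUL",
    scale: str = "per_gram",
) -> float:
    """Ratio of the lowest LD50s (over assessment times) of two species.

    ``scale`` selects per-gram (``ld50_ng_per_g``) or per-bee
    (``ld50_ng_per_bee``) values; only determinable entries enter the
    minima.  A value of r means the treatment is r times more toxic to
    species_b than to species_a.
    """
    col = {"per_gram": "ld50_ng_per_g", "per_bee": "ld50_ng_per_bee"}[scale]
    minima = {}
    for sp in (species_a, species_b):
        sub = ld50_frame[
            (ld50_frame["species"] == sp)
            & (ld50_frame["treatment"] == treatment)
            & (ld50_frame["determinable"])
        ][col].dropna()
        if sub.empty:
            raise ValueError(
                f"no determinable {treatment} LD50 for species {sp!r}"
            )
        minima[sp] = float(sub.min())
    return minima[species_a] / minima[species_b]


def nectar_exposure_dose(
    conc_mg_per_kg: float,
    consumption_mg: float = 80.0,
    ld50_ng: float | None = None,
) -> ExposureDose:
    """Ingested dose (ng) from nectar at a residue concentration.

    ``mg a.i. per kg nectar x mg nectar = ng a.i.`` — the default
    consumption is 80 mg of nectar (one hour of foraging on 15%-sugar
    nectar).  When an LD50 (ng/bee) is supplied, the dose is flagged
    lethal iff it reaches that LD50.
    """
    if conc_mg_per_kg < 0 or consumption_mg < 0:
        raise ValueError("concentration and consumption must be >= 0")
    dose_ng = conc_mg_per_kg * consumption_mg
    lethal = None if ld50_ng is None else bool(dose_ng >= ld50_ng)
    return ExposureDose(dose_ng=float(dose_ng), lethal=lethal)
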