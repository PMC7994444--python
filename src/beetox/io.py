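"""Data model and CSV I/O for acute-oral bee bioassays.

One row per bee, in long right-censored form: the bee's treatment arm, its
sulfoxaflor dose (ng/bee), its fluxapyroxad co-dose (ug/bee), the last time
it was observed (hours since the end of the exposure phase) and whether it
was found dead at that time (``event = 1``) or was still alive at the end of
the observation horizon (``event = 0``, right-censored).

Mortality is assessed on a fixed grid of times (3 h after exposure, then
every 24 h up to 96 h), so observation times always lie on that grid; the
exact moment of death within an interval is not observed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Valid treatment-arm labels: untreated control, solvent (acetone) control,
#: fungicide-only, insecticide-only, and the binary mixture.
ARMS = ("CONTROL", "SOLVENT", "FLU", "SUL", "SUL_FLU")

#: Default mortality-assessment grid, hours after the end of exposure.
DEFAULT_ASSESSMENT_TIMES = (3.0, 24.0, 48.0, 72.0, 96.0)

#: Column order of the bioassay CSV format.
CSV_COLUMNS = (
    "bee_id",
    "species",
    "arm",
    "sul_dose_ng",
    "flu_dose_ug",
    "last_time_h",
    "event",
)


class BioassayValidationError(ValueError):
    """A bioassay record or file violates the data-model invariants."""


class SchemaError(BioassayValidationError):
    """The CSV header does not match the expected bioassay schema."""


@dataclass(frozen=True)
class BeeRecord:
    """One bee's arm assignment, doses and right-censored survival outcome.

    Parameters
    ----------
    bee_id : str
        Opaque identifier, unique within a dataset.
    species : str
        Species label; canonical values are ``honeybee``, ``bumblebee``
        and ``osmia`` but any label is accepted.
    arm : str
        Treatment arm, one of :data:`ARMS`.
    sul_dose : float
        Insecticide dose in ng per bee (0 for arms without it).
    flu_dose : float
        Fungicide dose in ug per bee (0 or the single co-exposure dose).
    last_time : float
        Hours since end of exposure at the last observation.
    event : int
        1 if the bee was found dead at ``last_time``, 0 if right-censored.
    """

    bee_id: str
    species: str
    arm: str
    sul_dose: float
    flu_dose: float
    last_time: float
    event: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise BioassayValidationError(
                f"unknown arm {self.arm!r}; expected one of {ARMS}"
            )
        if self.event not in (0, 1):
            raise BioassayValidationError(
                f"event must be 0 or 1, got {self.event!r}"
            )
        if self.sul_dose < 0 or self.flu_dose < 0:
            raise BioassayValidationError("doses must be non-negative")
        if self.last_time <= 0:
            raise BioassayValidationError("last_time must be positive")
        if self.arm == "SUL" and self.flu_dose != 0:
            raise BioassayValidationError(
                f"arm SUL requires flu_dose = 0, got {self.flu_dose}"
            )
        if self.arm == "SUL" and self.sul_dose <= 0:
            raise BioassayValidationError("arm SUL requires sul_dose > 0")
        if self.arm == "FLU" and self.sul_dose != 0:
            raise BioassayValidationError(
                f"arm FLU requires sul_dose = 0, got {self.sul_dose}"
            )
        if self.arm == "FLU" and self.flu_dose <= 0:
            raise BioassayValidationError("arm FLU requires flu_dose > 0")
        if self.arm == "SUL_FLU" and (self.sul_dose <= 0 or self.flu_dose <= 0):
            raise BioassayValidationError(
                "arm SUL_FLU requires both doses > 0"
            )
        if self.arm in ("CONTROL", "SOLVENT") and (
            self.sul_dose != 0 or self.flu_dose != 0
        ):
            raise BioassayValidationError(
                f"arm {self.arm} requires zero doses"
            )


@dataclass(frozen=True)
class SpeciesProfile:
    """Species-level body-weight summary used for per-gram dose scaling."""

    label: str
    mean_body_weight: float  # g
    sd_body_weight: float = 0.0  # g

    def __post_init__(self) -> None:
        if not 0 < self.mean_body_weight < 2:
            raise BioassayValidationError(
                "mean body weight must lie in (0, 2) g for a bee"
            )
        if self.sd_body_weight < 0:
            raise BioassayValidationError("sd body weight must be >= 0")


#: Mean fresh body weights (g) of the three study species; individual test
#: bees are not weighed, so a single species mean is applied throughout.
SPECIES_REGISTRY: Mapping[str, SpeciesProfile] = {
    "honeybee": SpeciesProfile("honeybee", 0.081, 0.015),
    "bumblebee": SpeciesProfile("bumblebee", 0.263, 0.049),
    "osmia": SpeciesProfile("osmia", 0.092, 0.008),
}


@dataclass(frozen=True)
class StudyDesign:
    """Assessment grid, dose series and group size of an acute-oral assay."""

    assessment_times: tuple = DEFAULT_ASSESSMENT_TIMES
    sul_doses: tuple = ()
    flu_codose: float = 1.2  # ug/bee
    n_per_group: int = 30

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.assessment_times)
        doses = tuple(float(d) for d in self.sul_doses)
        object.__setattr__(self, "assessment_times", times)
        object.__setattr__(self, "sul_doses", doses)
        if len(times) < 1 or any(
            t2 <= t1 for t1, t2 in zip(times, times[1:])
        ):
            raise BioassayValidationError(
                "assessment_times must be strictly increasing"
            )
        if any(t <= 0 for t in times):
            raise BioassayValidationError("assessment times must be positive")
        if any(d <= 0 for d in doses) or any(
            d2 <= d1 for d1, d2 in zip(doses, doses[1:])
        ):
            raise BioassayValidationError(
                "sul_doses must be positive and strictly increasing"
            )
        if self.flu_codose < 0:
            raise BioassayValidationError("flu_codose must be >= 0")
        if self.n_per_group < 1:
            raise BioassayValidationError("n_per_group must be >= 1")

    @property
    def horizon(self) -> float:
        """Observation horizon: the last assessment time (h)."""
        return self.assessment_times[-1]


def geometric_dose_series(lowest: float, factor: float, n: int) -> tuple:
    """Dose series ``lowest * factor**k`` for ``k = 0 .. n-1``.

    The default study design uses a factor-2 series from 2.75 ng/bee
    (seven members up to 176 ng/bee).
    """
    if lowest <= 0:
        raise ValueError("lowest dose must be positive")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return tuple(lowest * factor**k for k in range(n))


def default_design(n_per_group: int = 30) -> StudyDesign:
    """The canonical design: 5 assessment times, factor-2 doses 2.75-176."""
    return StudyDesign(
        assessment_times=DEFAULT_ASSESSMENT_TIMES,
        sul_doses=geometric_dose_series(2.75, 2.0, 7),
        flu_codose=1.2,
        n_per_group=n_per_group,
    )


def _check_grid(time: float, grid: Sequence[float]) -> None:
    if not any(abs(time - t) < 1e-9 for t in grid):
        raise BioassayValidationError(
            f"time {time} not on the assessment grid {tuple(grid)}"
        )


def read_bioassay_csv(path, design: StudyDesign) -> list:
    """Read and validate a bioassay CSV into a list of :class:`BeeRecord`.

    Every row is validated against the record invariants and the design's
    assessment grid; all offending rows are reported together with their
    1-based file line numbers.
    """
    frame = pd.read_csv(path, dtype={"bee_id": str, "species": str, "arm": str})
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    records = []
    problems = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header on line 1
        try:
            rec = BeeRecord(
                bee_id=str(row["bee_id"]),
                species=str(row["species"]),
                arm=str(row["arm"]),
                sul_dose=float(row["sul_dose_ng"]),
                flu_dose=float(row["flu_dose_ug"]),
                last_time=float(row["last_time_h"]),
                event=int(row["event"]),
            )
            _check_grid(rec.last_time, design.assessment_times)
        except (BioassayValidationError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
            continue
        records.append(rec)
    if problems:
        raise BioassayValidationError(
            "invalid bioassay rows:\n" + "\n".join(problems)
        )
    return records


def write_bioassay_csv(records: Iterable[BeeRecord], path) -> None:
    """Write records to the bioassay CSV format (UTF-8, '.' decimal)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.bee_id,
                    r.species,
                    r.arm,
                    repr(r.sul_dose),
                    repr(r.flu_dose),
                    repr(r.last_time),
                    r.event,
                ]
            )


def records_to_frame(records: Iterable[BeeRecord]) -> pd.DataFrame:
    """Long-form DataFrame view of a record collection."""
    return pd.DataFrame(
        [
            {
                "bee_id": r.bee_id,
                "species": r.species,
                "arm": r.arm,
                "sul_dose_ng": r.sul_dose,
                "flu_dose_ug": r.flu_dose,
                "last_time_h": r.last_time,
                "event": r.event,
            }
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )


def aggregate_mortality(
    records: Sequence[BeeRecord],
    time: float,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Cumulative mortality per (species, arm, dose) group at a grid time.

    A bee counts as dead by ``time`` iff ``event == 1`` and
    ``last_time <= time``; this is the input builder for the cross-sectional
    probit fits.

    Returns a DataFrame with columns ``species, arm, sul_dose_ng,
    n_exposed, n_dead``.
    """
    if design is not None:
        _check_grid(time, design.assessment_times)
    elif time <= 0:
        raise BioassayValidationError("time must be positive")
    frame = records_to_frame(records)
    frame["dead"] = ((frame["event"] == 1) & (frame["last_time_h"] <= time)).astype(int)
    out = (
        frame.groupby(["species", "arm", "sul_dose_ng"], as_index=False)
        .agg(n_exposed=("bee_id", "size"), n_dead=("dead", "sum"))
        .sort_values(["species", "arm", "sul_dose_ng"], ignore_index=True)
    )
    return out
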