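"""End-to-end analysis orchestration and report assembly.

`run_analysis` drives the full pipeline on a validated dataset: per-species
Kaplan-Meier curves, the omnibus log-rank across all arms, Holm-corrected
pairwise comparisons, the per-dose Bliss independence tests, the
per-time probit LD50 table, and the downstream SR / toxic-unit / MDR
summaries.  Non-determinable LD50 cells propagate as explicit missing
values (rendered "-" in CSV), never as zeros.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from beetox.bliss import bliss_test
from beetox.io import SPECIES_REGISTRY, StudyDesign, records_to_frame
from beetox.probit import ld50_frame, ld50_table
from beetox.survival import omnibus_logrank, pairwise_logrank_holm
from beetox.synergy import (
    DEFAULT_FLU_LD50_UG,
    mdr,
    synergism_ratio_test,
    toxic_unit_fixed,
    toxic_units_mixture,
)

_MISSING = "-"


@dataclass
class AnalysisReport:
    """All pipeline outputs for one dataset, ready for serialization."""

    ld50_entries: list
    sr_rows: list
    mdr_rows: list
    bliss_rows: list
    omnibus: dict
    pairwise: dict  # species -> DataFrame of Holm-adjusted p-values
    provenance: dict

    def ld50_frame(self) -> pd.DataFrame:
        frame = ld50_frame(self.ld50_entries)
        sr = pd.DataFrame(self.sr_rows)
        if not sr.empty:
            frame = frame.merge(
                sr, on=["species", "time_h"], how="left"
            )
        return frame

    def mdr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mdr_rows)

    def bliss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bliss_rows)

    def validate_consistency(self, tol: float = 1e-9) -> None:
        """Check every emitted MDR equals 1/(TU_SUL + TU_FLU)."""
        for row in self.mdr_rows:
            if row["mdr"] is None:
                continue
            recomputed = 1.0 / (row["tu_sul"] + row["tu_flu"])
            if abs(recomputed - row["mdr"]) > tol:
                raise AssertionError(
                    f"inconsistent MDR row: {row} (expected {recomputed})"
                )

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "omnibus": self.omnibus,
            "ld50_table": _frame_records(self.ld50_frame()),
            "mdr_table": self.mdr_rows,
            "bliss": self.bliss_rows,
            "pairwise": {
                sp: mat.to_dict() for sp, mat in self.pairwise.items()
            },
        }


def _frame_records(frame: pd.DataFrame) -> list:
    return json.loads(frame.to_json(orient="records"))


def run_analysis(
    records: Sequence,
    design: StudyDesign,
    species_profiles: Mapping | None = None,
    rho: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
    flu_ld50_ug: float = DEFAULT_FLU_LD50_UG,
    bliss_calibration: str = "asymptotic",
    bliss_n_boot: int = 200,
) -> AnalysisReport:
    """Run the full synergism analysis on a validated dataset."""
    profiles = species_profiles if species_profiles is not None else SPECIES_REGISTRY
    frame = records_to_frame(records)
    species_list = sorted(frame["species"].unique())

    omnibus = {}
    pairwise = {}
    bliss_rows = []
    for species in species_list:
        recs = [r for r in records if r.species == species]
        groups = {}
        for (arm, dose), _sub in frame[frame["species"] == species].groupby(
            ["arm", "sul_dose_ng"]
        ):
            label = arm if dose == 0 else f"{arm}_{dose:g}"
            groups[label] = [
                r for r in recs if r.arm == arm and r.sul_dose == dose
            ]
        if len(groups) >= 2:
            res = omnibus_logrank(groups)
            omnibus[species] = {
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
            pairwise[species] = pairwise_logrank_holm(groups, rho=0.0)

        flu_arm = [r for r in recs if r.arm == "FLU"]
        for dose in design.sul_doses:
            mix = [r for r in recs if r.arm == "SUL_FLU" and r.sul_dose == dose]
            sul = [r for r in recs if r.arm == "SUL" and r.sul_dose == dose]
            if not (mix and sul and flu_arm):
                continue
            comp = bliss_test(
                mix,
                sul,
                flu_arm,
                rho=rho,
                seed=seed,
                calibration=bliss_calibration,
                n_boot=bliss_n_boot,
            )
            bliss_rows.append(
                {
                    "species": species,
                    "sul_dose_ng": dose,
                    "statistic": comp.test.statistic,
                    "p_value": comp.test.p_value,
                    "synergism": bool(comp.test.p_value < alpha),
                    "calibration": comp.calibration,
                    "seed": seed,
                }
            )

    entries = ld50_table(records, design, species_profiles=profiles)
    by_key = {(e.species, e.treatment, e.time): e for e in entries}

    sr_rows = []
    mdr_rows = []
    tu_flu = toxic_unit_fixed(design.flu_codose, flu_ld50_ug)
    for species in species_list:
        for time in design.assessment_times:
            alone = by_key.get((species, "SUL", time))
            mixed = by_key.get((species, "SUL_FLU", time))
            if alone is None or mixed is None:
                continue
            sr = None
            if alone.fit is not None and mixed.fit is not None:
                sr = synergism_ratio_test(alone.fit, mixed.fit, alpha)
            sr_rows.append(
                {
                    "species": species,
                    "time_h": time,
                    "sr": None if sr is None else sr.sr,
                    "sr_ci_low": None if sr is None else sr.ci_low,
                    "sr_ci_high": None if sr is None else sr.ci_high,
                    "sr_significant": None if sr is None else sr.significant,
                }
            )
            if alone.estimate.determinable and mixed.estimate.determinable:
                tu = toxic_units_mixture(
                    alone.estimate.ld50_ng_per_bee,
                    mixed.estimate.ld50_ng_per_bee,
                    tu_flu,
                )
                res = mdr(tu)
                mdr_rows.append(
                    {
                        "species": species,
                        "time_h": time,
                        "tu_sul": tu.tu_sul,
                        "tu_flu": tu.tu_flu,
                        "tu_total": tu.tu_total,
                        "mdr": res.mdr,
                        "classification": res.classification,
                    }
                )
            else:
                mdr_rows.append(
                    {
                        "species": species,
                        "time_h": time,
                        "tu_sul": None,
                        "tu_flu": tu_flu,
                        "tu_total": None,
                        "mdr": None,
                        "classification": _MISSING,
                    }
                )

    from beetox import __version__

    provenance = {
        "seed": seed,
        "rho": rho,
        "alpha": alpha,
        "flu_ld50_ug": flu_ld50_ug,
        "n_records": len(records),
        "data_hash": hashlib.sha256(
            frame.to_csv(index=False).encode()
        ).hexdigest()[:16],
        "version": __version__,
    }
    report = AnalysisReport(
        ld50_entries=entries,
        sr_rows=sr_rows,
        mdr_rows=mdr_rows,
        bliss_rows=bliss_rows,
        omnibus=omnibus,
        pairwise=pairwise,
        provenance=provenance,
    )
    report.validate_consistency()
    return report


def render_summary(report_dict: dict) -> str:
    """Species-by-species narrative summary of a report dictionary."""
    lines = ["Mixture-toxicity analysis summary", "=" * 33]
    prov = report_dict.get("provenance", {})
    lines.append(
        f"version {prov.get('version', '?')} | seed {prov.get('seed', '?')} "
        f"| data hash {prov.get('data_hash', '?')}"
    )
    for species, omni in report_dict.get("omnibus", {}).items():
        lines.append("")
        lines.append(f"Species: {species}")
        lines.append(
            f"  omnibus log-rank: chi2 = {omni['statistic']:.2f}, "
            f"df = {omni['df']}, p = {omni['p_value']:.3g}"
        )
        for row in report_dict.get("bliss", []):
            if row["species"] != species:
                continue
            flag = " SYNERGISM" if row["synergism"] else ""
            lines.append(
                f"  Bliss at {row['sul_dose_ng']:g} ng/bee: "
                f"p = {row['p_value']:.3f}{flag}"
            )
        for row in report_dict.get("mdr_table", []):
            if row["species"] != species:
                continue
            if row["mdr"] is None:
                lines.append(f"  MDR at {row['time_h']:g} h: {_MISSING}")
            else:
                lines.append(
                    f"  MDR at {row['time_h']:g} h: {row['mdr']:.2f} "
                    f"({row['classification']})"
                )
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, outdir) -> None:
    """Write CSV tables, the JSON report and a text summary to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.ld50_frame().to_csv(
        outdir / "ld50_table.csv", index=False, na_rep=_MISSING
    )
    report.mdr_frame().to_csv(
        outdir / "mdr_table.csv", index=False, na_rep=_MISSING
    )
    report.bliss_frame().to_csv(outdir / "bliss.csv", index=False)
    for species, mat in report.pairwise.items():
        mat.to_csv(outdir / f"pairwise_{species}.csv")
    payload = report.to_dict()
    (outdir / "report.json").write_text(json.dumps(payload, indent=2))
    (outdir / "summary.txt").write_text(render_summary(payload))
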