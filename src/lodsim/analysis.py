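"""Cohort-record aggregation, the youngest-cohort rule and summary tables.

The youngest usable cohort for a disease is the first mid-cohort age at
which the cohort's cumulative incidence reaches 0.25% of the population —
below that no adequately powered case/control study can be formed.  Summary
tables report, for the largest-effect tracked allele, the case/control MAF
difference and the cases needed for 80% GWAS power at the youngest cohort,
age 80 and age 100, plus the youngest-to-80 case-number multiple.
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import CohortRecord, SimulationConfig, YearRecord
from .epidemiology import IncidenceModel, cumulative_incidence
from .power import cases_for_power

__all__ = [
    "youngest_cohort_age",
    "cohort_frame",
    "iva_frame",
    "aggregate_cohort_runs",
    "delta_maf_at",
    "summary_table",
    "RunManifest",
]

MIN_COHORT_CUMULATIVE = 0.0025


def youngest_cohort_age(
    source: Sequence[CohortRecord] | IncidenceModel,
    span: int = 10,
    max_age: int = 100,
) -> int | None:
    """Smallest mid-cohort age whose cumulative incidence reaches 0.25%.

    ``source`` is either a list of cohort records (their recorded cumulative
    incidence is used) or an incidence model (deterministic survival-product
    evaluation, averaging the cohort's ``span`` ages).  Returns None when the
    threshold is never reached.
    """
    if isinstance(source, IncidenceModel):
        for start in range(0, max_age - span + 2):
            ages = np.arange(start, start + span)
            cum = np.mean([cumulative_incidence(source, a) for a in ages])
            if cum >= MIN_COHORT_CUMULATIVE:
                return start + span // 2
        return None
    for rec in source:
        if rec.cumulative_incidence >= MIN_COHORT_CUMULATIVE:
            return rec.mid_cohort_age
    return None


def iva_frame(records: Sequence[YearRecord]) -> pd.DataFrame:
    """One row per year of age; per-variant MAF columns are suffixed."""
    rows = []
    for r in records:
        row = {
            "age": r.age,
            "n_new_cases": r.n_new_cases,
            "n_unaffected": r.n_unaffected,
            "case_prs_mean": r.case_prs_mean,
            "case_prs_sd": r.case_prs_sd,
            "unaffected_prs_mean": r.unaffected_prs_mean,
            "unaffected_prs_sd": r.unaffected_prs_sd,
            "cumulative_incidence": r.cumulative_incidence,
        }
        if r.maf_cases is not None:
            for v, f in r.maf_cases.items():
                row[f"maf_cases_{v}"] = f
            for v, f in r.maf_unaffected.items():
                row[f"maf_unaffected_{v}"] = f
            for v, d in r.delta_maf.items():
                row[f"delta_maf_{v}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """One row per mid-cohort age; per-variant MAF columns are suffixed."""
    rows = []
    for r in records:
        row = {
            "mid_cohort_age": r.mid_cohort_age,
            "n_cases": r.n_cases,
            "n_controls": r.n_controls,
            "case_prs_mean": r.case_prs_mean,
            "case_prs_sd": r.case_prs_sd,
            "control_prs_mean": r.control_prs_mean,
            "control_prs_sd": r.control_prs_sd,
            "cumulative_incidence": r.cumulative_incidence,
            "reportable": r.reportable,
        }
        if r.maf_cases is not None and r.maf_controls is not None:
            for v, f in r.maf_cases.items():
                row[f"maf_cases_{v}"] = f
            for v, f in r.maf_controls.items():
                row[f"maf_controls_{v}"] = f
            for v, d in r.delta_maf.items():
                row[f"delta_maf_{v}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_cohort_runs(runs: Sequence[Sequence[CohortRecord]]) -> pd.DataFrame:
    """Average replicate cohort runs by mid-cohort age.

    Numeric columns are replicate means; each ``delta_maf_*`` column gains a
    ``*_se`` companion, the Monte-Carlo standard error SD/sqrt(replicates).
    """
    frames = [cohort_frame(r) for r in runs]
    stacked = pd.concat(frames, keys=range(len(frames)), names=["replicate"])
    numeric = stacked.drop(columns=["reportable"]).groupby("mid_cohort_age")
    mean = numeric.mean().reset_index()
    k = len(frames)
    if k > 1:
        for col in [c for c in mean.columns if c.startswith("delta_maf_")]:
            sd = numeric[col].std(ddof=1)
            mean[f"{col}_se"] = (sd / np.sqrt(k)).values
    reportable = stacked.groupby("mid_cohort_age")["reportable"].all()
    mean["reportable"] = reportable.values
    return mean


def delta_maf_at(frame: pd.DataFrame, variant: str, mid_age: int) -> float | None:
    """Replicate-averaged case-minus-control MAF at one mid-cohort age."""
    col = f"delta_maf_{variant}"
    sel = frame.loc[frame["mid_cohort_age"] == mid_age, col]
    if sel.empty or pd.isna(sel.iloc[0]):
        return None
    return float(sel.iloc[0])


def summary_table(
    runs_by_preset: Mapping[str, Sequence[Sequence[CohortRecord]]],
    variant: str = "s1_m5_o1",
    ages: tuple[int, int] = (80, 100),
) -> pd.DataFrame:
    """Cross-disease cohort summary for one tracked allele.

    For each disease: δMAF at the youngest cohort and at the requested ages,
    the cases needed for 80% power at the same ages, and the youngest-to-80
    case multiple.  δMAF is rounded to 3 decimals, multiples to 2.  Missing
    ages (pools below threshold, or cumulative incidence never reaching
    0.25%) are left as NA.
    """
    rows = []
    for name, runs in runs_by_preset.items():
        frame = aggregate_cohort_runs(runs)
        records0 = runs[0]
        youngest = youngest_cohort_age(records0)
        row: dict = {"disease": name, "youngest_cohort_age": youngest}
        deltas: dict[str, float | None] = {}
        points = [("youngest", youngest)] + [(str(a), a) for a in ages]
        for label, age in points:
            d = delta_maf_at(frame, variant, age) if age is not None else None
            deltas[label] = d
            row[f"delta_maf_{label}"] = round(d, 3) if d is not None else None
            row[f"cases_80pc_{label}"] = (
                round(cases_for_power(d)) if d else None
            )
        d_y, d_80 = deltas["youngest"], deltas[str(ages[0])]
        row["multiple_youngest_to_80"] = (
            round(cases_for_power(d_80) / cases_for_power(d_y), 2)
            if d_y and d_80
            else None
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility sidecar written next to each batch of CSV outputs."""

    config: dict
    seeds: list[int]
    outputs: list[str]
    software_version: str
    wall_time_s: float

    @classmethod
    def from_config(
        cls, config: SimulationConfig, outputs: Sequence[str | Path], t0: float
    ) -> "RunManifest":
        from . import __version__

        cfg = {
            "preset": config.preset_name,
            "scenario": config.architecture.scenario.name,
            "target_h2": config.architecture.target_h2,
            "n_sets": config.architecture.n_sets,
            "n_population": config.n_population,
            "mode": config.mode,
            "cohort_span": config.cohort_span,
            "max_age": config.max_age,
            "or_to_hr_mode": config.or_to_hr_mode,
            "mortality_case_multiplier": config.mortality.case_multiplier,
            "mortality_form": config.mortality.form,
            "seed": config.seed,
            "replicates": config.replicates,
        }
        return cls(
            config=cfg,
            seeds=[config.seed],
            outputs=[str(p) for p in outputs],
            software_version=__version__,
            wall_time_s=round(time.monotonic() - t0, 2),
        )

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
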