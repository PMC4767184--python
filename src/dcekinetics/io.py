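"""File formats, run configuration and the end-to-end pipeline.

The on-disk interchange format is a long-form CSV of per-ROI signal
intensities with the mandatory header

    subject_id,dose_mmol_per_kg,scan_slot,replicate,roi_index,signal

where ``scan_slot`` 0 denotes the pre-contrast repetitions
(distinguished by replicate letters ``a``, ``b``, ...) and slots
1..n_post the post-contrast scans (replicate ``-``); ``roi_index`` runs
1..3.  Comma-separated, UTF-8, ``.`` decimal.

:func:`run_pipeline` ties simulation (or CSV ingestion) to TIC
construction, classification, parameter extraction and the group
comparison, and writes a machine-parseable JSON report whose structure
is described by the packaged ``report_schema.json`` and checked by
:func:`validate_report`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .schedule import ScanSchedule
from .simulate import CohortSpec, NoiseModel, simulate_cohort, cohort_manifest
from .tic import RoiSignalSeries, build_tic, classify_tic, TICType
from .semiquant import all_params, PARAM_COLUMNS
from .stats import compare_groups, ComparisonReport

__all__ = [
    "CSV_HEADER",
    "write_signal_table",
    "read_signal_table",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "params_table",
    "validate_report",
    "load_report_schema",
]

log = logging.getLogger("dcekinetics")

CSV_HEADER = ["subject_id", "dose_mmol_per_kg", "scan_slot", "replicate",
              "roi_index", "signal"]

_PRE_LETTERS = string.ascii_lowercase


def write_signal_table(cohort: list[RoiSignalSeries], path) -> None:
    """Write a cohort to the long-form signal CSV (full float precision)."""
    rows = []
    for series in cohort:
        for row_idx in range(series.signals.shape[0]):
            pre = row_idx < series.n_pre
            slot = 0 if pre else row_idx - series.n_pre + 1
            rep = _PRE_LETTERS[row_idx] if pre else "-"
            for roi in range(series.n_roi):
                rows.append((series.subject_id, series.dose, slot, rep,
                             roi + 1, repr(float(series.signals[row_idx, roi]))))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_HEADER) + "\n")
        for r in rows:
            fh.write(",".join(str(v) for v in r) + "\n")


def read_signal_table(path) -> list[RoiSignalSeries]:
    """Read and validate a signal CSV into per-subject series.

    Every subject must carry the complete scan x ROI grid; errors name
    the offending subject, scan slot and CSV row.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "replicate": str},
                     float_precision="round_trip")
    if list(df.columns) != CSV_HEADER:
        raise ValueError(
            f"bad header: expected {','.join(CSV_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    bad = df[~np.isfinite(df["signal"]) | (df["signal"] <= 0)]
    if len(bad):
        i = bad.index[0]
        raise ValueError(
            f"non-positive or missing signal at CSV row {i + 2} "
            f"(subject {bad.loc[i, 'subject_id']}, "
            f"scan_slot {bad.loc[i, 'scan_slot']})"
        )
    series_list = []
    for subject_id, sub in df.groupby("subject_id", sort=False):
        doses = sub["dose_mmol_per_kg"].unique()
        if len(doses) != 1:
            raise ValueError(f"subject {subject_id}: inconsistent dose labels")
        n_roi = int(sub["roi_index"].max())
        pre = sub[sub["scan_slot"] == 0]
        n_pre = pre["replicate"].nunique()
        if n_pre == 0:
            raise ValueError(f"subject {subject_id}: no pre-contrast rows")
        n_post = int(sub["scan_slot"].max())
        grid = np.full((n_pre + n_post, n_roi), np.nan)
        for _, row in sub.iterrows():
            slot = int(row["scan_slot"])
            if slot == 0:
                r = _PRE_LETTERS.index(row["replicate"])
            else:
                r = n_pre + slot - 1
            grid[r, int(row["roi_index"]) - 1] = row["signal"]
        missing = np.argwhere(np.isnan(grid))
        if len(missing):
            ridx, roi = missing[0]
            slot = ridx if ridx < n_pre else ridx - n_pre + 1
            kind = "pre-contrast" if ridx < n_pre else "post-contrast"
            raise ValueError(
                f"subject {subject_id}: missing ROI {roi + 1} at {kind} "
                f"scan_slot {slot}"
            )
        series_list.append(RoiSignalSeries(
            subject_id=str(subject_id), dose=float(doses[0]),
            signals=grid, n_pre=n_pre))
    return series_list


# ---------------------------------------------------------------------------
# configuration


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pre: int = 2
    n_post: int = 39
    t_acq: float = 29.0
    t_offset: float = 50.0

    def build(self) -> ScanSchedule:
        return ScanSchedule(**self.model_dump())


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "gaussian"
    sigma_frac: float = 0.02
    roi_bias_frac: float = 0.02

    def build(self) -> NoiseModel:
        return NoiseModel(**self.model_dump())


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    doses: list[float] = [0.2, 0.3, 0.5]
    n_per_group: int = 7
    ktrans_mean: float = 0.5
    kep_mean: float = 2.0
    r10_mean: float = 0.7
    s_eq_mean: float = 98000.0
    r1_relaxivity: float = 3.6
    cv_ktrans: float = 0.15
    cv_kep: float = 0.15
    cv_r10: float = 0.05
    cv_s_eq: float = 0.05
    noise: NoiseConfig = Field(default_factory=NoiseConfig)

    def build(self, schedule: ScanSchedule, seed: int) -> CohortSpec:
        d = self.model_dump()
        d.pop("noise")
        return CohortSpec(**d, noise=self.noise.build(),
                          schedule=schedule, seed=seed)


class ClassifyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    early_window_s: float = 137.0
    tolerance: float = 0.10


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    homogeneity_alpha: float = 0.05


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    simulate: Optional[SimulateConfig] = None
    input_csv: Optional[str] = None
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# pipeline


def params_table(cohort: list[RoiSignalSeries],
                 schedule: ScanSchedule | None = None) -> pd.DataFrame:
    """Per-subject semi-quantitative parameter table for a cohort."""
    recs = []
    for series in cohort:
        tic = build_tic(series, schedule)
        p = all_params(tic)
        rec = {"subject_id": p.subject_id, "dose": p.dose}
        rec.update({c: getattr(p, c) for c in PARAM_COLUMNS})
        rec["r_wash"] = p.r_wash
        rec["ser_defined"] = p.ser_defined
        rec["washout_degenerate"] = p.washout_degenerate
        recs.append(rec)
    return pd.DataFrame(recs)


@dataclass
class PipelineResult:
    params: pd.DataFrame
    tic_types: dict
    report: dict
    comparison: ComparisonReport | None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate or ingest signals, extract parameters, compare groups.

    Deterministic given the configuration (including seed).  When
    ``out_dir`` is set, writes ``signals.csv`` + ``manifest.json`` (if
    simulating), ``params.csv`` and ``report.json``.
    """
    logging.basicConfig(level=config.log_level)
    schedule = config.schedule.build()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    if (config.simulate is None) == (config.input_csv is None):
        raise ValueError("configure exactly one of 'simulate' or 'input_csv'")
    if config.simulate is not None:
        spec = config.simulate.build(schedule, config.seed)
        cohort = simulate_cohort(spec)
        log.info("simulate: %d subjects, %d dose groups",
                 len(cohort), len(spec.doses))
        if out:
            write_signal_table(cohort, out / "signals.csv")
            (out / "manifest.json").write_text(cohort_manifest(spec),
                                               encoding="utf-8")
    else:
        cohort = read_signal_table(config.input_csv)
        log.info("read: %d subjects from %s", len(cohort), config.input_csv)

    tics = [build_tic(s, schedule) for s in cohort]
    types = [classify_tic(t, config.classify.early_window_s,
                          config.classify.tolerance) for t in tics]
    groups = sorted({t.dose for t in tics})
    tic_types = {
        str(g): {kind.value: sum(1 for t, k in zip(tics, types)
                                 if t.dose == g and k is kind)
                 for kind in TICType}
        for g in groups
    }
    log.info("tic: %d curves classified", len(tics))

    table = params_table(cohort, schedule)
    if out:
        table.to_csv(out / "params.csv", index=False)
    log.info("semiquant: %d parameter rows", len(table))

    comparison = None
    if len(groups) >= 2:
        comparison = compare_groups(
            table, group_col="dose", parameters=PARAM_COLUMNS,
            alpha=config.stats.alpha,
            homogeneity_alpha=config.stats.homogeneity_alpha)
        log.info("stats: %d parameters compared across %d groups",
                 len(comparison.rows), len(groups))
    else:
        log.warning("stats: single group — comparison skipped")

    report = {
        "schema_version": 1,
        "seed": config.seed,
        "n_subjects": len(cohort),
        "groups": [str(g) for g in groups],
        "tic_types": tic_types,
        "comparison": comparison.to_dict() if comparison else None,
    }
    validate_report(report)
    if out:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    return PipelineResult(params=table, tic_types=tic_types,
                          report=report, comparison=comparison)


# ---------------------------------------------------------------------------
# report schema


def load_report_schema() -> dict:
    with resources.files("dcekinetics.data").joinpath(
            "report_schema.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Structural check of a report dict against the shipped schema.

    Covers required keys, types and enums of the schema; raises
    ValueError on the first violation.
    """
    def fail(msg):
        raise ValueError(f"invalid report: {msg}")

    for key in ("schema_version", "n_subjects", "groups", "tic_types",
                "comparison"):
        if key not in report:
            fail(f"missing key {key!r}")
    if report["schema_version"] != 1:
        fail("unsupported schema_version")
    if not isinstance(report["n_subjects"], int) or report["n_subjects"] < 1:
        fail("n_subjects must be a positive integer")
    if not all(isinstance(g, str) for g in report["groups"]):
        fail("groups must be strings")
    for g, counts in report["tic_types"].items():
        for kind in ("I", "II", "III"):
            if not isinstance(counts.get(kind), int) or counts[kind] < 0:
                fail(f"tic_types[{g}][{kind}] must be a non-negative integer")
    comp = report["comparison"]
    if comp is not None:
        for key in ("alpha", "groups", "parameters"):
            if key not in comp:
                fail(f"comparison missing {key!r}")
        for row in comp["parameters"]:
            for key in ("parameter", "route", "statistic", "p", "significant"):
                if key not in row:
                    fail(f"comparison row missing {key!r}")
            if row["route"] not in ("anova", "kruskal-wallis"):
                fail(f"unknown route {row['route']!r}")
            if not 0 <= row["p"] <= 1:
                fail("p outside [0, 1]")
            if not isinstance(row["significant"], bool):
                fail("significant must be boolean")


def report_digest(report: dict) -> str:
    """Stable SHA-256 of a report (canonical JSON encoding)."""
    blob = json.dumps(report, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()
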