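"""End-to-end orchestration: CSV ingestion, the full validation run, and the
Table-1/2/3-style and figure-data outputs, with logging and seeded
reproducibility."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .clamp import ClampTrace
from .exceptions import ConfigurationError, SchemaError
from .indices import SubjectRecord
from .model import AnalysisConfig, ClampStudy, ClampStudyResults
from .synthetic import CohortSpec

logger = logging.getLogger("clampval")

SUBJECT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "waist_cm",
    "hip_cm",
    "percent_fat",
    "fat_free_mass_kg",
    "fasting_glucose_mmol_l",
    "fasting_insulin_uu_ml",
    "tc_mg_dl",
    "hdl_mg_dl",
    "tg_mg_dl",
    "sbp",
    "dbp",
]

CLAMP_COLUMNS = ["subject_id", "time_min", "glucose_mg_dl", "gir_mg_min", "insulin_uu_ml"]

_SUBJECT_FIELD_MAP = {
    "age": "age",
    "height_cm": "height",
    "weight_kg": "weight",
    "waist_cm": "waist",
    "hip_cm": "hip",
    "percent_fat": "percent_fat",
    "fat_free_mass_kg": "fat_free_mass",
    "fasting_glucose_mmol_l": "fasting_glucose",
    "fasting_insulin_uu_ml": "fasting_insulin",
    "tc_mg_dl": "total_chol",
    "hdl_mg_dl": "hdl",
    "tg_mg_dl": "triglycerides",
    "sbp": "sbp",
    "dbp": "dbp",
}


def _check_columns(df: pd.DataFrame, expected: List[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns: {missing}")


def read_subject_csv(path) -> List[SubjectRecord]:
    """Read the subject CSV dialect (one row per subject, empty cell = missing)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str})
    if df.empty:
        logger.warning("subject file %s is empty", path)
        return []
    _check_columns(df, SUBJECT_COLUMNS, "subject CSV")
    records = []
    for i, row in df.iterrows():
        sex = row["sex"]
        if sex not in ("M", "F"):
            raise SchemaError(f"row {i + 2}: unknown sex code {sex!r} (expected M/F)")
        kwargs = {}
        for col, fname in _SUBJECT_FIELD_MAP.items():
            v = row[col]
            if pd.isna(v):
                kwargs[fname] = None
            else:
                try:
                    kwargs[fname] = float(v)
                except (TypeError, ValueError) as exc:
                    raise SchemaError(f"row {i + 2}, column {col}: unparseable value {v!r}") from exc
        records.append(SubjectRecord(subject_id=str(row["subject_id"]), sex=sex, **kwargs))
    return records


def write_subject_csv(records: List[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "sex": r.sex,
                **{col: getattr(r, fname) for col, fname in _SUBJECT_FIELD_MAP.items()},
            }
        )
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


def read_clamp_csv(path) -> List[ClampTrace]:
    """Read the long-format clamp CSV (insulin populated only at sampled times)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if df.empty:
        logger.warning("clamp file %s is empty", path)
        return []
    _check_columns(df, CLAMP_COLUMNS, "clamp CSV")
    traces = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_min")
        samples = {
            float(t): float(v)
            for t, v in zip(grp["time_min"], grp["insulin_uu_ml"])
            if pd.notna(v)
        }
        traces.append(
            ClampTrace(
                subject_id=str(sid),
                time=grp["time_min"].to_numpy(dtype=float),
                blood_glucose=grp["glucose_mg_dl"].to_numpy(dtype=float),
                gir=grp["gir_mg_min"].to_numpy(dtype=float),
                insulin_samples=samples,
            )
        )
    return traces


def write_clamp_csv(traces: List[ClampTrace], path) -> None:
    rows = []
    for t in traces:
        for time, glu, gir in zip(t.time, t.blood_glucose, t.gir):
            ins = None
            for ts, v in t.insulin_samples.items():
                if abs(float(ts) - float(time)) <= 0.25:
                    ins = v
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "time_min": time,
                    "glucose_mg_dl": glu,
                    "gir_mg_min": gir,
                    "insulin_uu_ml": ins,
                }
            )
    pd.DataFrame(rows, columns=CLAMP_COLUMNS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one validation run.

    Exactly one of (``subjects_path`` + ``clamp_path``) or ``cohort_spec``
    must be given.
    """

    subjects_path: Optional[str] = None
    clamp_path: Optional[str] = None
    cohort_spec: Optional[CohortSpec] = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "clampval_out"

    def __post_init__(self) -> None:
        has_files = self.subjects_path is not None and self.clamp_path is not None
        has_spec = self.cohort_spec is not None
        if has_files == has_spec:
            raise ConfigurationError(
                "exactly one of (subjects_path + clamp_path) or cohort_spec must be set"
            )


def run_validation(config: RunConfig) -> ClampStudyResults:
    """Run the full study and write the report bundle to ``config.out_dir``.

    Outputs: ``table1.tsv``, ``correlations.tsv``, ``steiger.tsv``,
    ``regressions.tsv``, ``concordance.tsv``, ``figure_data.tsv`` (Box-Cox
    scatter coordinates plus fitted lines, enough to redraw the
    correlation panels) and ``run_log.json``.  Identical config + seed
    give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_spec is not None:
        study = ClampStudy.from_synthetic(config.cohort_spec)
    else:
        study = ClampStudy.from_csv(config.subjects_path, config.clamp_path)
    results = study.fit(config.analysis)
    dropped = int(results.counts["n_total"] - results.counts["n_complete"])
    logger.info(
        "analysis set: %d of %d subjects complete (%d dropped)",
        results.n_complete,
        int(results.counts["n_total"]),
        dropped,
    )

    results.table1_frame().to_csv(out / "table1.tsv", sep="\t", index=False)
    results.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    results.steiger.to_csv(out / "steiger.tsv", sep="\t", index=False)
    results.regressions.to_csv(out / "regressions.tsv", sep="\t", index=False)
    results.concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)
    _figure_data(results).to_csv(out / "figure_data.tsv", sep="\t", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")

    import clampval

    log = {
        "n_total": int(results.counts["n_total"]),
        "n_complete": results.n_complete,
        "n_dropped": dropped,
        "group_mean_ss_glucose": results.counts["group_mean_ss_glucose"],
        "seed": config.analysis.seed,
        "bootstrap_B": config.analysis.bootstrap_B,
        "t_df": config.analysis.t_df,
        "huber_tuning": config.analysis.huber_tuning,
        "package_version": clampval.__version__,
        "numpy_version": np.__version__,
        "significance_level": 0.05,
        "note": "No multiple-testing correction applied.",
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return results


def _figure_data(results: ClampStudyResults) -> pd.DataFrame:
    """Box-Cox scatter coordinates and OLS line parameters per surrogate/stratum."""
    from . import robust_stats as rs

    df = results.frame
    rows = []
    y_raw = df["m_adjusted"].to_numpy(dtype=float)
    ys = rs._shift_positive(y_raw)
    lam_y = rs.boxcox_lambda(ys)
    yt = rs.boxcox_transform(ys, lam_y)
    for name in results.correlations["surrogate"].unique():
        x_raw = df[name].to_numpy(dtype=float)
        xs = rs._shift_positive(x_raw)
        lam_x = rs.boxcox_lambda(xs)
        xt = rs.boxcox_transform(xs, lam_x)
        slope, intercept = np.polyfit(xt, yt, 1)
        for sid, sex, xv, yv in zip(df["subject_id"], df["sex"], xt, yt):
            rows.append(
                {
                    "surrogate": name,
                    "subject_id": sid,
                    "sex": sex,
                    "x_transformed": xv,
                    "y_transformed": yv,
                    "lambda_x": lam_x,
                    "lambda_y": lam_y,
                    "fit_slope": slope,
                    "fit_intercept": intercept,
                }
            )
    return pd.DataFrame(rows)
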