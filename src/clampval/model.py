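"""Model/Results objects tying the whole validation study together.

``ClampStudy`` is constructed from subject records plus clamp traces (or
a synthetic-cohort specification); ``fit()`` runs the complete analysis
sequence — fasting indices, clamp M values with the glucose-space
correction, descriptive strata tables, Box-Cox shaped multivariate-t
correlations with Fisher-z intervals, Steiger comparisons of dependent
correlations, Huber regressions of M on each index plus sex and
adiposity, and sex-specific tertile agreement with bootstrap kappa
intervals — and returns a ``ClampStudyResults`` carrying the estimates
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import clamp as clamp_mod
from . import concordance as conc_mod
from . import regression as reg_mod
from . import robust_stats as rs
from .cohort_summary import GroupSummary, make_table1, table1_frame
from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    DomainError,
    InsufficientDataError,
)
from .indices import SubjectRecord, convert_glucose, fasting_indices
from .synthetic import CohortSpec, generate_study

#: analysis variables a subject must have for the complete-case set
ANALYSIS_VARIABLES = [
    "age",
    "bmi",
    "waist",
    "whtr",
    "fasting_glucose",
    "fasting_insulin",
    "weight",
    "fat_free_mass",
]

#: surrogate -> direction of association with insulin *sensitivity*
SURROGATE_DIRECTIONS = {
    "fasting_insulin": "decreasing",
    "gi_ratio": "increasing",
    "homa_ir": "decreasing",
    "firi": "decreasing",
    "quicki": "increasing",
    "age": "decreasing",
    "bmi": "decreasing",
    "waist": "decreasing",
    "whtr": "decreasing",
}

FASTING_INDEX_NAMES = ["fasting_insulin", "homa_ir", "quicki", "firi", "gi_ratio"]
CLINICAL_SURROGATE_NAMES = ["age", "bmi", "waist", "whtr"]


@dataclass
class AnalysisConfig:
    """Tunable analysis options (defaults follow the study conventions)."""

    quicki_log_base: float = 10
    gi_glucose_units: str = "mg/dL"
    t_df: float = 4.0  # df of the multivariate-t correlation model
    huber_tuning: float = 1.345
    boxcox: bool = True
    bootstrap_B: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    window: Tuple[float, float] = clamp_mod.DEFAULT_WINDOW
    compute_concordance: bool = True
    compute_regressions: bool = True

    def __post_init__(self) -> None:
        if self.bootstrap_B < 100:
            raise ConfigurationError("bootstrap_B must be >= 100")


class ClampStudy:
    """The validation study: subjects plus their clamp traces.

    Parameters
    ----------
    subjects : list of SubjectRecord
    traces : list of ClampTrace, matched to subjects by ``subject_id``.
    s_true : optional hidden per-subject true sensitivity (synthetic
        cohorts only; used by recovery diagnostics, never by the analysis).
    """

    def __init__(
        self,
        subjects: Sequence[SubjectRecord],
        traces: Sequence[clamp_mod.ClampTrace],
        s_true: Optional[np.ndarray] = None,
    ):
        if len(subjects) < 2:
            raise InsufficientDataError("need at least 2 subjects")
        self.subjects = list(subjects)
        trace_map = {t.subject_id: t for t in traces}
        missing = [s.subject_id for s in subjects if s.subject_id not in trace_map]
        if missing:
            raise DomainError(f"no clamp trace for subjects: {missing[:5]}")
        self.traces = [trace_map[s.subject_id] for s in subjects]
        self.s_true = None if s_true is None else np.asarray(s_true, dtype=float)
        self.spec: Optional[CohortSpec] = None

    @classmethod
    def from_synthetic(cls, spec: CohortSpec) -> "ClampStudy":
        subjects, s_true, traces = generate_study(spec)
        obj = cls(subjects, traces, s_true=s_true)
        obj.spec = spec
        return obj

    @classmethod
    def from_csv(cls, subjects_path, clamp_path) -> "ClampStudy":
        from .pipeline import read_clamp_csv, read_subject_csv

        return cls(read_subject_csv(subjects_path), read_clamp_csv(clamp_path))

    # ------------------------------------------------------------------
    def build_frame(self, config: AnalysisConfig) -> Tuple[pd.DataFrame, Dict[str, int]]:
        """Per-subject analysis frame: record fields, indices and M values.

        The glucose-space correction uses the group-mean steady-state
        glucose of the *complete-case* analysis set, so M values are
        computed after the complete-case filter.
        """
        rows = []
        for i, s in enumerate(self.subjects):
            row = {k: getattr(s, k) for k in SubjectRecord.field_names()}
            if s.waist is not None and s.hip is not None:
                row["whr"] = s.waist / s.hip
            if self.s_true is not None:
                row["s_true"] = self.s_true[i]
            rows.append(row)
        df = pd.DataFrame(rows)

        complete = df[ANALYSIS_VARIABLES].notna().all(axis=1)
        counts = {"n_total": len(df), "n_complete": int(complete.sum())}
        df = df[complete].reset_index(drop=True)
        keep_ids = set(df["subject_id"])
        traces = [t for t in self.traces if t.subject_id in keep_ids]

        # fasting indices
        idx_rows = []
        for _, r in df.iterrows():
            rec = SubjectRecord(
                subject_id=r["subject_id"],
                sex=r["sex"],
                fasting_glucose=r["fasting_glucose"],
                fasting_insulin=r["fasting_insulin"],
            )
            fi = fasting_indices(
                rec,
                quicki_log_base=config.quicki_log_base,
                gi_glucose_units=config.gi_glucose_units,
            )
            idx_rows.append(
                {
                    "homa_ir": fi.homa_ir,
                    "firi": fi.firi,
                    "quicki": fi.quicki,
                    "gi_ratio": fi.gi_ratio,
                }
            )
        df = pd.concat([df, pd.DataFrame(idx_rows)], axis=1)

        # clamp M values against the analysis-set group mean
        g_mean = clamp_mod.group_mean_ss_glucose(traces, config.window)
        m_rows = {}
        subj_map = {s.subject_id: s for s in self.subjects}
        for t in traces:
            res = clamp_mod.m_value(t, subj_map[t.subject_id], g_mean, config.window)
            m_rows[t.subject_id] = res
        df["m_adjusted"] = [m_rows[i].m_adjusted for i in df["subject_id"]]
        df["m_unadjusted"] = [m_rows[i].m_unadjusted for i in df["subject_id"]]
        df["ss_glucose"] = [m_rows[i].ss_glucose for i in df["subject_id"]]
        df["cv_glucose"] = [m_rows[i].cv_glucose for i in df["subject_id"]]
        df["ss_insulin"] = [m_rows[i].ss_insulin for i in df["subject_id"]]
        counts["group_mean_ss_glucose"] = g_mean
        return df, counts

    def fit(self, config: Optional[AnalysisConfig] = None) -> "ClampStudyResults":
        config = config or AnalysisConfig()
        df, counts = self.build_frame(config)
        if len(df) < 10:
            raise InsufficientDataError(
                f"only {len(df)} complete cases; need >= 10 for the analysis"
            )

        table1 = make_table1(df)
        correlations = self._correlations(df, config)
        steiger = self._steiger_comparisons(df, config)
        regressions = (
            self._regressions(df, config) if config.compute_regressions else pd.DataFrame()
        )
        concordance = (
            self._concordance(df, config) if config.compute_concordance else pd.DataFrame()
        )
        return ClampStudyResults(
            model=self,
            config=config,
            frame=df,
            counts=counts,
            table1=table1,
            correlations=correlations,
            steiger=steiger,
            regressions=regressions,
            concordance=concordance,
        )

    # ------------------------------------------------------------------
    @staticmethod
    def _strata(df: pd.DataFrame):
        yield "all", df
        for sex, label in (("M", "male"), ("F", "female")):
            yield label, df[df["sex"] == sex]

    def _correlations(self, df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
        rows = []
        for stratum, sub in self._strata(df):
            y = sub["m_adjusted"].to_numpy(dtype=float)
            for name in FASTING_INDEX_NAMES + CLINICAL_SURROGATE_NAMES:
                x = sub[name].to_numpy(dtype=float)
                res = rs.transformed_robust_correlation(
                    x, y, df=config.t_df, level=config.ci_level, transform=config.boxcox
                )
                rows.append(
                    {
                        "stratum": stratum,
                        "surrogate": name,
                        "r": res.r,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n": res.n,
                        "lambda_x": res.lambda_x,
                        "lambda_y": res.lambda_y,
                        "method": res.method,
                    }
                )
        return pd.DataFrame(rows)

    def _steiger_comparisons(self, df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
        """All pairwise |r| comparisons among fasting indices vs clamp."""
        rows = []
        for stratum, sub in self._strata(df):
            n = len(sub)
            y = sub["m_adjusted"].to_numpy(dtype=float)
            transformed = {}
            for name in FASTING_INDEX_NAMES:
                x = sub[name].to_numpy(dtype=float)
                if config.boxcox:
                    xs = rs._shift_positive(x)
                    transformed[name] = rs.boxcox_transform(xs, rs.boxcox_lambda(xs))
                else:
                    transformed[name] = x
            ys = rs._shift_positive(y)
            yt = rs.boxcox_transform(ys, rs.boxcox_lambda(ys)) if config.boxcox else y
            for a_i in range(len(FASTING_INDEX_NAMES)):
                for b_i in range(a_i + 1, len(FASTING_INDEX_NAMES)):
                    a, b = FASTING_INDEX_NAMES[a_i], FASTING_INDEX_NAMES[b_i]
                    # a pair of (near-)monotone transforms of each other
                    # (e.g. FIRI = 0.9 x HOMA-IR) makes the comparison
                    # degenerate: identical correlations by construction
                    r_ab = np.corrcoef(transformed[a], transformed[b])[0, 1]
                    if abs(r_ab) > 0.9999:
                        continue
                    X = np.column_stack([yt, transformed[a], transformed[b]])
                    try:
                        _, _, corr = rs.t_cov_em(X, df=config.t_df)
                    except (DomainError, ConvergenceError):
                        continue
                    res = rs.compare_correlations_abs(
                        corr[0, 1], corr[0, 2], corr[1, 2], n
                    )
                    rows.append(
                        {
                            "stratum": stratum,
                            "index_a": a,
                            "index_b": b,
                            "r_a": corr[0, 1],
                            "r_b": corr[0, 2],
                            "t": res.t_stat,
                            "df": res.df,
                            "p": res.p_value,
                        }
                    )
        return pd.DataFrame(rows)

    def _regressions(self, df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
        """Huber fits mirroring the published model menu.

        Adiposity-only models: sex + one of BMI / waist / WHtR, or sex +
        BMI + waist.  Index models: each fasting index + sex + waist.
        Variables enter on their Box-Cox scales when ``config.boxcox``.
        """
        y = df["m_adjusted"].to_numpy(dtype=float)
        sex = df["sex"].to_numpy()

        def scaled(name):
            x = df[name].to_numpy(dtype=float)
            if not config.boxcox:
                return x
            xs = rs._shift_positive(x)
            return rs.boxcox_transform(xs, rs.boxcox_lambda(xs))

        cache = {
            n: scaled(n) for n in FASTING_INDEX_NAMES + CLINICAL_SURROGATE_NAMES
        }
        models = [("bmi", None), ("waist", None), ("whtr", None), ("bmi", "waist")]
        rows = []
        for main, extra in models:
            label = main if extra is None else f"{main}+{extra}"
            adip = [cache[extra]] if extra is not None else None
            X, names = reg_mod.build_design(
                cache[main],
                sex,
                adiposity=adip,
                adiposity_names=[extra] if extra else None,
                index_name=main,
            )
            fit = reg_mod.fit_huber(y, X, tuning=config.huber_tuning, term_names=names)
            rows.extend(self._fit_rows(f"adiposity:{label}", fit))
        for name in FASTING_INDEX_NAMES:
            X, names = reg_mod.build_design(
                cache[name],
                sex,
                adiposity=[cache["waist"]],
                adiposity_names=["waist"],
                index_name=name,
            )
            fit = reg_mod.fit_huber(y, X, tuning=config.huber_tuning, term_names=names)
            rows.extend(self._fit_rows(f"index:{name}", fit))
        return pd.DataFrame(rows)

    @staticmethod
    def _fit_rows(model_label: str, fit: reg_mod.RobustFit) -> List[dict]:
        rows = []
        for nm, b, se, p in zip(fit.term_names, fit.coefficients, fit.std_errors, fit.p_values):
            rows.append(
                {
                    "model": model_label,
                    "term": nm,
                    "beta": b,
                    "se": se,
                    "p": p,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                }
            )
        return rows

    def _concordance(self, df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
        rows = []
        rng_seed = np.random.SeedSequence([config.seed, 97])
        seeds = rng_seed.generate_state(3 * len(SURROGATE_DIRECTIONS)).tolist()
        k = 0
        for name, direction in SURROGATE_DIRECTIONS.items():
            for stratum, sub, sex_arg in (
                ("all", df, df["sex"].to_numpy()),
                ("male", df[df["sex"] == "M"], None),
                ("female", df[df["sex"] == "F"], None),
            ):
                res = conc_mod.concordance_analysis(
                    sub["m_adjusted"].to_numpy(dtype=float),
                    sub[name].to_numpy(dtype=float),
                    sex=sex_arg,
                    stratum=stratum,
                    ref_direction="increasing",
                    test_direction=direction,
                    B=config.bootstrap_B,
                    level=config.ci_level,
                    seed=int(seeds[k] % (2**31)),
                )
                k += 1
                rows.append(
                    {
                        "surrogate": name,
                        "stratum": stratum,
                        "pct_low": res.pct_correct_by_ref[0],
                        "pct_medium": res.pct_correct_by_ref[1],
                        "pct_high": res.pct_correct_by_ref[2],
                        "n_correct": int(np.trace(res.table)),
                        "n": res.n,
                        "overall_correct": res.overall_correct,
                        "kappa": res.kappa,
                        "kappa_ci_low": res.kappa_ci[0],
                        "kappa_ci_high": res.kappa_ci[1],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ClampStudyResults:
    """Fitted results bundle with a text ``summary()``."""

    model: ClampStudy
    config: AnalysisConfig
    frame: pd.DataFrame
    counts: Dict[str, float]
    table1: List[GroupSummary]
    correlations: pd.DataFrame
    steiger: pd.DataFrame
    regressions: pd.DataFrame
    concordance: pd.DataFrame

    @property
    def n_complete(self) -> int:
        return int(self.counts["n_complete"])

    def correlation(self, surrogate: str, stratum: str = "all") -> rs.CorrelationResult:
        row = self.correlations[
            (self.correlations["surrogate"] == surrogate)
            & (self.correlations["stratum"] == stratum)
        ]
        if row.empty:
            raise KeyError(f"no correlation for {surrogate!r} in stratum {stratum!r}")
        r = row.iloc[0]
        return rs.CorrelationResult(
            r=float(r["r"]),
            ci_low=float(r["ci_low"]),
            ci_high=float(r["ci_high"]),
            n=int(r["n"]),
            lambda_x=r["lambda_x"],
            lambda_y=r["lambda_y"],
            method=r["method"],
        )

    def table1_frame(self) -> pd.DataFrame:
        return table1_frame(self.table1)

    def summary(self) -> str:
        lines = []
        lines.append("Clamp validation study of fasting insulin-sensitivity indices")
        lines.append("=" * 62)
        lines.append(
            f"Subjects: {self.counts['n_total']} enrolled, "
            f"{self.n_complete} complete cases analysed"
        )
        m = self.frame["m_adjusted"]
        lines.append(
            f"Clamp M (adjusted to fat-free mass): "
            f"{m.mean():.1f} +/- {m.std(ddof=1):.1f} mg/min/kg FFM"
        )
        lines.append(
            f"Group steady-state glucose: {self.counts['group_mean_ss_glucose']:.1f} mg/dL"
        )
        lines.append("")
        lines.append("Correlations with clamp M (all subjects, Box-Cox + multivariate-t):")
        sub = self.correlations[self.correlations["stratum"] == "all"]
        for _, r in sub.iterrows():
            lines.append(
                f"  {r['surrogate']:<16} r = {r['r']:+.2f} "
                f"({r['ci_low']:+.2f} to {r['ci_high']:+.2f})"
            )
        if not self.concordance.empty:
            lines.append("")
            lines.append("Tertile agreement vs clamp thirds (all subjects):")
            sub = self.concordance[self.concordance["stratum"] == "all"]
            for _, r in sub.iterrows():
                lines.append(
                    f"  {r['surrogate']:<16} correct {r['n_correct']}/{r['n']}  "
                    f"kappa = {r['kappa']:+.2f} "
                    f"({r['kappa_ci_low']:+.2f} to {r['kappa_ci_high']:+.2f})"
                )
        if not self.regressions.empty:
            lines.append("")
            lines.append("Robust regression R^2 (index + sex + waist models):")
            for model_label in self.regressions["model"].unique():
                if model_label.startswith("index:"):
                    r2 = self.regressions.loc[
                        self.regressions["model"] == model_label, "r_squared"
                    ].iloc[0]
                    lines.append(f"  {model_label.split(':', 1)[1]:<16} R^2 = {r2:.3f}")
        lines.append("")
        lines.append(
            "R^2 for robust fits is the squared correlation of fitted vs observed. "
            "Significance level 0.05; no multiple-testing correction."
        )
        return "\n".join(lines)
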