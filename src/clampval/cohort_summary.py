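"""Descriptive cohort tables by sex x BMI category with Kruskal-Wallis,
linear-trend and sex-by-category interaction tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .indices import bmi_category

CATEGORY_ORDER = ("lean", "overweight", "obese")
_SCORES = {c: k for k, c in enumerate(CATEGORY_ORDER)}


@dataclass
class GroupSummary:
    """Per-variable summary across the six sex x BMI-category strata."""

    variable: str
    stats: Dict[Tuple[str, str], Tuple[float, float, int]] = field(default_factory=dict)
    p_kruskal: Dict[str, Optional[float]] = field(default_factory=dict)
    p_linearity: Dict[str, Optional[float]] = field(default_factory=dict)
    p_interaction: Optional[float] = None


def kruskal_wallis(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k-1 df.

    When all pooled values are identical, H = 0 and p = 1 (no error),
    since there is trivially no evidence of a group difference.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs >= 2 non-empty groups")
    total = sum(len(g) for g in groups)
    if total < 3:
        raise InsufficientDataError("Kruskal-Wallis needs >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def linear_trend_test(values, category_scores) -> float:
    """Two-sided p for the least-squares slope of values on ordinal scores 0/1/2."""
    values = np.asarray(values, dtype=float)
    scores = np.asarray(category_scores, dtype=float)
    if values.size != scores.size:
        raise DomainError("values and scores have mismatched lengths")
    if values.size < 3:
        raise InsufficientDataError("trend test needs n >= 3")
    if np.unique(scores).size < 2:
        raise DomainError("trend test needs >= 2 distinct category scores")
    res = stats.linregress(scores, values)
    return float(res.pvalue)


def interaction_test(values, sex, category, two_df: bool = False) -> float:
    """p for sex x BMI-category interaction in a linear model with main effects.

    Default is the 1-df test of the sex x ordinal-score product term
    (linear heterogeneity); ``two_df=True`` tests the full categorical
    interaction by an F-test of both product terms.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    category = np.asarray(category, dtype=object)
    if not (values.size == sex.size == category.size):
        raise DomainError("values, sex and category have mismatched lengths")
    if np.unique(sex).size < 2:
        raise DomainError("interaction test needs both sexes present")
    cats_present = np.unique(category)
    if cats_present.size < 2:
        raise DomainError("interaction test needs >= 2 BMI categories present")
    female = (sex == "F").astype(float)
    score = np.array([_SCORES[c] for c in category], dtype=float)
    if two_df:
        d_ow = (category == "overweight").astype(float)
        d_ob = (category == "obese").astype(float)
        X_full = np.column_stack(
            [np.ones_like(values), female, d_ow, d_ob, female * d_ow, female * d_ob]
        )
        X_red = X_full[:, :4]
        keep = [c for c in range(X_full.shape[1]) if np.ptp(X_full[:, c]) > 0 or c == 0]
        X_full = X_full[:, keep]
        if X_full.shape[1] <= X_red.shape[1]:
            raise DomainError("interaction term inestimable (empty sex x category cell)")
        full = sm.OLS(values, X_full).fit()
        red = sm.OLS(values, X_red).fit()
        df_num = X_full.shape[1] - X_red.shape[1]
        f = ((red.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
        return float(stats.f.sf(f, df_num, full.df_resid))
    X = np.column_stack([np.ones_like(values), female, score, female * score])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DomainError("interaction term inestimable (empty sex x category cell)")
    fit = sm.OLS(values, X).fit()
    return float(fit.pvalues[3])


#: Table-1-style row order: (label, column accessor)
TABLE1_VARIABLES = [
    ("Age (years)", "age"),
    ("BMI (kg/m2)", "bmi"),
    ("Percent fat (%)", "percent_fat"),
    ("Waist circumference (cm)", "waist"),
    ("Hip circumference (cm)", "hip"),
    ("Waist-to-hip ratio", "whr"),
    ("Waist-to-height ratio", "whtr"),
    ("Systolic blood pressure (mmHg)", "sbp"),
    ("Diastolic blood pressure (mmHg)", "dbp"),
    ("Total cholesterol (mg/dL)", "total_chol"),
    ("Triglycerides (mg/dL)", "triglycerides"),
    ("HDL cholesterol (mg/dL)", "hdl"),
    ("LDL cholesterol (mg/dL)", "ldl"),
    ("Fasting glucose (mmol/L)", "fasting_glucose"),
    ("Fasting insulin (uU/mL)", "fasting_insulin"),
    ("M unadjusted (mg/min/kg)", "m_unadjusted"),
    ("M adjusted to lean mass (mg/min/kg)", "m_adjusted"),
    ("Plasma insulin (uU/mL)", "fasting_insulin"),
    ("Glucose/Insulin ratio", "gi_ratio"),
    ("HOMA-IR", "homa_ir"),
    ("FIRI", "firi"),
    ("QUICKI", "quicki"),
]


def make_table1(df: pd.DataFrame, variables=None) -> List[GroupSummary]:
    """One GroupSummary per analysis variable over the sex x BMI-category strata.

    ``df`` is the analysis frame (one row per subject) carrying at least
    ``sex`` and ``bmi`` plus the summarised columns; rows missing a given
    variable are dropped for that variable only.  Empty strata yield n=0
    with the tests left as None.
    """
    if "bmi" not in df or "sex" not in df:
        raise DomainError("analysis frame must carry 'sex' and 'bmi' columns")
    cat = df["bmi"].map(bmi_category)
    if variables is None:
        variables = [(lbl, col) for lbl, col in TABLE1_VARIABLES if col in df.columns]
    out: List[GroupSummary] = []
    for label, col in variables:
        gs = GroupSummary(variable=label)
        valid = df[col].notna()
        sub = df[valid]
        sub_cat = cat[valid]
        for sex in ("M", "F"):
            groups = []
            for c in CATEGORY_ORDER:
                m = (sub["sex"] == sex) & (sub_cat == c)
                vals = sub.loc[m, col].to_numpy(dtype=float)
                gs.stats[(sex, c)] = (
                    float(vals.mean()) if vals.size else float("nan"),
                    float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    int(vals.size),
                )
                groups.append(vals)
            nonempty = [g for g in groups if g.size > 0]
            if len(nonempty) >= 2 and sum(g.size for g in nonempty) >= 3:
                gs.p_kruskal[sex] = kruskal_wallis(nonempty)[1]
                vals = np.concatenate(groups)
                scores = np.concatenate(
                    [np.full(g.size, k, dtype=float) for k, g in enumerate(groups)]
                )
                if np.unique(scores).size >= 2 and vals.size >= 3:
                    gs.p_linearity[sex] = linear_trend_test(vals, scores)
            else:
                gs.p_kruskal[sex] = None
                gs.p_linearity[sex] = None
        try:
            gs.p_interaction = interaction_test(
                sub[col].to_numpy(dtype=float), sub["sex"].to_numpy(), sub_cat.to_numpy()
            )
        except (DomainError, InsufficientDataError):
            gs.p_interaction = None
        out.append(gs)
    return out


def table1_frame(summaries: List[GroupSummary]) -> pd.DataFrame:
    """Flatten GroupSummary objects into a Table-1-style DataFrame."""
    rows = []
    for gs in summaries:
        row = {"variable": gs.variable}
        for (sex, c), (mean, sd, n) in gs.stats.items():
            key = f"{sex}_{c}"
            row[key] = f"{mean:.2f} +/- {sd:.2f}" if np.isfinite(mean) else ""
            row[f"{key}_n"] = n
        for sex in ("M", "F"):
            row[f"p_kruskal_{sex}"] = gs.p_kruskal.get(sex)
            row[f"p_linearity_{sex}"] = gs.p_linearity.get(sex)
        row["p_interaction"] = gs.p_interaction
        rows.append(row)
    return pd.DataFrame(rows)
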