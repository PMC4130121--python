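"""Tertile classification agreement: sex-specific thirds, 3x3 cross-tables,
Cohen's kappa and bootstrap confidence intervals.

Thirds are rank-based with a stable tie rule, so any strictly monotone
transform of the values yields identical categories — HOMA-IR and FIRI
(FIRI = 0.9 x HOMA-IR) therefore always produce identical agreement rows.
For indices that *decrease* with insulin sensitivity (age, BMI, waist,
WHtR, fasting insulin, HOMA-IR, FIRI) the ordering is negated before
ranking, so "high" always means high insulin sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import DomainError, InsufficientDataError

CATEGORIES = ("low", "medium", "high")


@dataclass(frozen=True)
class ConcordanceResult:
    """3x3 cross-classification of surrogate thirds against reference thirds."""

    table: np.ndarray  # rows: reference thirds, cols: surrogate thirds
    pct_correct_by_ref: np.ndarray  # % agreement per reference category
    overall_correct: float  # trace / n
    kappa: float
    kappa_ci: Optional[Tuple[float, float]]
    n: int
    stratum: str = "all"


def _third_sizes(n: int) -> Tuple[int, int, int]:
    """Group sizes (low, medium, high): base floor(n/3), remainders to high then medium."""
    base = n // 3
    rem = n % 3
    sizes = [base, base, base]
    if rem >= 1:
        sizes[2] += 1
    if rem == 2:
        sizes[1] += 1
    return tuple(sizes)


def assign_thirds(values, direction: str = "increasing") -> np.ndarray:
    """Rank-based thirds of insulin sensitivity: 'low' / 'medium' / 'high'.

    ``direction='increasing'`` means larger values indicate higher insulin
    sensitivity; ``'decreasing'`` negates the ordering first.  Ranking is
    stable (ties keep original order), so the assignment is deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise InsufficientDataError(f"tertile assignment needs n >= 3, got {n}")
    if np.any(~np.isfinite(values)):
        raise DomainError("values contain missing entries")
    if direction not in ("increasing", "decreasing"):
        raise DomainError(f"direction must be 'increasing' or 'decreasing', got {direction!r}")
    v = values if direction == "increasing" else -values
    order = np.argsort(v, kind="stable")
    sizes = _third_sizes(n)
    # warn when a run of ties straddles a cut point (assignment stays stable)
    cuts = np.cumsum(sizes)[:-1]
    sorted_v = v[order]
    for c in cuts:
        if sorted_v[c - 1] == sorted_v[c]:
            warnings.warn("tied values span a tertile boundary; stable-order rule applied")
            break
    cats = np.empty(n, dtype=object)
    start = 0
    for size, label in zip(sizes, CATEGORIES):
        cats[order[start : start + size]] = label
        start += size
    return cats


def sex_specific_thirds(values, sex, direction: str = "increasing") -> np.ndarray:
    """Thirds computed within each sex separately, then pooled."""
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    cats = np.empty(values.size, dtype=object)
    for s in np.unique(sex):
        m = sex == s
        cats[m] = assign_thirds(values[m], direction)
    return cats


def cross_classify(ref_cats, test_cats, stratum: str = "all") -> ConcordanceResult:
    """Counts, per-reference-category % correct, overall agreement and kappa."""
    ref_cats = np.asarray(ref_cats, dtype=object)
    test_cats = np.asarray(test_cats, dtype=object)
    if ref_cats.size != test_cats.size:
        raise DomainError("category vectors have mismatched lengths")
    for arr, nm in ((ref_cats, "reference"), (test_cats, "test")):
        bad = set(arr) - set(CATEGORIES)
        if bad:
            raise DomainError(f"unknown {nm} categories: {sorted(map(str, bad))}")
    n = ref_cats.size
    table = np.zeros((3, 3), dtype=int)
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    for r, t in zip(ref_cats, test_cats):
        table[idx[r], idx[t]] += 1
    row_tot = table.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_tot > 0, 100.0 * np.diag(table) / row_tot, np.nan)
    return ConcordanceResult(
        table=table,
        pct_correct_by_ref=pct,
        overall_correct=float(np.trace(table)) / n,
        kappa=cohen_kappa(table),
        kappa_ci=None,
        n=n,
        stratum=stratum,
    )


def cohen_kappa(table) -> float:
    """Unweighted Cohen's kappa from a square contingency table of counts."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise DomainError("kappa requires a square table")
    if np.any(table < 0):
        raise DomainError("table counts must be non-negative")
    total = table.sum()
    if total <= 0:
        raise DomainError("table is empty")
    p_o = np.trace(table) / total
    p_e = float((table.sum(axis=1) / total) @ (table.sum(axis=0) / total))
    if abs(1.0 - p_e) < 1e-12:
        raise DomainError("kappa undefined: expected agreement is 1 (degenerate margins)")
    return float((p_o - p_e) / (1.0 - p_e))


def bootstrap_kappa_ci(
    ref_values,
    test_values,
    sex=None,
    ref_direction: str = "increasing",
    test_direction: str = "increasing",
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for kappa, recomputing thirds per replicate.

    Subjects are resampled with replacement; when ``sex`` is given the
    resampling and the tertile formation are stratified by sex (matching
    how the observed thirds were formed).  Replicates with degenerate
    margins are skipped with a warning.
    """
    ref_values = np.asarray(ref_values, dtype=float)
    test_values = np.asarray(test_values, dtype=float)
    n = ref_values.size
    if test_values.size != n:
        raise DomainError("value vectors have mismatched lengths")
    if sex is not None:
        sex = np.asarray(sex)
        strata = [np.flatnonzero(sex == s) for s in np.unique(sex)]
        if any(len(ix) < 6 for ix in strata):
            raise InsufficientDataError("bootstrap needs n >= 6 per stratum")
    else:
        strata = [np.arange(n)]
        if n < 6:
            raise InsufficientDataError("bootstrap needs n >= 6")
    rng = np.random.default_rng(seed)
    kappas = []
    skipped = 0
    for _ in range(B):
        try:
            parts_ref, parts_test = [], []
            for ix in strata:
                take = rng.choice(ix, size=len(ix), replace=True)
                parts_ref.append(assign_thirds(ref_values[take], ref_direction))
                parts_test.append(assign_thirds(test_values[take], test_direction))
            res = cross_classify(np.concatenate(parts_ref), np.concatenate(parts_test))
            kappas.append(res.kappa)
        except DomainError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicates skipped (degenerate margins)")
    if not kappas:
        raise InsufficientDataError("all bootstrap replicates were degenerate")
    alpha = 1.0 - level
    lo, hi = np.quantile(kappas, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def concordance_analysis(
    ref_values,
    test_values,
    sex: Optional[Sequence] = None,
    stratum: str = "all",
    ref_direction: str = "increasing",
    test_direction: str = "increasing",
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> ConcordanceResult:
    """Full tertile agreement analysis for one surrogate against the reference.

    When ``sex`` is supplied, thirds are formed within sex and pooled
    (the 'all subjects' convention); otherwise thirds are formed on the
    stratum as given.
    """
    if sex is not None:
        ref_cats = sex_specific_thirds(ref_values, sex, ref_direction)
        test_cats = sex_specific_thirds(test_values, sex, test_direction)
    else:
        ref_cats = assign_thirds(ref_values, ref_direction)
        test_cats = assign_thirds(test_values, test_direction)
    base = cross_classify(ref_cats, test_cats, stratum=stratum)
    ci = bootstrap_kappa_ci(
        ref_values,
        test_values,
        sex=sex,
        ref_direction=ref_direction,
        test_direction=test_direction,
        B=B,
        level=level,
        seed=seed,
    )
    return ConcordanceResult(
        table=base.table,
        pct_correct_by_ref=base.pct_correct_by_ref,
        overall_correct=base.overall_correct,
        kappa=base.kappa,
        kappa_ci=ci,
        n=base.n,
        stratum=stratum,
    )
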