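"""Tertile assignment, cross-classification, Cohen's kappa and its bootstrap CI."""

import numpy as np
import pytest

from clampval import assign_thirds, bootstrap_kappa_ci, cohen_kappa, cross_classify
from clampval.concordance import concordance_analysis, sex_specific_thirds
from clampval.exceptions import DomainError, InsufficientDataError


def test_thirds_of_nine_increasing_and_decreasing():
    vals = np.arange(1.0, 10.0)
    up = assign_thirds(vals, "increasing")
    assert list(up) == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3
    down = assign_thirds(vals, "decreasing")
    assert list(down) == ["high"] * 3 + ["medium"] * 3 + ["low"] * 3


def test_third_sizes_match_study_margins():
    """Group sizes for n=47/32 and their pooled margins 25/27/27."""
    men = assign_thirds(np.arange(47.0))
    women = assign_thirds(np.arange(32.0))
    count = lambda cats, c: sum(1 for x in cats if x == c)
    assert [count(men, c) for c in ("low", "medium", "high")] == [15, 16, 16]
    assert [count(women, c) for c in ("low", "medium", "high")] == [10, 11, 11]
    sex = np.array(["M"] * 47 + ["F"] * 32)
    pooled = sex_specific_thirds(np.arange(79.0), sex)
    assert [count(pooled, c) for c in ("low", "medium", "high")] == [25, 27, 27]


def test_tied_boundary_resolved_by_stable_order():
    vals = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
    with pytest.warns(UserWarning, match="tie"):
        cats = assign_thirds(vals)
    # stable sort keeps original order among the tied 2.0s
    assert list(cats) == ["low", "low", "medium", "medium", "high", "high"]
    with pytest.warns(UserWarning):
        again = assign_thirds(vals)
    assert list(again) == list(cats)


def test_assign_thirds_validation():
    with pytest.raises(InsufficientDataError):
        assign_thirds([1.0, 2.0])
    with pytest.raises(DomainError):
        assign_thirds([1.0, np.nan, 2.0])
    with pytest.raises(DomainError):
        assign_thirds([1.0, 2.0, 3.0], direction="sideways")


def test_monotone_transform_invariance():
    """Rank-based thirds are identical for any strictly increasing transform,
    so HOMA-IR and FIRI (= 0.9 x HOMA-IR) always agree exactly."""
    rng = np.random.default_rng(5)
    homa = rng.lognormal(0.2, 0.6, size=79)
    firi = 0.9 * homa
    quirky = np.exp(homa)  # another strictly monotone transform
    assert list(assign_thirds(homa, "decreasing")) == list(assign_thirds(firi, "decreasing"))
    assert list(assign_thirds(homa, "decreasing")) == list(assign_thirds(quirky, "decreasing"))


def test_cross_classify_perfect_and_disjoint():
    cats = np.array(["low"] * 5 + ["medium"] * 5 + ["high"] * 5, dtype=object)
    res = cross_classify(cats, cats)
    assert np.all(np.diag(res.table) == 5)
    assert res.overall_correct == 1.0
    assert np.all(res.pct_correct_by_ref == 100.0)
    rotated = np.array(
        ["high"] * 5 + ["low"] * 5 + ["medium"] * 5, dtype=object
    )  # cyclic shift: no agreement anywhere
    res2 = cross_classify(cats, rotated)
    assert np.trace(res2.table) == 0
    assert res2.overall_correct == 0.0


def test_random_classification_agreement_near_one_third(rng):
    n = 10_000
    a = assign_thirds(rng.standard_normal(n))
    b = assign_thirds(rng.standard_normal(n))
    res = cross_classify(a, b)
    assert res.overall_correct == pytest.approx(1 / 3, abs=0.02)


def test_kappa_reference_values():
    assert cohen_kappa(np.diag([5, 5, 5])) == pytest.approx(1.0)
    observed_equals_expected = np.array([[4, 2, 2], [4, 2, 2], [4, 2, 2]])
    assert cohen_kappa(observed_equals_expected) == pytest.approx(0.0)
    # uniform margins 15/15/15, diagonal total 30 of 45: p_o=2/3, p_e=1/3
    table = np.array([[10, 2, 3], [3, 10, 2], [2, 3, 10]])
    assert table.sum() == 45 and np.trace(table) == 30
    assert cohen_kappa(table) == pytest.approx(0.5)


def test_kappa_matches_sklearn_on_random_labels(rng):
    from sklearn.metrics import cohen_kappa_score

    a = rng.integers(0, 3, size=300)
    b = rng.integers(0, 3, size=300)
    table = np.zeros((3, 3))
    for i, j in zip(a, b):
        table[i, j] += 1
    assert cohen_kappa(table) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_kappa_relabel_invariance(rng):
    a = rng.integers(0, 3, size=200)
    b = rng.integers(0, 3, size=200)
    table = np.zeros((3, 3))
    for i, j in zip(a, b):
        table[i, j] += 1
    perm = [2, 0, 1]
    relabeled = table[np.ix_(perm, perm)]
    assert cohen_kappa(relabeled) == pytest.approx(cohen_kappa(table))


def test_kappa_validation():
    with pytest.raises(DomainError):
        cohen_kappa(np.zeros((3, 3)))
    with pytest.raises(DomainError):
        cohen_kappa(np.array([[5, 0, 0], [0, 0, 0], [0, 0, 0]]))  # degenerate margins


def test_bootstrap_ci_perfect_agreement_collapses(rng):
    vals = rng.standard_normal(30)
    lo, hi = bootstrap_kappa_ci(vals, vals, B=200, seed=1)
    assert lo == hi == pytest.approx(1.0)


def test_bootstrap_ci_seed_determinism(rng):
    x = rng.standard_normal(40)
    y = x + rng.standard_normal(40)
    ci1 = bootstrap_kappa_ci(x, y, B=300, seed=7)
    ci2 = bootstrap_kappa_ci(x, y, B=300, seed=7)
    ci3 = bootstrap_kappa_ci(x, y, B=300, seed=8)
    assert ci1 == ci2
    assert ci1 != ci3


def test_bootstrap_ci_nominal_coverage(rng):
    """Percentile-interval coverage for a misclassification model with a
    population kappa fixed by a large one-off simulation."""
    sigma = 0.5
    n_big = 200_000
    x = rng.standard_normal(n_big)
    kappa_pop = cross_classify(
        assign_thirds(x), assign_thirds(x + sigma * rng.standard_normal(n_big))
    ).kappa
    n, outer, B = 60, 300, 200
    covered = 0
    for _ in range(outer):
        xi = rng.standard_normal(n)
        yi = xi + sigma * rng.standard_normal(n)
        lo, hi = bootstrap_kappa_ci(xi, yi, B=B, seed=int(rng.integers(2**31)))
        covered += lo <= kappa_pop <= hi
    assert 0.88 <= covered / outer <= 0.99


def test_concordance_analysis_sex_pooling(rng):
    n = 79
    sex = np.array(["M"] * 47 + ["F"] * 32)
    m = rng.standard_normal(n)
    surrogate = -m + 0.8 * rng.standard_normal(n)
    res = concordance_analysis(m, surrogate, sex=sex, test_direction="decreasing", B=200, seed=3)
    assert res.table.sum() == n
    assert res.n == n
    assert res.overall_correct == pytest.approx(np.trace(res.table) / n)
    assert res.kappa_ci[0] <= res.kappa <= res.kappa_ci[1]
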