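"""Differential statistics: size factors, NB Wald test, miRNA summary,
multi-set overlap."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from roguesrna import diffsrna


def _nb_matrix(seed, n=500, mu=50.0, alpha=0.1, fold=None, reps=2):
    rng = np.random.default_rng(seed)
    fold = np.ones(n) if fold is None else fold
    lam_a = rng.gamma(1 / alpha, alpha * mu, size=(n, reps))
    lam_b = rng.gamma(1 / alpha, alpha * mu * fold[:, None], size=(n, reps))
    counts = np.hstack([rng.poisson(lam_a), rng.poisson(lam_b)])
    cols = [f"a{i}" for i in range(reps)] + [f"b{i}" for i in range(reps)]
    cond = {c: ("A" if c.startswith("a") else "B") for c in cols}
    return pd.DataFrame(counts, columns=cols), cond


# ---------------------------------------------------------------- factors

def test_size_factors_identical_libraries():
    mat = pd.DataFrame({"a": np.arange(1, 101), "b": np.arange(1, 101)})
    f = diffsrna.size_factors(mat)
    assert np.allclose(f, [1.0, 1.0])


def test_size_factors_scaling():
    mat = pd.DataFrame({"a": np.arange(1, 101), "b": 2 * np.arange(1, 101)})
    f = diffsrna.size_factors(mat)
    assert f["b"] / f["a"] == pytest.approx(2.0)


def test_size_factors_match_brute_force_median_of_ratios():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.integers(1, 100, size=(10, 4)),
                       columns=list("abcd")).astype(float)
    f = diffsrna.size_factors(mat, min_positive_units=5)
    log_ref = np.log(mat).mean(axis=1)
    expected = np.exp(np.median(np.log(mat).sub(log_ref, axis=0), axis=0))
    expected = expected / np.exp(np.mean(np.log(expected)))
    assert np.allclose(f, expected)


def test_size_factors_all_zero_library_errors():
    mat = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError, match="all-zero"):
        diffsrna.size_factors(mat)


# ---------------------------------------------------------------- NB Wald

def test_identical_counts_give_zero_lfc():
    mat = pd.DataFrame({"a": [10, 50], "b": [10, 50],
                        "c": [10, 50], "d": [10, 50]})
    res = diffsrna.nb_wald_test(mat, {"a": "A", "b": "A", "c": "B", "d": "B"},
                                "A", "B")
    assert np.allclose(res.log2fc, 0.0)
    assert np.all(res.p >= 0.99)


def test_condition_swap_negates_lfc_preserves_p():
    mat, cond = _nb_matrix(2, n=200)
    res1 = diffsrna.nb_wald_test(mat, cond, "A", "B")
    res2 = diffsrna.nb_wald_test(mat, cond, "B", "A")
    assert np.allclose(res1.log2fc, -res2.log2fc)
    assert np.allclose(res1.p, res2.p)


def test_all_zero_unit_flagged_untestable():
    mat = pd.DataFrame({"a": [0, 10], "b": [0, 12],
                        "c": [0, 9], "d": [0, 11]})
    res = diffsrna.nb_wald_test(mat, {"a": "A", "b": "A", "c": "B", "d": "B"},
                                "A", "B")
    assert bool(res.untestable.iloc[0])
    assert res.p.iloc[0] == 1.0 and res.log2fc.iloc[0] == 0.0
    assert res.padj.iloc[0] == 1.0


def test_poisson_limit_agrees_with_proportion_z_test():
    """Dispersion forced to 0, equal size factors: the Wald p agrees with
    the two-proportion z-test on the same totals (moderate effects)."""
    worst = 0.0
    for a, b in [(50, 50), (50, 70), (60, 88), (88, 50), (40, 40)]:
        mat = pd.DataFrame({"x": [a], "y": [b]})
        res = diffsrna.nb_wald_test(mat, {"x": "A", "y": "B"}, "A", "B",
                                    factors=pd.Series({"x": 1.0, "y": 1.0}),
                                    fixed_dispersion=0.0)
        z = (b - a) / np.sqrt(a + b) if a != b else 0.0
        p_prop = 2 * stats.norm.sf(abs(z))
        if a != b:
            worst = max(worst, abs(np.log10(res.p.iloc[0]) - np.log10(p_prop)))
        else:
            assert res.p.iloc[0] > 0.95
    assert worst < 0.1


def test_bh_is_monotone_within_family():
    mat, cond = _nb_matrix(3, n=300)
    res = diffsrna.nb_wald_test(mat, cond, "A", "B")
    sub = res[~res.untestable].sort_values("p")
    assert (np.diff(sub.padj.to_numpy()) >= -1e-12).all()
    assert (sub.padj >= sub.p - 1e-12).all()


def test_power_monotone_in_effect_size():
    """Detection of a planted minority effect grows with its size.

    The effect is planted on 30 of 300 units: a global fold change would
    (correctly) be absorbed by median-of-ratios normalization."""
    n, n_planted = 300, 30
    hits = []
    for fold_val in (1.0, 2.0, 4.0, 8.0):
        fold = np.ones(n)
        fold[:n_planted] = fold_val
        mat, cond = _nb_matrix(4, n=n, fold=fold)
        res = diffsrna.nb_wald_test(mat, cond, "A", "B")
        hits.append(int((res.p.iloc[:n_planted] < 0.01).sum()))
    assert hits == sorted(hits)
    assert hits[-1] > 0.9 * n_planted


# ---------------------------------------------------------------- calls

def test_calls_empty_and_mutually_exclusive():
    mat, cond = _nb_matrix(5, n=200)
    called = diffsrna.call_dsr_dsg(
        diffsrna.nb_wald_test(mat, cond, "A", "B"), padj_threshold=1e-12)
    assert (called.call == "ns").all()
    fold = np.ones(200)
    fold[:20] = 8.0
    fold[20:40] = 1 / 8.0
    mat, cond = _nb_matrix(6, n=200, fold=fold)
    called = diffsrna.call_dsr_dsg(diffsrna.nb_wald_test(mat, cond, "A", "B"))
    hyper = set(called.index[called.call == "hyper"])
    hypo = set(called.index[called.call == "hypo"])
    assert hyper and hypo and not hyper & hypo


# ---------------------------------------------------------------- miRNA

def test_mirna_summary_df_and_closed_form_t():
    rng = np.random.default_rng(7)
    n = 10
    mat = pd.DataFrame(rng.integers(50, 500, size=(n, 4)),
                       columns=["w1", "w2", "m1", "m2"])
    cond = {"w1": "WT", "w2": "WT", "m1": "mut", "m2": "mut"}
    summary = diffsrna.mirna_fold_change_summary(mat, cond, "WT", "mut")
    assert summary.df == n - 1
    lfc = summary.per_mirna.log2fc.to_numpy()
    t_manual = lfc.mean() / (lfc.std(ddof=1) / np.sqrt(len(lfc)))
    assert summary.t_statistic == pytest.approx(t_manual)
    p_manual = 2 * stats.t.sf(abs(t_manual), df=len(lfc) - 1)
    assert summary.p_value == pytest.approx(p_manual)


def test_mirna_summary_symmetric_fold_changes_give_t_zero():
    # counts engineered so log2FCs come in +/- pairs
    base = np.array([100, 200, 400, 800])
    mat = pd.DataFrame({
        "w1": np.concatenate([base, base]),
        "w2": np.concatenate([base, base]),
        "m1": np.concatenate([2 * base, base // 2]),
        "m2": np.concatenate([2 * base, base // 2]),
    })
    cond = {"w1": "WT", "w2": "WT", "m1": "mut", "m2": "mut"}
    unit_factors = pd.Series(1.0, index=mat.columns)
    summary = diffsrna.mirna_fold_change_summary(mat, cond, "WT", "mut",
                                                 factors=unit_factors)
    assert abs(summary.t_statistic) < 0.2
    assert summary.p_value > 0.5


# ---------------------------------------------------------------- overlap

def brute_force_two_set_p(n1, n2, universe, observed):
    """Enumerate all placements of set B against a fixed A."""
    total = 0
    hits = 0
    a = set(range(n1))
    for b in combinations(range(universe), n2):
        total += 1
        if len(a & set(b)) >= observed:
            hits += 1
    return hits / total


@pytest.mark.parametrize("n1,n2,universe", [(4, 5, 10), (6, 6, 12), (3, 7, 9)])
def test_two_set_overlap_matches_enumeration(n1, n2, universe):
    a = set(range(n1))
    b = set(range(n1 - 2, n1 - 2 + n2))  # fixed overlap of 2 (clipped)
    b = {x % universe for x in b}
    res = diffsrna.multiset_overlap_test([a, b], universe)
    expected_p = brute_force_two_set_p(len(a), len(b), universe, res.observed)
    assert res.p == pytest.approx(expected_p, abs=1e-12)


def test_three_set_overlap_matches_enumeration():
    universe = 8
    a, b, c = {0, 1, 2, 3}, {1, 2, 3, 4}, {2, 3, 4, 5}
    res = diffsrna.multiset_overlap_test([a, b, c], universe)
    total = 0
    hits = 0
    for bb in combinations(range(universe), len(b)):
        for cc in combinations(range(universe), len(c)):
            total += 1
            if len(a & set(bb) & set(cc)) >= res.observed:
                hits += 1
    assert res.p == pytest.approx(hits / total, abs=1e-10)


def test_overlap_degenerate_and_expected():
    universe = 12
    full = set(range(12))
    b = set(range(5))
    res = diffsrna.multiset_overlap_test([full, b], universe)
    assert res.p == pytest.approx(1.0)
    half = set(range(6)), set(range(3, 9))
    res2 = diffsrna.multiset_overlap_test(list(half), universe)
    assert res2.expected == pytest.approx(12 / 4)
    with pytest.raises(ValueError, match="universe"):
        diffsrna.multiset_overlap_test([set(range(20)), b], universe)
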