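"""Differential sRNA analysis on bins and feature units.

The core test is a self-contained negative-binomial Wald test:

* library size factors by median-of-ratios against a geometric-mean
  pseudo-reference;
* per-unit dispersion by method of moments on normalized counts,
  ``alpha = max(0, (s^2 - m) / m^2)``, shrunk halfway toward a fitted
  mean-dispersion trend ``alpha(mu) = a0 + a1 / mu``;
* Wald z = log2FC / SE with the NB delta-method variance
  ``Var(log2 m_g) = (1/ln2^2) (1/(n_g m_g) + alpha/n_g)`` per condition;
* Benjamini-Hochberg adjustment within each (category x length) family.

Exact numerical parity with external count-model packages is not a goal;
the contract is distributional calibration (type-I error, recovery), which
the test suite checks by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = np.log(2.0)
PSEUDOCOUNT = 0.5


def size_factors(mat: pd.DataFrame, min_positive_units: int = 50) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Falls back to column-total ratios when fewer than
    ``min_positive_units`` units have all-positive counts.
    """
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 libraries for size factors")
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValueError(f"libraries with all-zero counts: {zero}")
    positive = mat[(mat > 0).all(axis=1)]
    if len(positive) >= min_positive_units:
        log_ref = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_ref, axis=0)
        factors = np.exp(ratios.median(axis=0))
    else:
        factors = totals.astype(float)
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def _dispersion_trend(mean: np.ndarray, alpha_raw: np.ndarray
                      ) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by least squares on positive raw estimates,
    with one outlier-trimming pass; coefficients clipped at zero."""
    ok = (mean > 0) & np.isfinite(alpha_raw) & (alpha_raw > 0)
    if ok.sum() < 10:
        med = float(np.median(alpha_raw[np.isfinite(alpha_raw)])) \
            if np.isfinite(alpha_raw).any() else 0.0
        return max(med, 0.0), 0.0
    for _ in range(2):
        x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
        coef, *_ = np.linalg.lstsq(x, alpha_raw[ok], rcond=None)
        a0, a1 = max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)
        fit = a0 + a1 / np.maximum(mean, 1e-9)
        keep = ok & (alpha_raw <= 10.0 * np.maximum(fit, 1e-4))
        if keep.sum() == ok.sum() or keep.sum() < 10:
            break
        ok = keep
    return a0, a1


def nb_wald_test(mat: pd.DataFrame, condition: pd.Series | dict,
                 reference: str, treatment: str | None = None,
                 factors: pd.Series | None = None,
                 fixed_dispersion: float | None = None,
                 family: pd.Series | None = None,
                 trend_shrinkage: float = 0.5) -> pd.DataFrame:
    """Per-unit NB Wald test of treatment vs reference.

    ``mat`` is units x libraries of raw weighted counts; ``condition`` maps
    library -> condition label. log2FC is treatment over reference with a
    0.5 pseudocount on normalized means. ``family`` (unit -> label) defines
    the BH adjustment families; default one family.
    """
    condition = pd.Series(condition)
    cond = condition.reindex(mat.columns)
    if cond.isna().any():
        raise ValueError("condition labels missing for some libraries")
    levels = [lvl for lvl in pd.unique(cond) if lvl != reference]
    if treatment is None:
        if len(levels) != 1:
            raise ValueError("treatment level is ambiguous; pass it explicitly")
        treatment = levels[0]
    use = cond.isin([reference, treatment])
    mat = mat.loc[:, use.to_numpy()]
    cond = cond[use]
    if factors is None:
        factors = size_factors(mat)
    norm = mat / factors.reindex(mat.columns)

    ref_cols = cond.index[cond == reference]
    trt_cols = cond.index[cond == treatment]
    n_ref, n_trt = len(ref_cols), len(trt_cols)
    if n_ref < 1 or n_trt < 1:
        raise ValueError("need >= 1 replicate per condition")
    m_ref = norm[ref_cols].mean(axis=1).to_numpy()
    m_trt = norm[trt_cols].mean(axis=1).to_numpy()
    m_all = norm.mean(axis=1).to_numpy()

    # method-of-moments dispersion from pooled within-condition variance
    df_total = max(n_ref - 1, 0) + max(n_trt - 1, 0)
    if df_total > 0:
        ss = np.zeros(len(mat))
        for cols, n in ((ref_cols, n_ref), (trt_cols, n_trt)):
            if n > 1:
                ss += norm[cols].var(axis=1, ddof=1).to_numpy() * (n - 1)
        s2 = ss / df_total
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_raw = np.where(m_all > 0, (s2 - m_all) / m_all ** 2, np.nan)
        alpha_raw = np.maximum(alpha_raw, 0.0)
    else:
        alpha_raw = np.full(len(mat), np.nan)

    if fixed_dispersion is not None:
        alpha = np.full(len(mat), float(fixed_dispersion))
    else:
        a0, a1 = _dispersion_trend(m_all, alpha_raw)
        trend = a0 + a1 / np.maximum(m_all, 1e-9)
        alpha = np.where(np.isfinite(alpha_raw),
                         (1 - trend_shrinkage) * alpha_raw
                         + trend_shrinkage * trend,
                         trend)

    log2fc = np.log2((m_trt + PSEUDOCOUNT) / (m_ref + PSEUDOCOUNT))
    se2 = (1.0 / LN2 ** 2) * (
        (1.0 / (n_ref * (m_ref + PSEUDOCOUNT)) + alpha / n_ref)
        + (1.0 / (n_trt * (m_trt + PSEUDOCOUNT)) + alpha / n_trt))
    se = np.sqrt(se2)
    z = log2fc / se
    pval = 2.0 * stats.norm.sf(np.abs(z))

    untestable = (m_ref == 0) & (m_trt == 0)
    log2fc[untestable] = 0.0
    z[untestable] = 0.0
    pval[untestable] = 1.0

    res = pd.DataFrame({
        "unit_id": mat.index,
        "base_mean_ref": m_ref,
        "base_mean_trt": m_trt,
        "log2fc": log2fc,
        "dispersion": alpha,
        "wald_z": z,
        "p": pval,
        "untestable": untestable,
    }).set_index("unit_id")
    fam = (family.reindex(res.index).fillna("all") if family is not None
           else pd.Series("all", index=res.index))
    res["family"] = fam
    # untestable (all-zero) units are excluded from the BH family size
    res["padj"] = 1.0
    testable = ~res.untestable
    for _, idx in res[testable].groupby("family").groups.items():
        res.loc[idx, "padj"] = bh_adjust(res.loc[idx, "p"].to_numpy())
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def call_dsr_dsg(results: pd.DataFrame, padj_threshold: float = 0.05,
                 lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Add hyper/hypo/ns calls: hyper iff padj < t and log2FC >= lfc."""
    call = np.where(
        (results.padj < padj_threshold) & (results.log2fc >= lfc_threshold),
        "hyper",
        np.where((results.padj < padj_threshold)
                 & (results.log2fc <= -lfc_threshold), "hypo", "ns"))
    out = results.copy()
    out["call"] = call
    return out


def dsr_tally(called: pd.DataFrame, categories: pd.Series | None = None
              ) -> pd.DataFrame:
    """Hyper/hypo counts, optionally per category."""
    out = called.copy()
    out["category"] = (out.index.map(categories).fillna("other")
                       if categories is not None else "all")
    tally = (out[out.call != "ns"]
             .groupby(["category", "call"]).size().rename("n").reset_index())
    return tally


@dataclass
class MirnaSummary:
    per_mirna: pd.DataFrame    # log2fc, p, padj, call per miRNA
    t_statistic: float
    df: int
    p_value: float
    n_up: int
    n_down: int


def mirna_fold_change_summary(mat: pd.DataFrame, condition: pd.Series | dict,
                              reference: str, treatment: str | None = None,
                              padj_threshold: float = 0.05,
                              lfc_threshold: float = 1.0,
                              factors: pd.Series | None = None
                              ) -> MirnaSummary:
    """Per-miRNA fold changes plus a one-sample t test of the log2FC vector.

    The t test asks whether the central tendency of miRNA fold changes
    differs from zero (global up/down shift); df = n_finite - 1.
    """
    res = call_dsr_dsg(
        nb_wald_test(mat, condition, reference, treatment, factors=factors),
        padj_threshold, lfc_threshold)
    lfc = res.loc[~res.untestable, "log2fc"].to_numpy()
    lfc = lfc[np.isfinite(lfc)]
    if len(lfc) < 2:
        raise ValueError("need >= 2 miRNAs with finite fold changes")
    t_res = stats.ttest_1samp(lfc, popmean=0.0)
    return MirnaSummary(
        per_mirna=res,
        t_statistic=float(t_res.statistic),
        df=len(lfc) - 1,
        p_value=float(t_res.pvalue),
        n_up=int((res.call == "hyper").sum()),
        n_down=int((res.call == "hypo").sum()),
    )


@dataclass
class OverlapTest:
    set_sizes: list[int]
    universe: int
    observed: int
    expected: float
    p: float


def multiset_overlap_test(sets: list[set], universe: int) -> OverlapTest:
    """Upper-tail significance of a k-set intersection.

    Null model: each set is an independent uniform draw of its size from
    the universe. The intersection-size distribution is built recursively:
    |A1 ∩ ... ∩ A_j| given |A1 ∩ ... ∩ A_{j-1}| = m is hypergeometric
    (universe, m, n_j); for two sets this is the classic hypergeometric
    test. p = P(X >= observed).
    """
    sizes = [len(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    if any(n > universe for n in sizes):
        raise ValueError("set larger than universe")
    inter = set.intersection(*sets)
    observed = len(inter)
    if observed > min(sizes):
        raise ValueError("intersection exceeds smallest set")
    expected = universe * float(np.prod([n / universe for n in sizes]))

    # dist_full[m] = P(|running intersection| = m)
    dist_full = np.zeros(universe + 1)
    dist_full[sizes[0]] = 1.0
    for n_j in sizes[1:]:
        new = np.zeros(universe + 1)
        for m in np.flatnonzero(dist_full > 0):
            x = np.arange(0, min(m, n_j) + 1)
            new[x] += dist_full[m] * stats.hypergeom.pmf(x, universe, m, n_j)
        dist_full = new
    p = float(dist_full[observed:].sum())
    p = min(max(p, 0.0), 1.0)
    return OverlapTest(sizes, universe, observed, expected, p)
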