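"""AGO-IP enrichment and miRNA loading-efficiency statistics.

IP-enriched units are those with a statistically significant increase in
sRNA abundance in the IP versus the matched input libraries (the NB Wald
test from :mod:`.diffsrna` with conditions {IP, input}, called in the
hyper direction only). Loading efficiency of a miRNA is its RPM in IP
divided by its RPM in input; genotypes are compared over the same miRNAs
with an exact paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import diffsrna

EXACT_N_MAX = 25


def ip_enrichment(mat: pd.DataFrame, fraction: pd.Series | dict,
                  padj_threshold: float = 0.05, lfc_threshold: float = 0.0,
                  categories: pd.Series | None = None,
                  fixed_dispersion: float | None = None) -> pd.DataFrame:
    """Per-unit IP-vs-input enrichment records.

    ``mat`` is units x libraries (one genotype); ``fraction`` maps
    library -> 'IP' or 'input'. Enriched = padj < threshold and
    log2 enrichment above ``lfc_threshold`` (> 0 by default: any
    significant increase).
    """
    res = diffsrna.nb_wald_test(mat, fraction, reference="input",
                                treatment="IP",
                                fixed_dispersion=fixed_dispersion)
    out = pd.DataFrame({
        "input_mean": res.base_mean_ref,
        "ip_mean": res.base_mean_trt,
        "log2_enrichment": res.log2fc,
        "p": res.p,
        "padj": res.padj,
    })
    out["enriched"] = (out.padj < padj_threshold) & \
        (out.log2_enrichment > lfc_threshold)
    if categories is not None:
        out["category"] = out.index.map(categories).fillna("other")
    return out


def enrichment_tally(records: pd.DataFrame) -> pd.Series:
    """Enriched-unit counts per category (each unit in exactly one)."""
    if "category" not in records:
        raise ValueError("records carry no category column")
    return records[records.enriched].groupby("category").size()


@dataclass
class LoadingTable:
    efficiencies: pd.DataFrame   # miRNA x genotype loading efficiency
    flagged: pd.DataFrame        # True where input RPM was zero (pseudocount)
    top_n: list[str]
    tests: pd.DataFrame          # genotype_a, genotype_b, statistic, p, method


def loading_efficiency(rpm_ip: pd.DataFrame, rpm_input: pd.DataFrame,
                       wt_genotype: str = "WT", top_n: int = 20,
                       pseudocount: float = 0.5) -> LoadingTable:
    """miRNA x genotype IP/input RPM ratios and paired genotype tests.

    ``rpm_ip`` / ``rpm_input`` are miRNA x genotype mean RPM tables. A zero
    input RPM is replaced by ``pseudocount`` RPM and flagged. The top-N
    membership is ranked by input abundance in the wild type, ties broken
    by miRNA name; the paired Wilcoxon tests run on the top-N only, as the
    low-abundance tail has unstable ratios.
    """
    rpm_ip, rpm_input = rpm_ip.align(rpm_input)
    flagged = rpm_input <= 0
    denom = rpm_input.where(~flagged, pseudocount)
    eff = rpm_ip / denom
    ranked = rpm_input[wt_genotype].sort_values(
        ascending=False, kind="stable")
    order = sorted(ranked.index, key=lambda m: (-ranked[m], str(m)))
    top = order[:top_n]
    tests = []
    for a, b in combinations(eff.columns, 2):
        stat, p, method = paired_wilcoxon(eff.loc[top, a].to_numpy(),
                                          eff.loc[top, b].to_numpy())
        tests.append((a, b, stat, p, method))
    return LoadingTable(
        efficiencies=eff,
        flagged=flagged,
        top_n=top,
        tests=pd.DataFrame(tests, columns=["genotype_a", "genotype_b",
                                           "statistic", "p", "method"]),
    )


def paired_wilcoxon(a: np.ndarray, b: np.ndarray
                    ) -> tuple[float, float, str]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties get average ranks. The null
    distribution of W+ is exact (dynamic programming over sign
    assignments) for n <= 25 non-zero pairs, otherwise a normal
    approximation with continuity and tie corrections. Returns
    (W+, p, method); identical vectors give p = 1 with method
    'degenerate'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need n >= 5 pairs")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, "degenerate"
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        return w_plus, p, "exact"
    mean = n * (n + 1) / 4.0
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - (tie_sizes ** 3 - tie_sizes).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_plus, p, "normal"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ given the (possibly tied) rank multiset.

    Ranks are doubled to integers (average ranks are half-integral) and
    the distribution of W+ over the 2^n equiprobable sign assignments is
    accumulated by convolution.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    lower = dist[:w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))
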