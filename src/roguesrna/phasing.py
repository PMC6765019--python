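"""Phased siRNA (phasiRNA) detection by register concentration.

phasiRNAs are diced head-to-tail from a double-stranded precursor, so
their 5' ends recur every ``phase`` (21) nucleotides in one register.
Minus-strand 5' ends are shifted by +2 before register assignment to
account for the 2-nt 3' overhang of the siRNA duplex, then both strands
are pooled.

The score over a sliding window of ``cycles`` (10) phase cycles, stepped
by one phase length, is the widely used form

    score = (k - 2) * ln(1 + 10 * P / (1 + U))   for k >= 3, else 0

where, for the window's dominant register, P is the phased read weight,
U the out-of-phase weight, and k the number of distinct cycles occupied
in that register.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_PHASE = 21
DEFAULT_CYCLES = 10
DEFAULT_THRESHOLD = 10.0
MINUS_SHIFT = 2   # 2-nt 3' overhang convention
MIN_CYCLES = 3


@dataclass
class PhasedRegion:
    chrom: str
    start: int
    end: int
    phase: int
    register: int
    k: int
    phased_weight: float
    unphased_weight: float
    score: float


def phase_assign(placements: pd.DataFrame, phase: int = DEFAULT_PHASE,
                 length: int | None = None) -> pd.DataFrame:
    """Pooled per-position 5'-end weight after the minus-strand +2 shift.

    ``length`` defaults to ``phase`` (21-nt reads exactly); pass e.g. 22
    for DCL2-product analysis. Returns chrom, pos, register, weight.
    """
    length = phase if length is None else length
    pl = placements[placements.length == length]
    if pl.empty:
        return pd.DataFrame(columns=["chrom", "pos", "register", "weight"])
    pos = pl.five_prime_pos + np.where(pl.strand == "-", MINUS_SHIFT, 0)
    tall = (pd.DataFrame({"chrom": pl.chrom, "pos": pos, "weight": pl.weight})
            .groupby(["chrom", "pos"], as_index=False)["weight"].sum())
    tall["register"] = tall.pos % phase
    return tall[["chrom", "pos", "register", "weight"]]


def phasing_score(k: int, phased: float, unphased: float) -> float:
    """Closed-form window score; 0 below the k >= 3 occupancy floor."""
    if k < MIN_CYCLES:
        return 0.0
    return float((k - 2) * np.log1p(10.0 * phased / (1.0 + unphased)))


def score_windows(tallies: pd.DataFrame, phase: int = DEFAULT_PHASE,
                  cycles: int = DEFAULT_CYCLES) -> pd.DataFrame:
    """Score all windows of ``cycles`` phase lengths, stepped by one phase.

    The dominant register of each window (max pooled weight, lowest
    register on ties) defines P, U and k.
    """
    span = phase * cycles
    rows = []
    for chrom, grp in tallies.groupby("chrom"):
        pos = grp.pos.to_numpy()
        w = grp.weight.to_numpy()
        reg = grp.register.to_numpy()
        if len(pos) == 0:
            continue
        first = (pos.min() // phase) * phase
        last = pos.max()
        for start in range(int(first), int(last) + 1, phase):
            sel = (pos >= start) & (pos < start + span)
            if not sel.any():
                continue
            regw = np.zeros(phase)
            np.add.at(regw, reg[sel], w[sel])
            r_star = int(np.argmax(regw))
            in_phase = sel & (reg == r_star)
            k = len(np.unique((pos[in_phase] - start) // phase))
            P = float(w[in_phase].sum())
            U = float(regw.sum() - P)
            rows.append((chrom, start, start + span, r_star, k, P, U,
                         phasing_score(k, P, U)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "register",
                                       "k", "P", "U", "score"])


def call_phased_regions(windows: pd.DataFrame,
                        threshold: float = DEFAULT_THRESHOLD,
                        phase: int = DEFAULT_PHASE) -> list[PhasedRegion]:
    """Merge overlapping windows with score >= threshold into regions.

    A region's score, register and tallies are those of its best window.
    """
    qual = windows[windows.score >= threshold].sort_values(["chrom", "start"])
    regions: list[PhasedRegion] = []
    for chrom, grp in qual.groupby("chrom", sort=True):
        current: list[pd.Series] = []
        for _, row in grp.iterrows():
            if current and row.start <= current[-1].end:
                current.append(row)
            else:
                if current:
                    regions.append(_merge(chrom, current, phase))
                current = [row]
        if current:
            regions.append(_merge(chrom, current, phase))
    return regions


def _merge(chrom: str, rows: list[pd.Series], phase: int) -> PhasedRegion:
    best = max(rows, key=lambda r: r.score)
    return PhasedRegion(
        chrom=chrom,
        start=int(min(r.start for r in rows)),
        end=int(max(r.end for r in rows)),
        phase=phase,
        register=int(best.register),
        k=int(best.k),
        phased_weight=float(best.P),
        unphased_weight=float(best.U),
        score=float(best.score),
    )


def regions_to_frame(regions: list[PhasedRegion]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in regions],
                        columns=["chrom", "start", "end", "phase", "register",
                                 "k", "phased_weight", "unphased_weight",
                                 "score"])
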