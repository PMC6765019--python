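"""Weighted 5'-end counting on genome bins and feature units.

All counting is keyed by the 5'-end coordinate of each placement: a read
contributes its placement weight to exactly one 100-bp bin (the one
containing its 5' end), and to every feature unit whose interval contains
the 5' end (gene bodies and the 1000-bp upstream region of a neighbouring
gene may both receive it, which is documented behaviour). Normalisation is
reads-per-million mapped (RPM) against the per-library weighted placement
total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io

LENGTH_RANGE = range(18, 43)
DEFAULT_PRECEDENCE = ("miRNA", "TAS", "rRNA", "gene", "TE", "other")

#: annotation feature_class -> reporting category
CLASS_TO_CATEGORY = {
    "miRNA": "miRNA",
    "TAS": "TAS",
    "rRNA_mature": "rRNA",
    "rRNA_spacer": "rRNA",
    "gene": "gene",
    "TE": "TE",
}


@dataclass
class BinMatrix:
    """Long-format weighted count tensor over (unit, library, length, strand)."""

    units: pd.DataFrame    # unit_id, chrom, start, end, kind [, category]
    counts: pd.DataFrame   # unit_id, library_id, length, strand, count
    mapped_totals: dict[str, float] = field(default_factory=dict)

    def library_ids(self) -> list[str]:
        return sorted(self.mapped_totals)

    def total_counts(self, library_id: str) -> float:
        sub = self.counts[self.counts.library_id == library_id]
        return float(sub["count"].sum())

    def matrix(self, lengths: list[int] | None = None,
               value: str = "count") -> pd.DataFrame:
        """Pivot to a unit x library matrix, optionally restricted by length."""
        sub = self.counts
        if lengths is not None:
            sub = sub[sub.length.isin(lengths)]
        mat = (sub.groupby(["unit_id", "library_id"])[value].sum()
               .unstack(fill_value=0.0))
        mat = mat.reindex(index=self.units.unit_id,
                          columns=self.library_ids(), fill_value=0.0)
        return mat

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.units.to_csv(path.with_suffix(".units.tsv"), sep="\t", index=False)
        self.counts.to_csv(path.with_suffix(".counts.tsv"), sep="\t", index=False)
        io.dump_json(self.mapped_totals, path.with_suffix(".totals.json"))

    @classmethod
    def load(cls, path: str | Path) -> "BinMatrix":
        path = Path(path)
        return cls(
            units=pd.read_csv(path.with_suffix(".units.tsv"), sep="\t"),
            counts=pd.read_csv(path.with_suffix(".counts.tsv"), sep="\t"),
            mapped_totals=io.load_json(path.with_suffix(".totals.json")),
        )


def make_bins(chrom_lengths: dict[str, int], bin_size: int = 100) -> pd.DataFrame:
    """Tile every chromosome with fixed-width bins; the last bin is truncated."""
    if bin_size < 10:
        raise ValueError("bin size must be >= 10")
    rows = []
    for chrom, n in chrom_lengths.items():
        starts = np.arange(0, n, bin_size)
        for s in starts:
            e = min(s + bin_size, n)
            rows.append((f"{chrom}:{s}-{e}", chrom, int(s), int(e), "bin"))
    return pd.DataFrame(rows, columns=["unit_id", "chrom", "start", "end", "kind"])


def count_bins(placements: pd.DataFrame, chrom_lengths: dict[str, int],
               bin_size: int = 100) -> BinMatrix:
    """Bin-level weighted 5'-end counts.

    ``placements`` needs columns library_id, chrom, five_prime_pos, strand,
    length, weight. Each placement lands in exactly one bin.
    """
    units = make_bins(chrom_lengths, bin_size)
    pl = placements.copy()
    for chrom, grp in pl.groupby("chrom"):
        if chrom not in chrom_lengths:
            raise ValueError(f"placement on unknown chromosome {chrom!r}")
        bad = (grp.five_prime_pos < 0) | (grp.five_prime_pos >= chrom_lengths[chrom])
        if bad.any():
            raise ValueError(f"5' position outside {chrom}: corrupt input")
    bin_start = (pl.five_prime_pos // bin_size) * bin_size
    bin_end = np.minimum(bin_start + bin_size,
                         pl.chrom.map(chrom_lengths).to_numpy())
    pl["unit_id"] = (pl.chrom.astype(str) + ":" + bin_start.astype(str)
                     + "-" + pd.Series(bin_end, index=pl.index).astype(str))
    counts = (pl.groupby(["unit_id", "library_id", "length", "strand"],
                         observed=True)["weight"].sum()
              .rename("count").reset_index())
    totals = pl.groupby("library_id")["weight"].sum().to_dict()
    return BinMatrix(units=units, counts=counts, mapped_totals=totals)


def feature_units(annotation: pd.DataFrame, include_upstream: int = 1000,
                  chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Feature-level units: every annotated feature plus gene upstream regions."""
    rows = []
    for f in annotation.itertuples(index=False):
        rows.append((f.feature_id, f.chrom, f.start, f.end, f.feature_class))
        if f.feature_class == "gene" and include_upstream:
            if f.strand == "+":
                s, e = max(0, f.start - include_upstream), f.start
            else:
                s, e = f.end, f.end + include_upstream
                if chrom_lengths:
                    e = min(e, chrom_lengths[f.chrom])
            if e > s:
                rows.append((f"{f.feature_id}_upstream", f.chrom, s, e, "upstream"))
    return pd.DataFrame(rows, columns=["unit_id", "chrom", "start", "end", "kind"])


def count_features(placements: pd.DataFrame, annotation: pd.DataFrame,
                   include_upstream: int = 1000,
                   chrom_lengths: dict[str, int] | None = None) -> BinMatrix:
    """Feature-unit weighted counts; a read may hit several overlapping units."""
    units = feature_units(annotation, include_upstream, chrom_lengths)
    trees: dict[str, IntervalTree] = {}
    for u in units.itertuples(index=False):
        trees.setdefault(u.chrom, IntervalTree()).addi(u.start, u.end, u.unit_id)

    pl = placements
    uniq = pl[["chrom", "five_prime_pos"]].drop_duplicates()
    pos_units = []
    for chrom, pos in uniq.itertuples(index=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos):
            pos_units.append((chrom, pos, iv.data))
    pos_units = pd.DataFrame(pos_units,
                             columns=["chrom", "five_prime_pos", "unit_id"])
    merged = pl.merge(pos_units, on=["chrom", "five_prime_pos"], how="inner")
    counts = (merged.groupby(["unit_id", "library_id", "length", "strand"],
                             observed=True)["weight"].sum()
              .rename("count").reset_index())
    totals = pl.groupby("library_id")["weight"].sum().to_dict()
    return BinMatrix(units=units, counts=counts, mapped_totals=totals)


def rpm(bm: BinMatrix) -> pd.DataFrame:
    """Counts with an added RPM column (reads per million mapped)."""
    for lib, total in bm.mapped_totals.items():
        if total <= 0:
            raise ValueError(f"library {lib} has zero mapped reads")
    out = bm.counts.copy()
    out["rpm"] = out["count"] * 1e6 / out.library_id.map(bm.mapped_totals)
    return out


def length_profile(bm: BinMatrix) -> pd.DataFrame:
    """Percentage of mapped reads per insert length (18-42) per library."""
    per = (bm.counts.groupby(["library_id", "length"])["count"].sum()
           .unstack(fill_value=0.0)
           .reindex(columns=list(LENGTH_RANGE), fill_value=0.0))
    return per.div(per.sum(axis=1), axis=0) * 100.0


def classify_units(units: pd.DataFrame, annotation: pd.DataFrame,
                   precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                   min_overlap_frac: float = 0.5) -> pd.Series:
    """Category per unit: highest-precedence category covering >= 50% of it.

    Overlap is summed per category before thresholding, so a bin spanning
    two contiguous rRNA subfeatures is still fully rRNA. Units reaching the
    threshold for no category are 'other'.
    """
    unknown = set(annotation.feature_class) - set(CLASS_TO_CATEGORY)
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
    rank = {cat: i for i, cat in enumerate(precedence)}
    trees: dict[str, IntervalTree] = {}
    for f in annotation.itertuples(index=False):
        trees.setdefault(f.chrom, IntervalTree()).addi(
            f.start, f.end, CLASS_TO_CATEGORY[f.feature_class])
    out = []
    for u in units.itertuples(index=False):
        tree = trees.get(u.chrom)
        size = u.end - u.start
        cover: dict[str, int] = {}
        if tree is not None:
            for iv in tree.overlap(u.start, u.end):
                ov = min(iv.end, u.end) - max(iv.begin, u.start)
                cover[iv.data] = cover.get(iv.data, 0) + ov
        eligible = [c for c, ov in cover.items()
                    if ov >= min_overlap_frac * size and c in rank]
        out.append(min(eligible, key=rank.get) if eligible else "other")
    return pd.Series(out, index=units.unit_id, name="category")


def class_profile(bm: BinMatrix, categories: pd.Series, length: int,
                  value: str = "rpm") -> pd.DataFrame:
    """Cumulative RPM per category for one read length, per library."""
    vals = rpm(bm) if value == "rpm" else bm.counts.assign(rpm=bm.counts["count"])
    vals = vals[vals.length == length]
    vals = vals.assign(category=vals.unit_id.map(categories).fillna("other"))
    return (vals.groupby(["library_id", "category"])["rpm"].sum()
            .unstack(fill_value=0.0))


def five_prime_composition(placements: pd.DataFrame,
                           length: int | None = None,
                           strand: str | None = None,
                           unit_filter: pd.Index | None = None,
                           categories: pd.Series | None = None,
                           bin_size: int = 100) -> pd.Series:
    """Weight-weighted fractions of A/C/G/U at insert position 1.

    ``unit_filter`` restricts to placements whose 5'-end bin (of
    ``bin_size``) is in the given unit_id index; requires ``categories``-style
    bin ids (chrom:start-end).
    """
    pl = placements
    if length is not None:
        pl = pl[pl.length == length]
    if strand is not None:
        pl = pl[pl.strand == strand]
    if unit_filter is not None:
        bin_start = (pl.five_prime_pos // bin_size) * bin_size
        ids = (pl.chrom.astype(str) + ":" + bin_start.astype(str) + "-"
               + (bin_start + bin_size).astype(str))
        pl = pl[ids.isin(unit_filter)]
    if pl.empty:
        return pd.Series(0.0, index=list("ACGU"))
    first = pl.sequence.str[0].replace("T", "U")
    frac = pl.groupby(first)["weight"].sum()
    frac = frac.reindex(list("ACGU"), fill_value=0.0)
    return frac / frac.sum()


def export_tracks(placements: pd.DataFrame, mapped_total: float,
                  out_prefix: str | Path, length: int | None = None
                  ) -> tuple[Path, Path]:
    """Per-position 5'-end RPM bedGraph pair; minus-strand values negative."""
    if mapped_total <= 0:
        raise ValueError("mapped total must be positive")
    pl = placements
    if length is not None:
        pl = pl[pl.length == length]
    out_prefix = Path(out_prefix)
    paths = []
    for strand, sign, suffix in (("+", 1.0, "plus"), ("-", -1.0, "minus")):
        sub = pl[pl.strand == strand]
        per_pos = (sub.groupby(["chrom", "five_prime_pos"])["weight"].sum()
                   * 1e6 / mapped_total * sign).reset_index()
        track = pd.DataFrame({
            "chrom": per_pos.chrom,
            "start": per_pos.five_prime_pos,
            "end": per_pos.five_prime_pos + 1,
            "value": per_pos.weight,
        })
        path = out_prefix.parent / f"{out_prefix.name}.{suffix}.bedgraph"
        io.write_bedgraph(track, path)
        paths.append(path)
    return paths[0], paths[1]
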