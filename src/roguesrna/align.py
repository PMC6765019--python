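"""Exact-match read placement with configurable multimapper handling.

Reads are placed by looking up an anchor k-mer (k = 18, the minimum insert
length) in a genome-wide hash index and verifying the full insert; both
strands are searched. Three placement modes are supported:

* ``unique``     - only single-hit reads are placed, weight 1;
* ``fractional`` - each of a read's n placements gets weight 1/n;
* ``guided``     - each placement's weight is proportional to 1 + U_c,
  where U_c is the uniquely-placed read weight whose 5' ends fall within
  a +/- 100-nt window of the candidate 5' end. This is a deterministic
  stand-in for density-guided multimapper assignment; the original tools
  break remaining ties randomly, which we deliberately do not.

Coordinates are 0-based half-open. The 5' end of a minus-strand placement
is the rightmost genomic coordinate of its span.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SizedRead
from .synthio import revcomp

ANCHOR_K = 18
GUIDED_WINDOW = 100


@dataclass
class Placement:
    read_id: str
    chrom: str
    five_prime_pos: int
    strand: str
    length: int
    n_hits: int
    weight: float
    sequence: str = ""

    @property
    def start(self) -> int:
        """Leftmost coordinate of the matched interval."""
        return (self.five_prime_pos if self.strand == "+"
                else self.five_prime_pos - self.length + 1)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class AlignmentStats:
    total: int = 0
    placed: int = 0
    unplaced: int = 0
    suppressed: int = 0
    unique: int = 0
    multi: int = 0

    def check(self) -> None:
        assert self.placed + self.unplaced + self.suppressed == self.total

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class GenomeIndex:
    """Hash index of all plus-strand anchor k-mers of the genome."""

    def __init__(self, seqs: dict[str, str], k: int = ANCHOR_K):
        self.k = k
        self.seqs = {c: s.upper() for c, s in seqs.items()}
        for chrom, s in self.seqs.items():
            bad = set(s) - set("ACGT")
            if bad:
                raise ValueError(f"non-ACGT characters in {chrom}: {sorted(bad)}")
        self._anchors: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, s in self.seqs.items():
            for i in range(len(s) - k + 1):
                self._anchors[s[i:i + k]].append((chrom, i))

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = ANCHOR_K) -> "GenomeIndex":
        from . import io
        return cls(io.read_fasta(path), k)

    def lookup(self, query: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``query`` as (chrom, five_prime_pos, strand).

        Reverse-complement occurrences are reported on the minus strand with
        the 5' position at the rightmost coordinate of the genomic match.
        """
        query = query.upper()
        if len(query) < self.k:
            raise ValueError(f"query shorter than anchor k={self.k}")
        hits: list[tuple[str, int, str]] = []
        for chrom, pos in self._anchors.get(query[:self.k], ()):
            if self.seqs[chrom][pos:pos + len(query)] == query:
                hits.append((chrom, pos, "+"))
        rc = revcomp(query)
        for chrom, pos in self._anchors.get(rc[:self.k], ()):
            if self.seqs[chrom][pos:pos + len(rc)] == rc:
                hits.append((chrom, pos + len(query) - 1, "-"))
        return sorted(hits)


def five_prime_position(match_start: int, match_end: int, strand: str) -> int:
    """5' end of a match on [start, end): leftmost on +, rightmost on -."""
    return match_start if strand == "+" else match_end - 1


def place_reads(reads: list[SizedRead], index: GenomeIndex,
                mode: str = "guided", max_hits: int = 1000,
                mismatches: int = 0, guided_window: int = GUIDED_WINDOW
                ) -> tuple[list[Placement], AlignmentStats]:
    """Place size-selected reads on the genome; see module docstring for modes."""
    if mismatches != 0:
        raise ValueError("only exact matching (mismatches=0) is supported")
    if mode not in ("unique", "fractional", "guided"):
        raise ValueError(f"unknown placement mode {mode!r}")
    stats = AlignmentStats(total=len(reads))

    hit_cache: dict[str, list[tuple[str, int, str]]] = {}
    read_hits: list[list[tuple[str, int, str]] | None] = []
    for r in reads:
        hits = hit_cache.get(r.sequence)
        if hits is None:
            hits = index.lookup(r.sequence)
            hit_cache[r.sequence] = hits
        read_hits.append(hits)

    # First pass: classify and collect unique 5' ends for guided weighting.
    unique_pos: dict[str, list[int]] = defaultdict(list)
    for r, hits in zip(reads, read_hits):
        if not hits:
            stats.unplaced += 1
        elif len(hits) > max_hits:
            stats.suppressed += 1
        elif len(hits) == 1:
            stats.placed += 1
            stats.unique += 1
            unique_pos[hits[0][0]].append(hits[0][1])
        else:
            stats.placed += 1
            stats.multi += 1
    for chrom in unique_pos:
        unique_pos[chrom].sort()

    def unique_density(chrom: str, pos: int) -> int:
        positions = unique_pos.get(chrom)
        if not positions:
            return 0
        lo = bisect.bisect_left(positions, pos - guided_window)
        hi = bisect.bisect_right(positions, pos + guided_window)
        return hi - lo

    placements: list[Placement] = []
    for r, hits in zip(reads, read_hits):
        if not hits or len(hits) > max_hits:
            continue
        n = len(hits)
        if n == 1:
            weights = [1.0]
        elif mode == "unique":
            continue
        elif mode == "fractional":
            weights = [1.0 / n] * n
        else:  # guided
            raw = np.array([1.0 + unique_density(c, p) for c, p, _ in hits])
            weights = (raw / raw.sum()).tolist()
        for (chrom, pos, strand), w in zip(hits, weights):
            placements.append(Placement(r.read_id, chrom, pos, strand,
                                        len(r.sequence), n, w, r.sequence))
    if mode == "unique":
        # multi-hit reads were classified as placed in pass 1 but carry no
        # placements in this mode; keep the stats partition honest.
        stats.placed -= stats.multi
        stats.unplaced += stats.multi
    stats.check()
    return placements, stats


def placements_to_frame(placements: list[Placement]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.read_id, p.chrom, p.five_prime_pos, p.strand, p.length,
          p.n_hits, p.weight, p.sequence) for p in placements],
        columns=["read_id", "chrom", "five_prime_pos", "strand", "length",
                 "n_hits", "weight", "sequence"],
    )


def write_placements_tsv(placements: list[Placement], path: str | Path) -> None:
    placements_to_frame(placements).to_csv(path, sep="\t", index=False)


def read_placements_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"chrom": str, "strand": str, "sequence": str})


def write_sam(placements: list[Placement], chrom_lengths: dict[str, int],
              path: str | Path) -> None:
    """Export placements as SAM; the placement weight goes in the XW:f tag."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, ln in chrom_lengths.items():
            out.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for p in placements:
            flag = 16 if p.strand == "-" else 0
            seq = p.sequence if p.strand == "+" else revcomp(p.sequence)
            out.write(
                f"{p.read_id}\t{flag}\t{p.chrom}\t{p.start + 1}\t255\t"
                f"{p.length}M\t*\t0\t0\t{seq or '*'}\t*\t"
                f"NH:i:{p.n_hits}\tXW:f:{p.weight:.6g}\n"
            )


def read_sam(path: str | Path) -> list[Placement]:
    """Import placements from SAM (ours or external, exact-match alignments)."""
    import pysam

    placements: list[Placement] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            start, end = rec.reference_start, rec.reference_end
            length = end - start
            n_hits = rec.get_tag("NH") if rec.has_tag("NH") else 1
            weight = (float(rec.get_tag("XW")) if rec.has_tag("XW")
                      else 1.0 / n_hits)
            seq = rec.query_sequence or ""
            if strand == "-":
                seq = revcomp(seq)
            placements.append(Placement(
                rec.query_name, rec.reference_name,
                five_prime_position(start, end, strand), strand,
                length, int(n_hits), weight, seq))
    return placements
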