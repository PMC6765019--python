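"""File-format helpers: FASTA, FASTQ, GFF3, manifests, bedGraph.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and bedGraph (0-based half-open) are converted at these boundaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) triples."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), qual


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> int:
    """Write (read_id, sequence) pairs with a constant Phred+33 quality."""
    n = 0
    with open(path, "w") as out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (0-based half-open `start`/`end`) as GFF3.

    Expects columns: chrom, start, end, strand, feature_id, feature_class.
    """
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            attrs = f"ID={row.feature_id};feature_class={row.feature_class}"
            out.write(
                f"{row.chrom}\t.\t{row.feature_class}\t{row.start + 1}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into the internal feature table (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "start": int, "end": int},
    )
    attrs = df["attributes"].map(_parse_gff_attributes)
    out = pd.DataFrame({
        "chrom": df["seqid"],
        "start": df["start"] - 1,
        "end": df["end"],
        "strand": df["strand"],
        "feature_id": [a.get("ID", f"feat{i}") for i, a in enumerate(attrs)],
        "feature_class": [a.get("feature_class", t) for a, t in zip(attrs, df["type"])],
    })
    return out


def _parse_gff_attributes(field: str) -> dict[str, str]:
    pairs = (item.split("=", 1) for item in field.strip().split(";") if "=" in item)
    return {k: v for k, v in pairs}


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "genotype": str})
    required = {"library_id", "genotype", "replicate", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_bedgraph(values: pd.DataFrame, path: str | Path) -> None:
    """Write per-position values as bedGraph (columns chrom, start, end, value)."""
    values.to_csv(path, sep="\t", index=False, header=False,
                  float_format="%.6g")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
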