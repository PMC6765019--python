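#!/usr/bin/env python
"""Trim adapters, place reads, and build the bin/feature count matrices.

Reads every library from results/analysis/sim/, writes placements,
bin-level and feature-level count matrices, per-library length profiles,
the 21-nt genomic class profile, and strand-resolved rDNA coverage
tracks under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from roguesrna import align, io, preprocess, quantify

SIM = Path("results/analysis/sim")
OUT = Path("results/analysis")


def main() -> None:
    seqs = io.read_fasta(SIM / "genome.fa")
    annotation = io.read_gff3(SIM / "annotation.gff3")
    manifest = io.read_manifest(SIM / "manifest.tsv")
    index = align.GenomeIndex(seqs)
    chrom_lengths = {c: len(s) for c, s in seqs.items()}

    frames = []
    for lib in manifest.library_id:
        reads, rep = preprocess.trim_library(SIM / f"{lib}.fastq")
        placements, stats = align.place_reads(reads, index, mode="guided")
        frame = align.placements_to_frame(placements)
        frame["library_id"] = lib
        frames.append(frame)
        print(f"{lib}: {rep.retained}/{rep.input} retained, "
              f"{stats.placed} placed ({stats.multi} multimapping)")
    placements = pd.concat(frames, ignore_index=True)
    placements.to_csv(OUT / "placements.tsv", sep="\t", index=False)

    bins = quantify.count_bins(placements, chrom_lengths)
    feats = quantify.count_features(placements, annotation, 1000,
                                    chrom_lengths)
    bins.save(OUT / "bins")
    feats.save(OUT / "features")

    profiles = quantify.length_profile(bins)
    profiles.to_csv(OUT / "length_profiles.tsv", sep="\t")
    geno = manifest.set_index("library_id")
    for g in geno.genotype.unique():
        libs = geno[(geno.genotype == g) & (geno.fraction == "total")].index
        p = profiles.loc[libs].mean()
        print(f"{g}: 21-nt {p[21]:.1f}%  24-nt {p[24]:.1f}%")

    cats = quantify.classify_units(bins.units, annotation)
    class21 = quantify.class_profile(bins, cats, length=21)
    class21.to_csv(OUT / "class_profile_21nt.tsv", sep="\t")

    # strand-resolved rDNA 21-nt coverage, one track pair per genotype
    for g in geno.genotype.unique():
        libs = geno[(geno.genotype == g) & (geno.fraction == "total")].index
        sub = placements[placements.library_id.isin(libs)
                         & (placements.chrom == "rDNA")]
        total = placements[placements.library_id.isin(libs)].weight.sum()
        quantify.export_tracks(sub, total, OUT / f"rdna_21nt_{g}", length=21)
    print(f"wrote matrices, profiles and rDNA tracks to {OUT}")


if __name__ == "__main__":
    main()
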