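#!/usr/bin/env python
"""Differential sRNA analysis: DSRs on 100-bp bins, DSGs on genes,
the global miRNA fold-change t test, and the overlap of hyper-DSG sets
between the two mutant genotypes (multi-set hypergeometric test).

Reads results/analysis/{bins,features,sim}; writes per-unit tables and
a summary under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from roguesrna import diffsrna, io, quantify

OUT = Path("results/analysis")
LENGTHS = (21, 24)
WT = "WT"


def main() -> None:
    bins = quantify.BinMatrix.load(OUT / "bins")
    feats = quantify.BinMatrix.load(OUT / "features")
    annotation = io.read_gff3(OUT / "sim" / "annotation.gff3")
    manifest = io.read_manifest(OUT / "sim" / "manifest.tsv")
    geno = manifest.set_index("library_id")
    total_libs = geno[geno.fraction == "total"].index.tolist()
    cats = quantify.classify_units(bins.units, annotation)
    gene_units = feats.units.query("kind == 'gene'").unit_id
    mutants = [g for g in geno.genotype.unique() if g != WT]

    hyper_sets: dict[str, set] = {}
    summary = {}
    for L in LENGTHS:
        bmat = bins.matrix(lengths=[L])[total_libs]
        fmat = feats.matrix(lengths=[L]).loc[gene_units, total_libs]
        factors = diffsrna.size_factors(bmat)
        for mut in mutants:
            libs = [l for l in total_libs
                    if geno.loc[l, "genotype"] in (WT, mut)]
            cond = {l: geno.loc[l, "genotype"] for l in libs}
            dsr = diffsrna.call_dsr_dsg(diffsrna.nb_wald_test(
                bmat[libs], cond, WT, mut, factors[libs], None, cats))
            dsg = diffsrna.call_dsr_dsg(diffsrna.nb_wald_test(
                fmat[libs], cond, WT, mut, factors[libs]))
            dsr.to_csv(OUT / f"dsr_{mut}_{L}nt.tsv", sep="\t")
            dsg.to_csv(OUT / f"dsg_{mut}_{L}nt.tsv", sep="\t")
            tally = diffsrna.dsr_tally(dsr, cats)
            summary[f"dsr_{mut}_{L}nt"] = {
                f"{r.category}:{r.call}": int(r.n)
                for r in tally.itertuples(index=False)}
            n_hyper = int((dsg.call == "hyper").sum())
            n_hypo = int((dsg.call == "hypo").sum())
            summary[f"dsg_{mut}_{L}nt"] = {"hyper": n_hyper, "hypo": n_hypo}
            print(f"{mut} {L}-nt: "
                  f"{int((dsr.call == 'hyper').sum())} hyper / "
                  f"{int((dsr.call == 'hypo').sum())} hypo DSRs; "
                  f"{n_hyper} hyper / {n_hypo} hypo DSGs")
            if L == 21:
                hyper_sets[mut] = set(dsg.index[dsg.call == "hyper"])

    # miRNA panel: global downregulation t test per mutant
    mir_units = feats.units.query("kind == 'miRNA'").unit_id
    mir_mat = feats.matrix(lengths=[21]).loc[mir_units, total_libs]
    for mut in mutants:
        libs = [l for l in total_libs if geno.loc[l, "genotype"] in (WT, mut)]
        cond = {l: geno.loc[l, "genotype"] for l in libs}
        factors = diffsrna.size_factors(bins.matrix(lengths=[21])[libs])
        ms = diffsrna.mirna_fold_change_summary(mir_mat[libs], cond, WT, mut,
                                                factors=factors)
        summary[f"mirna_t_{mut}"] = {
            "t": round(ms.t_statistic, 4), "df": ms.df,
            "p": float(ms.p_value), "down": ms.n_down, "up": ms.n_up}
        print(f"{mut}: miRNA log2FC t={ms.t_statistic:.3f} (df={ms.df}, "
              f"p={ms.p_value:.3g}); {ms.n_down} down / {ms.n_up} up")

    # do the two mutant genotypes silence the same genes?
    if len(hyper_sets) == 2:
        universe = len(gene_units)
        (m1, s1), (m2, s2) = hyper_sets.items()
        ov = diffsrna.multiset_overlap_test([s1, s2], universe)
        summary["hyper_dsg_overlap"] = {
            "sets": {m1: len(s1), m2: len(s2)},
            "observed": ov.observed, "expected": round(ov.expected, 3),
            "p": float(ov.p)}
        print(f"hyper-DSG overlap {m1} vs {m2}: {ov.observed} observed, "
              f"{ov.expected:.2f} expected, p={ov.p:.3g}")
    io.dump_json(summary, OUT / "differential_summary.json")


if __name__ == "__main__":
    main()
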