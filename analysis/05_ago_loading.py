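#!/usr/bin/env python
"""AGO-IP analysis: IP-vs-input enriched 21-nt bins per genotype, the
genomic class profile of AGO-associated 21-nt sRNAs, and the miRNA
loading-efficiency table with paired Wilcoxon tests between genotypes.

Reads results/analysis/{bins,features,placements.tsv,sim}; writes
enrichment and loading tables under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from roguesrna import agoload, io, quantify

OUT = Path("results/analysis")
TOP_N = 20


def main() -> None:
    bins = quantify.BinMatrix.load(OUT / "bins")
    feats = quantify.BinMatrix.load(OUT / "features")
    annotation = io.read_gff3(OUT / "sim" / "annotation.gff3")
    manifest = io.read_manifest(OUT / "sim" / "manifest.tsv")
    geno = manifest.set_index("library_id")
    cats = quantify.classify_units(bins.units, annotation)
    genotypes = list(geno.genotype.unique())

    for g in genotypes:
        libs_ip = geno[(geno.fraction == "IP") & (geno.genotype == g)].index
        libs_in = geno[(geno.fraction == "total") & (geno.genotype == g)].index
        mat = bins.matrix(lengths=[21])[list(libs_ip) + list(libs_in)]
        frac = {l: ("IP" if l in set(libs_ip) else "input")
                for l in mat.columns}
        rec = agoload.ip_enrichment(mat, frac, categories=cats)
        rec.to_csv(OUT / f"ip_enrichment_{g}_21nt.tsv", sep="\t")
        tally = agoload.enrichment_tally(rec)
        print(f"{g}: {int(rec.enriched.sum())} enriched 21-nt bins "
              f"{dict(tally)}")

    # miRNA loading efficiency over genotypes
    mir_units = feats.units.query("kind == 'miRNA'").unit_id
    rpm_tbl = quantify.rpm(feats)
    rpm_tbl = rpm_tbl[rpm_tbl.unit_id.isin(mir_units)]
    per_lib = (rpm_tbl.groupby(["unit_id", "library_id"])["rpm"].sum()
               .unstack(fill_value=0.0))
    rpm_ip = pd.DataFrame({
        g: per_lib[geno[(geno.fraction == "IP")
                        & (geno.genotype == g)].index].mean(axis=1)
        for g in genotypes})
    rpm_in = pd.DataFrame({
        g: per_lib[geno[(geno.fraction == "total")
                        & (geno.genotype == g)].index].mean(axis=1)
        for g in genotypes})
    table = agoload.loading_efficiency(rpm_ip, rpm_in, "WT", TOP_N)
    table.efficiencies.to_csv(OUT / "loading_efficiency.tsv", sep="\t")
    table.tests.to_csv(OUT / "loading_tests.tsv", sep="\t", index=False)
    med = table.efficiencies.loc[table.top_n].median()
    print("median loading efficiency (top miRNAs by WT input):")
    print(med.round(3).to_string())
    for row in table.tests.itertuples(index=False):
        print(f"paired Wilcoxon {row.genotype_a} vs {row.genotype_b}: "
              f"W+={row.statistic:.0f}, p={row.p:.4g} ({row.method})")


if __name__ == "__main__":
    main()
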