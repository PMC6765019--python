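"""Bin/feature counting, RPM, classification, composition, tracks."""

import numpy as np
import pandas as pd
import pytest

from roguesrna import io, quantify


def _placements(rows):
    return pd.DataFrame(rows, columns=["library_id", "chrom", "five_prime_pos",
                                       "strand", "length", "weight",
                                       "sequence"])


@pytest.fixture()
def tiny_placements():
    return _placements([
        ("L1", "c1", 0, "+", 21, 1.0, "T" * 21),
        ("L1", "c1", 100, "+", 21, 1.0, "A" * 21),
        ("L1", "c1", 150, "-", 24, 0.5, "C" * 24),
        ("L1", "c1", 350, "-", 24, 0.5, "C" * 24),
    ])


def test_bin_boundaries_are_half_open(tiny_placements):
    bm = quantify.count_bins(tiny_placements, {"c1": 400})
    by_bin = bm.counts.groupby("unit_id")["count"].sum()
    assert by_bin["c1:0-100"] == 1.0       # 5' end at 0
    assert by_bin["c1:100-200"] == 1.5     # 5' end at exactly 100 rolls over
    assert by_bin["c1:300-400"] == 0.5


def test_bin_counts_conserve_weight(study_placements, toy_genome):
    bm = quantify.count_bins(study_placements, toy_genome.chrom_lengths())
    assert bm.counts["count"].sum() == pytest.approx(
        study_placements.weight.sum(), rel=1e-9)
    for lib, total in bm.mapped_totals.items():
        assert bm.total_counts(lib) == pytest.approx(total, rel=1e-6)


def test_bins_tile_without_gaps():
    units = quantify.make_bins({"c1": 250}, 100)
    assert list(units.start) == [0, 100, 200]
    assert list(units.end) == [100, 200, 250]   # last bin truncated


def test_out_of_range_position_is_an_error(tiny_placements):
    with pytest.raises(ValueError, match="outside"):
        quantify.count_bins(tiny_placements, {"c1": 300})


def test_feature_counting_body_and_upstream():
    ann = pd.DataFrame([
        ("c1", 2000, 3000, "+", "G1", "gene"),
    ], columns=["chrom", "start", "end", "strand", "feature_id",
                "feature_class"])
    pl = _placements([
        ("L1", "c1", 2500, "+", 21, 1.0, "A" * 21),   # body
        ("L1", "c1", 1500, "+", 21, 1.0, "A" * 21),   # 500 bp upstream of TSS
        ("L1", "c1", 3500, "+", 21, 1.0, "A" * 21),   # downstream: nothing
    ])
    bm = quantify.count_features(pl, ann, include_upstream=1000,
                                 chrom_lengths={"c1": 5000})
    per_unit = bm.counts.groupby("unit_id")["count"].sum()
    assert per_unit["G1"] == 1.0
    assert per_unit["G1_upstream"] == 1.0
    assert "c1:3500" not in per_unit.index


def test_planted_mirna_reads_land_in_mir_units(study_placements, study_run,
                                               toy_genome):
    """>= 99% of miRNA-population read weight is assigned to MIR units."""
    pl = study_placements[study_placements.read_id.str.contains(":mirna:")]
    ann = toy_genome.features
    bm = quantify.count_features(pl, ann, include_upstream=0,
                                 chrom_lengths=toy_genome.chrom_lengths())
    mir_units = bm.units[bm.units.kind == "miRNA"].unit_id
    in_mir = bm.counts[bm.counts.unit_id.isin(mir_units)]["count"].sum()
    assert in_mir >= 0.99 * pl.weight.sum()


def test_rpm_definition_and_totals(tiny_placements):
    bm = quantify.count_bins(tiny_placements, {"c1": 400})
    bm.mapped_totals = {"L1": 1_000_000.0}
    tbl = quantify.rpm(bm)
    row = tbl[(tbl.unit_id == "c1:0-100")]
    assert row.rpm.iloc[0] == pytest.approx(1.0)
    bm2 = quantify.count_bins(tiny_placements, {"c1": 400})
    assert quantify.rpm(bm2).rpm.sum() == pytest.approx(1e6)
    bm2.mapped_totals["L1"] = 0.0
    with pytest.raises(ValueError, match="zero mapped"):
        quantify.rpm(bm2)


def test_length_profile_degenerate_and_sums():
    pl = _placements([("L1", "c1", i, "+", 21, 1.0, "A" * 21)
                      for i in range(5)])
    prof = quantify.length_profile(quantify.count_bins(pl, {"c1": 100}))
    assert prof.loc["L1", 21] == pytest.approx(100.0)
    assert prof.loc["L1"].sum() == pytest.approx(100.0)


def test_mutant_shifts_length_profile(study_outdir, study_manifest):
    prof = pd.read_csv(study_outdir / "length_profiles.tsv", sep="\t",
                       index_col=0)
    prof.columns = prof.columns.astype(int)
    geno = study_manifest.set_index("library_id")
    wt = [l for l in prof.index if geno.loc[l, "genotype"] == "WT"
          and geno.loc[l, "fraction"] == "total"]
    mut = [l for l in prof.index if geno.loc[l, "genotype"] == "fry1"
           and geno.loc[l, "fraction"] == "total"]
    assert prof.loc[mut, 24].mean() < prof.loc[wt, 24].mean()
    assert prof.loc[mut, 21].mean() > prof.loc[wt, 21].mean()


def test_classification_precedence_and_partition(toy_genome):
    units = quantify.make_bins(toy_genome.chrom_lengths())
    cats = quantify.classify_units(units, toy_genome.features)
    assert len(cats) == len(units)
    assert set(cats.unique()) <= {"miRNA", "TAS", "rRNA", "gene", "TE", "other"}
    # a bin fully inside ITS1 is rRNA
    its1 = toy_genome.features.query("feature_id == 'ITS1'").iloc[0]
    inside = units[(units.chrom == "rDNA") & (units.start >= its1.start)
                   & (units.end <= its1.end)]
    assert (cats.loc[inside.unit_id] == "rRNA").all()


def test_classification_tie_break_uses_precedence():
    ann = pd.DataFrame([
        ("c1", 0, 50, "+", "MIRX", "miRNA"),
        ("c1", 50, 100, "+", "GX", "gene"),
    ], columns=["chrom", "start", "end", "strand", "feature_id",
                "feature_class"])
    units = quantify.make_bins({"c1": 100}, 100)
    cats = quantify.classify_units(units, ann)
    assert cats.iloc[0] == "miRNA"


def test_classification_rejects_unknown_class():
    ann = pd.DataFrame([("c1", 0, 50, "+", "X", "enhancer")],
                       columns=["chrom", "start", "end", "strand",
                                "feature_id", "feature_class"])
    with pytest.raises(ValueError, match="unknown"):
        quantify.classify_units(quantify.make_bins({"c1": 100}), ann)


def test_five_prime_composition_degenerate_and_sum():
    pl = _placements([("L1", "c1", i, "+", 21, 1.0, "T" + "A" * 20)
                      for i in range(4)])
    frac = quantify.five_prime_composition(pl)
    assert frac["U"] == pytest.approx(1.0)
    assert frac.sum() == pytest.approx(1.0)


def test_planted_five_prime_u_bias_recovered(study_placements, toy_genome):
    """Sense-strand 21-nt reads at planted phased rDNA loci show the
    configured 0.8 5'-U bias within 3 sigma binomial."""
    mut_libs = study_placements.library_id.str.startswith("fry1_rep")
    pl = study_placements[mut_libs
                          & (study_placements.chrom == "rDNA")
                          & (study_placements.read_id.str.contains(":phased"))]
    frac = quantify.five_prime_composition(pl, length=21, strand="+")
    # the realized per-position bias in the genome (positions are drawn
    # Bernoulli(0.8) at build time), against which the read-level estimate
    # is checked with read-sampling noise only
    planted = []
    for locus in toy_genome.phase_loci.itertuples(index=False):
        if locus.chrom != "rDNA":
            continue
        seq = toy_genome.seqs[locus.chrom]
        for j in range(locus.n_cycles):
            planted.append(seq[locus.register_start + j * 21] == "T")
    realized = np.mean(planted)
    sigma_pos = np.sqrt(0.8 * 0.2 / len(planted))
    assert abs(realized - 0.8) < 3 * sigma_pos
    n = float(pl[(pl.length == 21) & (pl.strand == "+")].weight.sum())
    assert abs(frac["U"] - realized) < 3 * np.sqrt(realized * (1 - realized) / n) + 0.02


def test_track_export_and_round_trip(tmp_path):
    pl = _placements([("L1", "c1", 5, "+", 21, 1.0, "A" * 21)])
    plus, minus = quantify.export_tracks(pl, mapped_total=1e6,
                                         out_prefix=tmp_path / "t")
    track = io.read_bedgraph(plus)
    assert list(track.itertuples(index=False))[0] == ("c1", 5, 6, 1.0)
    assert io.read_bedgraph(minus).empty
    # minus-strand values are emitted negative
    pl2 = _placements([("L1", "c1", 30, "-", 21, 2.0, "A" * 21)])
    _, minus2 = quantify.export_tracks(pl2, mapped_total=1e6,
                                       out_prefix=tmp_path / "u")
    assert io.read_bedgraph(minus2).value.iloc[0] == pytest.approx(-2.0)
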