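"""Generator contracts: determinism, genome structure, count model."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from roguesrna import io, preprocess, synthio


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def test_genome_build_is_deterministic(tmp_path):
    hashes = []
    for rep in ("a", "b"):
        g = synthio.build_toy_genome(1)
        fasta, gff = g.save(tmp_path / rep)
        hashes.append((_file_hash(fasta), _file_hash(gff)))
    assert hashes[0] == hashes[1]


def test_rdna_unit_has_seven_contiguous_subfeatures():
    sizes = synthio.GenomeSizes(rdna_unit_len=6000)
    g = synthio.build_toy_genome(3, sizes)
    rdna = (g.features[g.features.chrom == "rDNA"]
            .sort_values("start").reset_index(drop=True))
    assert len(rdna) == 7
    assert rdna.start.iloc[0] == 0 and rdna.end.iloc[-1] == 6000
    assert (rdna.start.iloc[1:].to_numpy() == rdna.end.iloc[:-1].to_numpy()).all()
    assert list(rdna.feature_id) == ["5ETS", "18S", "ITS1", "5.8S", "ITS2",
                                     "25S", "3ETS"]


def test_genome_meets_minimum_feature_counts(toy_genome):
    classes = toy_genome.features.feature_class.value_counts()
    assert classes["gene"] >= 20
    assert classes["miRNA"] >= 5
    assert classes["TE"] >= 5
    assert classes["TAS"] == 1
    assert set(toy_genome.seqs["chr1"]) <= set("ACGT")


def test_mature_mirnas_unique_by_exhaustive_scan(toy_genome):
    """Brute-force substring search over both strands finds each mature
    miRNA exactly once."""
    for mature in toy_genome.mirnas.mature_seq:
        n = 0
        for seq in toy_genome.seqs.values():
            for q in {mature, synthio.revcomp(mature)}:
                start = seq.find(q)
                while start != -1:
                    n += 1
                    start = seq.find(q, start + 1)
        assert n == 1


def test_undersized_genome_rejected():
    with pytest.raises(ValueError, match="rDNA"):
        synthio.build_toy_genome(1, synthio.GenomeSizes(rdna_unit_len=5000))
    with pytest.raises(ValueError, match="genome too small"):
        synthio.build_toy_genome(1, synthio.GenomeSizes(n_genes=10))


def test_simulation_rejects_bad_config(toy_genome, tmp_path):
    with pytest.raises(ValueError, match="depth"):
        cfg = synthio.SimulationConfig(depth=0)
        synthio.simulate_libraries(toy_genome, cfg, tmp_path)
    with pytest.raises(ValueError, match="dispersion"):
        cfg = synthio.SimulationConfig(dispersion=-1)
        synthio.simulate_libraries(toy_genome, cfg, tmp_path)


def test_simulation_deterministic_and_depth_exact(toy_genome, tmp_path):
    cfg = synthio.SimulationConfig(depth=3000, ip_depth=3000, seed=5,
                                   replicates=1)
    hashes = []
    for rep in ("a", "b"):
        out = tmp_path / rep
        synthio.simulate_libraries(toy_genome, cfg, out)
        libs = sorted(out.glob("*.fastq"))
        hashes.append([_file_hash(p) for p in libs])
        for p in libs:
            n = sum(1 for _ in io.iter_fastq(p))
            assert n == 3000
    assert hashes[0] == hashes[1]


def test_null_effect_map_gives_identical_expectations(toy_genome, tmp_path):
    cfg = synthio.SimulationConfig(
        depth=2000, make_ip=False, seed=2, replicates=1,
        effects={"WT": {}, "fry1": {}})
    truth = synthio.simulate_libraries(toy_genome, cfg, tmp_path)
    exp = truth.expected_counts.pivot_table(
        index="locus_id", columns="library_id", values="expected")
    assert np.allclose(exp["WT_rep1"], exp["fry1_rep1"])
    assert truth.planted_hyper.empty


def test_zero_pulldown_weight_excludes_24nt_from_ip(toy_genome, tmp_path):
    cfg = synthio.SimulationConfig(
        depth=5000, ip_depth=5000, seed=3, replicates=1,
        genotypes=("WT",),
        ip_length_weights={21: 2.0, 22: 2.0, 24: 0.0})
    synthio.simulate_libraries(toy_genome, cfg, tmp_path)
    lengths = {int(rid.rsplit(":", 1)[1])
               for rid, _, _ in io.iter_fastq(tmp_path / "WT_IP_rep1.fastq")}
    assert 24 not in lengths
    # 24-nt reads exist in the matched input
    in_lengths = {int(rid.rsplit(":", 1)[1])
                  for rid, _, _ in io.iter_fastq(tmp_path / "WT_rep1.fastq")}
    assert 24 in in_lengths


def test_poisson_limit_counts_match_expectations(toy_genome, tmp_path):
    """alpha=0, large depth: observed/expected per-locus ratios near 1
    (law of large numbers against the ground-truth bookkeeping)."""
    cfg = synthio.SimulationConfig(depth=200_000, make_ip=False, seed=4,
                                   replicates=1, dispersion=0.0,
                                   genotypes=("WT",))
    truth = synthio.simulate_libraries(toy_genome, cfg, tmp_path)
    observed = {}
    for rid, _, _ in io.iter_fastq(tmp_path / "WT_rep1.fastq"):
        pop = rid.split(":")[2]
        observed[pop] = observed.get(pop, 0) + 1
    expected = (truth.expected_counts
                .groupby("population")["expected"].sum())
    for pop, exp in expected.items():
        if exp < 100:
            continue
        obs = observed.get(pop, 0)
        assert abs(obs - exp) < 3 * np.sqrt(exp) + 1, pop


def test_read_structure_insert_plus_adapter_padded(toy_genome, tmp_path):
    cfg = synthio.SimulationConfig(depth=500, make_ip=False, seed=6,
                                   replicates=1, genotypes=("WT",))
    synthio.simulate_libraries(toy_genome, cfg, tmp_path)
    for rid, seq, qual in io.iter_fastq(tmp_path / "WT_rep1.fastq"):
        L = int(rid.rsplit(":", 1)[1])
        assert len(seq) == synthio.MACHINE_READ_LEN
        assert len(qual) == len(seq)
        adapter_part = seq[L:L + len(cfg.adapter)]
        assert adapter_part == cfg.adapter[:len(adapter_part)]


def test_nb_overdispersion_moment_check(toy_genome, tmp_path):
    """Across many replicate libraries, per-locus count variance follows
    the NB mean-variance law var = m + alpha m^2 (within chi^2 bounds)."""
    n_rep = 400
    alpha = 0.2
    depth = 5000
    cfg = synthio.SimulationConfig(depth=depth, make_ip=False, seed=8,
                                   dispersion=alpha, replicates=1,
                                   genotypes=("WT",))
    # use the internal count model directly (library writing not needed)
    rng = np.random.default_rng(8)
    units = synthio._population_table(toy_genome, cfg, rng)
    probs = units.share.to_numpy() / units.share.sum()
    counts = np.empty((n_rep, len(probs)))
    for r in range(n_rep):
        lam = rng.gamma(1.0 / alpha, alpha * probs)
        counts[r] = rng.multinomial(depth, lam / lam.sum())
    m = counts.mean(0)
    v = counts.var(0, ddof=1)
    big = m > 50
    # NB variance, corrected for conditioning on the fixed total
    expect_v = m + alpha * m ** 2 - m ** 2 * (1 + alpha) / depth
    ratio = v[big] / expect_v[big]
    # chi^2_{n-1}/(n-1) 3-sigma band around 1
    bound = 3 * np.sqrt(2.0 / (n_rep - 1))
    assert np.all(np.abs(ratio - 1) < 6 * bound), ratio
    assert abs(ratio.mean() - 1) < 2 * bound
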