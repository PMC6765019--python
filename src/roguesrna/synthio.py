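"""Synthetic genome and sRNA-library simulator.

The generator emulates the statistical structure of a small-RNA sequencing
study of a wild-type line and a silencing-pathway mutant:

* a dominant 24-nt heterochromatic siRNA peak in WT that collapses in the
  mutant, with a concomitant rise of the 21-nt peak;
* 21-nt double-stranded, head-to-tail phased siRNAs planted at rDNA
  spacer regions (5'ETS / ITS) and at a subset of coding genes, expressed
  essentially only in the mutant; a TAS locus phased in both genotypes;
* a sense-strand rRNA degradation background uniform over 18-30 nt present
  in all genotypes, plus a small antisense background with a 5'-C bias;
* mature miRNAs (21 nt, 5'-U biased) that are mostly reduced in the mutant;
* AGO-IP libraries importance-resampled from the matched input composition
  so that 21-nt 5'-U reads are retained preferentially and 24-nt reads
  are depleted, with a genotype-specific miRNA loading factor.

Because downstream alignment is exact-match, all sequence biases
(miRNA 5'-U, phased-register 5'-U) are baked into the genome sequence at
construction time; simulated reads are verbatim genomic substrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: rDNA subfeatures in transcription order with their share of the unit length
RDNA_LAYOUT = [
    ("5ETS", "rRNA_spacer", 0.10),
    ("18S", "rRNA_mature", 0.26),
    ("ITS1", "rRNA_spacer", 0.045),
    ("5.8S", "rRNA_mature", 0.025),
    ("ITS2", "rRNA_spacer", 0.035),
    ("25S", "rRNA_mature", 0.48),
    ("3ETS", "rRNA_spacer", 0.055),
]

DEFAULT_ADAPTER = "AGATCGGAAGAGC"
MACHINE_READ_LEN = 75  # single-end read length of the emulated platform


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSizes:
    """Size knobs for the toy genome; defaults give ~47 kb + 7 kb rDNA."""

    n_genes: int = 24
    gene_len: int = 1200
    n_mirna: int = 8
    n_te: int = 6
    te_len: int = 800
    tas_len: int = 500
    mir_locus_len: int = 120
    spacer_len: int = 300
    rdna_unit_len: int = 7000
    n_phased_genes: int = 6
    phase_cycles: int = 12
    phase_len: int = 21
    mirna_five_prime_u: float = 0.9
    phased_five_prime_u: float = 0.8

    def validate(self) -> None:
        if self.rdna_unit_len < 6000:
            raise ValueError("rDNA unit must be >= 6 kb (>= 60 bins)")
        if self.n_genes < 20 or self.n_mirna < 5 or self.n_te < 5:
            raise ValueError("genome too small: need >= 20 genes, >= 5 MIR loci, >= 5 TEs")
        if self.n_phased_genes > self.n_genes:
            raise ValueError("more phased genes requested than genes")
        if self.gene_len < self.phase_cycles * self.phase_len + 60:
            raise ValueError("gene_len too short for the requested phase cycles")


@dataclass
class ToyGenome:
    seqs: dict[str, str]
    features: pd.DataFrame       # chrom,start,end,strand,feature_id,feature_class
    mirnas: pd.DataFrame         # feature_id, chrom, mature_start, mature_seq
    phase_loci: pd.DataFrame     # locus_id, feature_id, feature_class, chrom,
                                 #   register_start, n_cycles, register
    sizes: GenomeSizes

    def save(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        gff = outdir / "annotation.gff3"
        io.write_fasta(self.seqs, fasta)
        io.write_gff3(self.features, gff)
        return fasta, gff

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.seqs.items()}


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def build_toy_genome(seed: int, sizes: GenomeSizes | None = None) -> ToyGenome:
    """Deterministically construct the two-contig toy genome.

    chr1 interleaves MIR loci, coding genes (a subset phase-capable),
    one TAS locus and TEs, separated by intergenic spacers. The rDNA
    contig is a single transcription unit tiled contiguously by
    5'ETS-18S-ITS1-5.8S-ITS2-25S-3'ETS.
    """
    sizes = sizes or GenomeSizes()
    sizes.validate()
    rng = np.random.default_rng(seed)

    feats: list[dict] = []
    phase_loci: list[dict] = []
    chunks: list[np.ndarray] = []
    pos = 0

    def spacer():
        nonlocal pos
        chunks.append(_random_seq(rng, sizes.spacer_len))
        pos += sizes.spacer_len

    def add_feature(fid: str, fclass: str, length: int, strand: str,
                    seq: np.ndarray | None = None) -> int:
        nonlocal pos
        start = pos
        chunks.append(_random_seq(rng, length) if seq is None else seq.copy())
        pos += length
        feats.append(dict(chrom="chr1", start=start, end=start + length,
                          strand=strand, feature_id=fid, feature_class=fclass))
        spacer()
        return start

    # Interleave feature types so bins of different classes are spread out.
    spacer()
    mir_slots = [add_feature(f"MIR{i + 1}", "miRNA", sizes.mir_locus_len, "+")
                 for i in range(sizes.n_mirna)]
    phased_gene_idx = set(range(0, sizes.n_phased_genes))
    gene_starts = []
    for i in range(sizes.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        gene_starts.append(add_feature(f"GENE{i + 1}", "gene", sizes.gene_len, strand))
    tas_start = add_feature("TAS1", "TAS", sizes.tas_len, "+")
    # TE1/TE2 are an identical repeat-family pair so that TE-derived reads
    # genuinely multimap and exercise fractional/guided placement.
    te_template = _random_seq(rng, sizes.te_len)
    for i in range(sizes.n_te):
        seq = te_template if i < 2 else None
        add_feature(f"TE{i + 1}", "TE", sizes.te_len,
                    "+" if i % 2 else "-", seq)
    chr1 = np.concatenate(chunks)

    # rDNA unit: subfeature boundaries from the layout fractions, tiled exactly.
    L = sizes.rdna_unit_len
    bounds = np.round(np.cumsum([0.0] + [f for _, _, f in RDNA_LAYOUT]) /
                      sum(f for _, _, f in RDNA_LAYOUT) * L).astype(int)
    rdna = _random_seq(rng, L)
    for (name, fclass, _), s, e in zip(RDNA_LAYOUT, bounds[:-1], bounds[1:]):
        feats.append(dict(chrom="rDNA", start=int(s), end=int(e), strand="+",
                          feature_id=name, feature_class=fclass))

    seqs = {"chr1": chr1, "rDNA": rdna}

    # Plant phased registers: 5'-U bias written into the genome so that
    # exact-match reads started at register positions carry the bias.
    def plant_register(locus_id, fid, fclass, chrom, reg_start, n_cycles):
        arr = seqs[chrom]
        for j in range(n_cycles):
            p = reg_start + j * sizes.phase_len
            if rng.random() < sizes.phased_five_prime_u:
                arr[p] = "T"
        phase_loci.append(dict(locus_id=locus_id, feature_id=fid,
                               feature_class=fclass, chrom=chrom,
                               register_start=reg_start, n_cycles=n_cycles,
                               register=reg_start % sizes.phase_len))

    for i in sorted(phased_gene_idx):
        plant_register(f"phas_GENE{i + 1}", f"GENE{i + 1}", "gene", "chr1",
                       gene_starts[i] + 60, sizes.phase_cycles)
    plant_register("phas_TAS1", "TAS1", "TAS", "chr1", tas_start + 40,
                   min(sizes.phase_cycles, (sizes.tas_len - 80) // sizes.phase_len))
    spacer_feats = [f for f in feats if f["feature_class"] == "rRNA_spacer"]
    for f in spacer_feats[:3]:  # 5'ETS, ITS1, ITS2
        room = (f["end"] - f["start"] - 40) // sizes.phase_len
        n_cyc = min(sizes.phase_cycles, room)
        if n_cyc >= 3:
            plant_register(f"phas_rDNA_{f['feature_id']}", f["feature_id"],
                           "rRNA_spacer", "rDNA", f["start"] + 20, n_cyc)

    # Mature miRNAs: 21-mers inside the MIR loci, 5'-U biased, and unique in
    # the genome on either strand (resample the locus on collision).
    mir_rows = []
    k = 21
    for i, start in enumerate(mir_slots):
        mstart = start + 30
        while True:
            if rng.random() < sizes.mirna_five_prime_u:
                seqs["chr1"][mstart] = "T"
            mature = "".join(seqs["chr1"][mstart:mstart + k])
            if _genome_occurrences(seqs, mature) == 1:
                break
            seqs["chr1"][mstart:mstart + k] = _random_seq(rng, k)
        mir_rows.append(dict(feature_id=f"MIR{i + 1}", chrom="chr1",
                             mature_start=mstart, mature_seq=mature))

    genome = ToyGenome(
        seqs={name: "".join(arr) for name, arr in seqs.items()},
        features=pd.DataFrame(feats),
        mirnas=pd.DataFrame(mir_rows),
        phase_loci=pd.DataFrame(phase_loci),
        sizes=sizes,
    )
    return genome


def _genome_occurrences(seqs: dict[str, np.ndarray], query: str) -> int:
    n = 0
    rc = revcomp(query)
    for arr in seqs.values():
        s = "".join(arr) if isinstance(arr, np.ndarray) else arr
        for q in {query, rc}:
            start = s.find(q)
            while start != -1:
                n += 1
                start = s.find(q, start + 1)
    return n


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study design and noise model for the simulated libraries.

    ``effects`` maps genotype -> {population or locus_id -> fold change
    relative to WT}; a locus-level entry overrides its population entry.
    ``ip_length_weights`` and related fields define the relative retention
    of read classes in the AGO-IP pull-down.
    """

    genotypes: tuple[str, ...] = ("WT", "fry1")
    replicates: int = 2
    depth: int = 100_000
    ip_depth: int = 100_000
    dispersion: float = 0.02          # NB alpha for per-locus counts across reps
    adapter: str = DEFAULT_ADAPTER
    read_len: int = MACHINE_READ_LEN
    seed: int = 0
    make_ip: bool = True
    phased_len_probs: dict[int, float] = field(default_factory=lambda: {21: 1.0})
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    # baseline abundance shares per population. The phased populations are
    # planted only where the effect map switches them on (mutant), so their
    # shares are the expressing-genotype level; the rest are WT levels.
    share_mirna: float = 0.30
    share_het: float = 0.45
    share_tas: float = 0.04
    share_phased_rdna: float = 0.28
    share_phased_gene: float = 0.18
    share_degradation: float = 0.15
    share_antisense_bg: float = 0.03
    antisense_c_bias: float = 0.6
    # AGO pull-down: weight = length_weight * (u_bonus if 21/22-nt 5'-U)
    #                         * genotype miRNA loading factor (miRNA reads)
    ip_length_weights: dict[int, float] = field(
        default_factory=lambda: {21: 2.0, 22: 2.0, 24: 0.1})
    ip_default_length_weight: float = 0.5
    ip_five_prime_u_bonus: float = 4.0
    ip_mirna_loading: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "fry1": 0.5})

    def validate(self) -> None:
        if self.depth <= 0 or self.ip_depth <= 0:
            raise ValueError("library depth must be positive")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        p = sum(self.phased_len_probs.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError("phased_len_probs must sum to 1")
        if any(w < 0 for w in self.ip_length_weights.values()):
            raise ValueError("pull-down weights must be >= 0")


def default_effects() -> dict[str, dict[str, float]]:
    """fry1-like genotype effect map (multiplier on the baseline shares).

    The planted phased populations are absent in WT (multiplier 0) and
    expressed at their baseline share in the mutant; the rescue genotype
    loses the rDNA phased population again while keeping the coding-gene
    one, mirroring an RDR6-dependent risiRNA pathway.
    """
    mir_down = {"MIR1": 0.3, "MIR2": 0.3, "MIR3": 0.35}
    mir_up = {"MIR8": 1.6}   # one AGO1-feedback-like upregulated miRNA
    return {
        "WT": {"phased_rdna": 0.0, "phased_gene": 0.0},
        "fry1": {"mirna": 0.55, "het_sirna": 0.15, "phased_rdna": 1.0,
                 "phased_gene": 1.0, "tas": 0.8, **mir_down, **mir_up},
        "fry1_rdr6": {"mirna": 0.85, "het_sirna": 0.15, "phased_rdna": 0.0,
                      "phased_gene": 1.0, "tas": 0.8},
    }


@dataclass
class GroundTruth:
    expected_counts: pd.DataFrame  # locus_id, population, library_id, expected
    planted_hyper: pd.DataFrame    # locus_id, feature_id, feature_class, fold
    phased_loci: pd.DataFrame      # as genome.phase_loci + genotype expression
    loading_factors: dict[str, float]
    manifest: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expected_counts.to_csv(outdir / "truth_expected_counts.tsv",
                                    sep="\t", index=False)
        self.planted_hyper.to_csv(outdir / "truth_planted_hyper.tsv",
                                  sep="\t", index=False)
        self.phased_loci.to_csv(outdir / "truth_phased_loci.tsv",
                                sep="\t", index=False)
        io.dump_json({"loading_factors": self.loading_factors},
                     outdir / "truth_loading.json")
        io.write_manifest(self.manifest, outdir / "manifest.tsv")


def _population_table(genome: ToyGenome, cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """One row per source locus with its baseline WT abundance share."""
    rows = []
    # miRNAs: fixed abundance ladder spanning ~1.5 decades (miRNA levels in
    # real libraries span orders of magnitude). A fixed profile, not a
    # random draw: the genotype contrasts planted on top of it are design
    # guarantees of the generator.
    n_mir = len(genome.mirnas)
    w = 10.0 ** (-1.5 * np.arange(n_mir) / max(n_mir - 1, 1))
    w = w / w.sum() * cfg.share_mirna
    for share, row in zip(w, genome.mirnas.itertuples(index=False)):
        rows.append(dict(locus_id=row.feature_id, population="mirna",
                         feature_id=row.feature_id, share=share))
    # 24-nt heterochromatic siRNAs from TEs
    tes = genome.features.query("feature_class == 'TE'")
    for _, te in tes.iterrows():
        rows.append(dict(locus_id=te.feature_id, population="het_sirna",
                         feature_id=te.feature_id,
                         share=cfg.share_het / len(tes)))
    # phased loci
    phased = genome.phase_loci
    rdna_ph = phased[phased.chrom == "rDNA"]
    gene_ph = phased[(phased.chrom == "chr1") & (phased.feature_class == "gene")]
    tas_ph = phased[phased.feature_class == "TAS"]
    for _, p in rdna_ph.iterrows():
        rows.append(dict(locus_id=p.locus_id, population="phased_rdna",
                         feature_id=p.feature_id,
                         share=cfg.share_phased_rdna / max(len(rdna_ph), 1)))
    for _, p in gene_ph.iterrows():
        rows.append(dict(locus_id=p.locus_id, population="phased_gene",
                         feature_id=p.feature_id,
                         share=cfg.share_phased_gene / max(len(gene_ph), 1)))
    for _, p in tas_ph.iterrows():
        rows.append(dict(locus_id=p.locus_id, population="tas",
                         feature_id=p.feature_id,
                         share=cfg.share_tas / max(len(tas_ph), 1)))
    rows.append(dict(locus_id="rDNA_degradation", population="degradation",
                     feature_id="rDNA_unit", share=cfg.share_degradation))
    rows.append(dict(locus_id="rDNA_antisense_bg", population="antisense_bg",
                     feature_id="rDNA_unit", share=cfg.share_antisense_bg))
    return pd.DataFrame(rows)


def _effect(cfg: SimulationConfig, genotype: str, locus_id: str,
            population: str) -> float:
    emap = cfg.effects.get(genotype, {})
    return float(emap.get(locus_id, emap.get(population, 1.0)))


def _draw_unit_reads(unit, count: int, genome: ToyGenome,
                     cfg: SimulationConfig, rng: np.random.Generator
                     ) -> list[tuple[str, int]]:
    """Return (insert_sequence, insert_length) tuples for one source locus."""
    if count == 0:
        return []
    pop = unit.population
    out: list[tuple[str, int]] = []
    if pop == "mirna":
        seq = genome.mirnas.set_index("feature_id").loc[unit.feature_id,
                                                        "mature_seq"]
        return [(seq, len(seq))] * count
    if pop == "het_sirna":
        feat = genome.features.set_index("feature_id").loc[unit.feature_id]
        chrom_seq = genome.seqs[feat.chrom]
        starts = rng.integers(feat.start, feat.end - 24, size=count)
        strands = rng.integers(0, 2, size=count)
        for s, neg in zip(starts, strands):
            insert = chrom_seq[s:s + 24]
            out.append((revcomp(insert) if neg else insert, 24))
        return out
    if pop in ("phased_rdna", "phased_gene", "tas"):
        locus = genome.phase_loci.set_index("locus_id").loc[unit.locus_id]
        chrom_seq = genome.seqs[locus.chrom]
        phase = genome.sizes.phase_len
        lens = np.array(sorted(cfg.phased_len_probs))
        lprob = np.array([cfg.phased_len_probs[l] for l in lens])
        cycles = rng.integers(0, locus.n_cycles, size=count)
        senses = rng.integers(0, 2, size=count)  # 1 = sense
        read_lens = lens[rng.choice(len(lens), size=count, p=lprob)]
        s0 = int(locus.register_start)
        for j, sense, L in zip(cycles, senses, read_lens):
            if sense:
                a = s0 + phase * int(j)
                insert = chrom_seq[a:a + int(L)]
            else:
                # antisense 5' end (rightmost coord) at register (s0 - 2) mod phase
                q = s0 + phase * int(j) + phase - 2
                insert = revcomp(chrom_seq[q - int(L) + 1:q + 1])
            out.append((insert, int(L)))
        return out
    if pop in ("degradation", "antisense_bg"):
        chrom_seq = genome.seqs["rDNA"]
        n = len(chrom_seq)
        read_lens = rng.integers(18, 31, size=count)
        if pop == "degradation":
            starts = rng.integers(0, n - 31, size=count)
            return [(chrom_seq[s:s + int(L)], int(L))
                    for s, L in zip(starts, read_lens)]
        # antisense background, 5'-C biased: read 5' base is the complement of
        # the genomic base at the rightmost coordinate, so target genomic 'G'.
        g_positions = np.frombuffer(chrom_seq.encode(), dtype=np.uint8)
        g_idx = np.flatnonzero(g_positions == ord("G"))
        g_idx = g_idx[(g_idx >= 31) & (g_idx < n - 1)]
        for L in read_lens:
            if rng.random() < cfg.antisense_c_bias and len(g_idx):
                q = int(g_idx[rng.integers(0, len(g_idx))])
            else:
                q = int(rng.integers(31, n - 1))
            out.append((revcomp(chrom_seq[q - int(L) + 1:q + 1]), int(L)))
        return out
    raise ValueError(f"unknown population {pop!r}")


def simulate_libraries(genome: ToyGenome, cfg: SimulationConfig,
                       outdir: str | Path) -> GroundTruth:
    """Simulate FASTQ libraries plus ground truth under the configured design.

    Per library, per-locus intensities follow the NB hierarchy conditioned
    on the configured depth: Gamma(1/alpha, alpha * mean) intensities, then
    a multinomial over loci, so each library has exactly ``depth`` reads.
    With alpha = 0 this is the conditional law of independent Poisson draws
    given their sum.
    """
    cfg.validate()
    if not cfg.effects:
        cfg.effects = {g: default_effects().get(g, {}) for g in cfg.genotypes}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    units = _population_table(genome, cfg, rng)

    manifest_rows = []
    truth_rows = []
    for genotype in cfg.genotypes:
        eff = np.array([_effect(cfg, genotype, u.locus_id, u.population)
                        for u in units.itertuples(index=False)])
        means = units["share"].to_numpy() * eff
        probs = means / means.sum()
        for rep in range(1, cfg.replicates + 1):
            lib = f"{genotype}_rep{rep}"
            if cfg.dispersion > 0:
                shape = 1.0 / cfg.dispersion
                lam = rng.gamma(shape, cfg.dispersion * probs)
            else:
                lam = probs.copy()
            counts = rng.multinomial(cfg.depth, lam / lam.sum())
            reads: list[tuple[str, str]] = []  # (read_id, machine read)
            input_categories: dict[tuple[str, str], int] = {}
            idx = 0
            for unit, c in zip(units.itertuples(index=False), counts):
                for insert, L in _draw_unit_reads(unit, int(c), genome, cfg, rng):
                    rid = f"{lib}:{idx}:{unit.population}:{L}"
                    reads.append((rid, _machine_read(insert, cfg)))
                    key = (insert, unit.population)
                    input_categories[key] = input_categories.get(key, 0) + 1
                    idx += 1
            io.write_fastq(reads, outdir / f"{lib}.fastq")
            manifest_rows.append(dict(library_id=lib, genotype=genotype,
                                      replicate=rep, fraction="total"))
            for unit, m in zip(units.itertuples(index=False), probs):
                truth_rows.append(dict(locus_id=unit.locus_id,
                                       population=unit.population,
                                       library_id=lib,
                                       expected=float(cfg.depth * m)))
            if cfg.make_ip:
                ip_lib = f"{genotype}_IP_rep{rep}"
                ip_reads = _resample_ip(input_categories, genotype, cfg, rng,
                                        ip_lib)
                io.write_fastq(ip_reads, outdir / f"{ip_lib}.fastq")
                manifest_rows.append(dict(library_id=ip_lib, genotype=genotype,
                                          replicate=rep, fraction="IP"))

    manifest = pd.DataFrame(manifest_rows)
    io.write_manifest(manifest, outdir / "manifest.tsv")

    hyper = []
    mutants = [g for g in cfg.genotypes if g != "WT"]
    for u in units.itertuples(index=False):
        wt_eff = _effect(cfg, "WT", u.locus_id, u.population)
        folds = [_effect(cfg, g, u.locus_id, u.population) for g in mutants]
        if folds and max(folds) > wt_eff:
            fold = max(folds) / wt_eff if wt_eff > 0 else float("inf")
            hyper.append(dict(locus_id=u.locus_id, feature_id=u.feature_id,
                              population=u.population, fold=fold))
    phased = genome.phase_loci.copy()
    phased["expressed_in"] = [
        ",".join(g for g in cfg.genotypes
                 if _effect(cfg, g, lid, pop) * base > 0.001)
        for lid, pop, base in zip(
            phased.locus_id,
            ["tas" if fc == "TAS" else
             ("phased_rdna" if ch == "rDNA" else "phased_gene")
             for fc, ch in zip(phased.feature_class, phased.chrom)],
            [units.set_index("locus_id").share.get(lid, 0.0)
             for lid in phased.locus_id])
    ]
    truth = GroundTruth(
        expected_counts=pd.DataFrame(truth_rows),
        planted_hyper=pd.DataFrame(hyper),
        phased_loci=phased,
        loading_factors=dict(cfg.ip_mirna_loading),
        manifest=manifest,
    )
    truth.save(outdir)
    return truth


def _machine_read(insert: str, cfg: SimulationConfig) -> str:
    """Insert + 3' adapter, padded with G (dark cycles) to the machine length."""
    read = insert + cfg.adapter
    if len(read) >= cfg.read_len:
        return read[:cfg.read_len]
    return read + "G" * (cfg.read_len - len(read))


def _resample_ip(input_categories: dict[tuple[str, str], int], genotype: str,
                 cfg: SimulationConfig, rng: np.random.Generator,
                 lib: str) -> list[tuple[str, str]]:
    """Importance-resample the matched input composition with pull-down weights."""
    keys = sorted(input_categories)
    weights = np.empty(len(keys))
    for i, (insert, pop) in enumerate(keys):
        L = len(insert)
        w = cfg.ip_length_weights.get(L, cfg.ip_default_length_weight)
        if L in (21, 22) and insert.startswith("T"):
            w *= cfg.ip_five_prime_u_bonus
        if pop == "mirna":
            w *= cfg.ip_mirna_loading.get(genotype, 1.0)
        weights[i] = w * input_categories[(insert, pop)]
    if weights.sum() <= 0:
        raise ValueError("all pull-down weights are zero for this library")
    counts = rng.multinomial(cfg.ip_depth, weights / weights.sum())
    reads = []
    idx = 0
    for (insert, pop), c in zip(keys, counts):
        for _ in range(int(c)):
            reads.append((f"{lib}:{idx}:{pop}:{len(insert)}",
                          _machine_read(insert, cfg)))
            idx += 1
    return reads
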