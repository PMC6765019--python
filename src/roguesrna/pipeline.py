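"""End-to-end orchestration: simulate -> trim -> align -> quantify ->
differential analysis -> phasing -> AGO loading -> report.

``run_all`` is deterministic given the config seed and writes every
stage's tables under the output directory plus a machine-readable JSON
report with per-stage record counts and the headline summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import agoload, align, diffsrna, io, phasing, preprocess, quantify, synthio


@dataclass
class RunConfig:
    outdir: str = "run_out"
    seed: int = 1
    # simulation (used unless fastq_dir points at existing libraries)
    genotypes: tuple[str, ...] = ("WT", "fry1")
    replicates: int = 2
    depth: int = 100_000
    ip_depth: int = 100_000
    make_ip: bool = True
    sim_dispersion: float = 0.02
    effects: dict | None = None
    fastq_dir: str | None = None
    genome_fasta: str | None = None
    annotation_gff: str | None = None
    manifest: str | None = None
    # preprocess
    adapter: str = preprocess.DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 42
    min_overlap: int = 3
    max_error_rate: float = 0.1
    # align
    align_mode: str = "guided"
    max_hits: int = 1000
    guided_window: int = 100
    # quantify / diff
    bin_size: int = 100
    diff_lengths: tuple[int, ...] = (21, 24)
    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    # phasing
    phase: int = 21
    phase_cycles: int = 10
    phase_threshold: float = 10.0
    # agoload
    top_n: int = 20
    wt_genotype: str = "WT"

    def validate(self) -> None:
        if self.bin_size < 10:
            raise ValueError("bin size must be >= 10")
        if not (18 <= self.min_len <= self.max_len <= 42):
            raise ValueError("size range must satisfy 18 <= min <= max <= 42")
        for key in ("fastq_dir", "genome_fasta", "annotation_gff", "manifest"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: {val}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for key in ("genotypes", "diff_lengths"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_all(cfg: RunConfig) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _jsonable(asdict(cfg)), "stages": {}}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                raise StageError(name, exc) from exc
        return wrap

    # --- simulate or load inputs -----------------------------------------
    sim_dir = outdir / "sim"
    if cfg.fastq_dir is None:
        genome = stage("simulate")(synthio.build_toy_genome, cfg.seed)
        sim_cfg = synthio.SimulationConfig(
            genotypes=tuple(cfg.genotypes), replicates=cfg.replicates,
            depth=cfg.depth, ip_depth=cfg.ip_depth, make_ip=cfg.make_ip,
            dispersion=cfg.sim_dispersion, adapter=cfg.adapter,
            seed=cfg.seed,
            effects=cfg.effects or {g: synthio.default_effects().get(g, {})
                                    for g in cfg.genotypes})
        stage("simulate")(genome.save, sim_dir)
        truth = stage("simulate")(synthio.simulate_libraries, genome, sim_cfg,
                                  sim_dir)
        manifest = truth.manifest
        fastq_dir = sim_dir
        seqs = genome.seqs
        annotation = genome.features
    else:
        fastq_dir = Path(cfg.fastq_dir)
        manifest = io.read_manifest(cfg.manifest or fastq_dir / "manifest.tsv")
        seqs = io.read_fasta(cfg.genome_fasta)
        annotation = io.read_gff3(cfg.annotation_gff)
        truth = None
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    report["stages"]["libraries"] = {"n": len(manifest)}

    # --- trim + align ------------------------------------------------------
    index = stage("align")(align.GenomeIndex, seqs)
    frames = []
    trim_reports = {}
    align_stats = {}
    for lib in manifest.library_id:
        reads, rep = stage("trim")(preprocess.trim_library,
                                   fastq_dir / f"{lib}.fastq",
                                   cfg.adapter, cfg.min_overlap,
                                   cfg.max_error_rate, cfg.min_len,
                                   cfg.max_len, lib)
        trim_reports[lib] = rep.as_dict()
        placements, stats = stage("align")(align.place_reads, reads, index,
                                           cfg.align_mode, cfg.max_hits, 0,
                                           cfg.guided_window)
        align_stats[lib] = stats.as_dict()
        frame = align.placements_to_frame(placements)
        frame["library_id"] = lib
        frames.append(frame)
    placements = pd.concat(frames, ignore_index=True)
    placements.to_csv(outdir / "placements.tsv", sep="\t", index=False)
    io.dump_json(trim_reports, outdir / "trim_reports.json")
    io.dump_json(align_stats, outdir / "align_stats.json")
    report["stages"]["trim"] = {lib: r["retained"]
                                for lib, r in trim_reports.items()}
    report["stages"]["align"] = {lib: s["placed"]
                                 for lib, s in align_stats.items()}

    # --- quantify ----------------------------------------------------------
    bins = stage("quantify")(quantify.count_bins, placements, chrom_lengths,
                             cfg.bin_size)
    feats = stage("quantify")(quantify.count_features, placements, annotation,
                              1000, chrom_lengths)
    bins.save(outdir / "bins")
    feats.save(outdir / "features")
    bin_categories = quantify.classify_units(bins.units, annotation)
    profiles = quantify.length_profile(bins)
    profiles.to_csv(outdir / "length_profiles.tsv", sep="\t")
    lib_geno = manifest.set_index("library_id")
    total_libs = lib_geno[lib_geno.fraction == "total"].index.tolist()

    def genotype_profile(genotype, libs=None):
        rows = [l for l in (libs or total_libs)
                if lib_geno.loc[l, "genotype"] == genotype]
        return profiles.loc[rows].mean(axis=0)

    report["length_profiles"] = {
        g: {int(k): round(v, 4)
            for k, v in genotype_profile(g).items()}
        for g in cfg.genotypes}
    class21 = quantify.class_profile(bins, bin_categories, length=21)
    class21.to_csv(outdir / "class_profile_21nt.tsv", sep="\t")
    report["class_profile_21nt"] = {
        g: class21.reindex([l for l in total_libs
                            if lib_geno.loc[l, "genotype"] == g])
        .mean(axis=0).round(3).to_dict()
        for g in cfg.genotypes}

    # --- differential analysis (total libraries, mutants vs WT) ------------
    report["dsr"] = {}
    report["dsg"] = {}
    mutants = [g for g in cfg.genotypes if g != cfg.wt_genotype]
    genotype_of = {l: lib_geno.loc[l, "genotype"] for l in total_libs}
    for L in cfg.diff_lengths:
        bmat = bins.matrix(lengths=[L]).loc[:, total_libs]
        fmat = feats.matrix(lengths=[L]).loc[:, total_libs]
        gene_units = feats.units.query("kind == 'gene'").unit_id
        for mut in mutants:
            libs = [l for l in total_libs
                    if genotype_of[l] in (cfg.wt_genotype, mut)]
            # one normalization per length class, from the genome-wide bins
            factors = stage("diff")(diffsrna.size_factors, bmat[libs])
            for name, mat, fam in (
                    ("dsr", bmat[libs], bin_categories),
                    ("dsg", fmat.loc[gene_units, libs], None)):
                res = stage("diff")(
                    diffsrna.nb_wald_test, mat,
                    {l: genotype_of[l] for l in libs}, cfg.wt_genotype, mut,
                    factors, None, fam)
                called = diffsrna.call_dsr_dsg(res, cfg.padj_threshold,
                                               cfg.lfc_threshold)
                called.to_csv(outdir / f"{name}_{mut}_{L}nt.tsv", sep="\t")
                tally = diffsrna.dsr_tally(
                    called, bin_categories if name == "dsr" else None)
                key = f"{mut}_{L}nt"
                report[name][key] = {
                    f"{row.category}:{row.call}": int(row.n)
                    for row in tally.itertuples(index=False)}

    # --- phasing ------------------------------------------------------------
    report["phasing"] = {}
    for g in cfg.genotypes:
        libs = [l for l in total_libs if genotype_of[l] == g]
        pl = placements[placements.library_id.isin(libs)]
        tallies = phasing.phase_assign(pl, cfg.phase)
        windows = stage("phasing")(phasing.score_windows, tallies, cfg.phase,
                                   cfg.phase_cycles)
        regions = phasing.call_phased_regions(windows, cfg.phase_threshold,
                                              cfg.phase)
        rframe = phasing.regions_to_frame(regions)
        rframe.to_csv(outdir / f"phased_regions_{g}.tsv", sep="\t",
                      index=False)
        report["phasing"][g] = {
            "n_regions": len(regions),
            "n_rdna_regions": int((rframe.chrom == "rDNA").sum())
            if len(rframe) else 0,
            "max_score": float(rframe.score.max()) if len(rframe) else 0.0,
        }

    # --- AGO loading --------------------------------------------------------
    if cfg.make_ip and (lib_geno.fraction == "IP").any():
        report["agoload"] = _agoload_stage(cfg, bins, feats, bin_categories,
                                           lib_geno, placements, outdir)

    # checksum over the results only: path-like parameters are excluded so
    # identical runs in different directories hash identically
    path_keys = {"outdir", "fastq_dir", "genome_fasta", "annotation_gff",
                 "manifest"}
    hashable = dict(_jsonable(report))
    hashable["parameters"] = {k: v for k, v in hashable["parameters"].items()
                              if k not in path_keys}
    report["checksum"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True).encode()).hexdigest()
    io.dump_json(_jsonable(report), outdir / "report.json")
    return report


def _agoload_stage(cfg, bins, feats, bin_categories, lib_geno, placements,
                   outdir) -> dict:
    out: dict = {"enriched_bins": {}}
    ip_libs = lib_geno[lib_geno.fraction == "IP"]
    for g in cfg.genotypes:
        libs_ip = ip_libs[ip_libs.genotype == g].index.tolist()
        libs_in = lib_geno[(lib_geno.fraction == "total")
                           & (lib_geno.genotype == g)].index.tolist()
        if not libs_ip or not libs_in:
            continue
        mat = bins.matrix(lengths=[21])[libs_ip + libs_in]
        frac = {l: ("IP" if l in libs_ip else "input") for l in mat.columns}
        rec = agoload.ip_enrichment(mat, frac, cfg.padj_threshold,
                                    categories=bin_categories)
        rec.to_csv(outdir / f"ip_enrichment_{g}_21nt.tsv", sep="\t")
        out["enriched_bins"][g] = {
            str(k): int(v) for k, v in agoload.enrichment_tally(rec).items()}

    # genomic classification of AGO-associated 21-nt sRNAs per genotype
    out["ip_class_profile_21nt"] = {}
    ip_only = placements[placements.library_id.isin(ip_libs.index)]
    if not ip_only.empty:
        ip_bins = quantify.count_bins(ip_only, _chrom_lengths_from(bins),
                                      cfg.bin_size)
        prof = quantify.class_profile(ip_bins, bin_categories, length=21)
        for g in cfg.genotypes:
            libs = [l for l in ip_libs.index if ip_libs.loc[l, "genotype"] == g]
            if libs:
                out["ip_class_profile_21nt"][g] = (
                    prof.reindex(libs).mean(axis=0).round(3).to_dict())

    # miRNA loading efficiency over genotypes with both fractions
    mir_units = feats.units[feats.units.kind == "miRNA"].unit_id
    rpm_tbl = quantify.rpm(feats)
    rpm_tbl = rpm_tbl[rpm_tbl.unit_id.isin(mir_units)]
    per_lib = (rpm_tbl.groupby(["unit_id", "library_id"])["rpm"].sum()
               .unstack(fill_value=0.0))
    geno_frac: dict[tuple[str, str], list[str]] = {}
    for lib, row in lib_geno.iterrows():
        if lib in per_lib.columns:
            geno_frac.setdefault((row.genotype, row.fraction), []).append(lib)
    genotypes = [g for g in cfg.genotypes
                 if (g, "IP") in geno_frac and (g, "total") in geno_frac]
    if len(genotypes) >= 2:
        rpm_ip = pd.DataFrame({g: per_lib[geno_frac[(g, "IP")]].mean(axis=1)
                               for g in genotypes})
        rpm_in = pd.DataFrame({g: per_lib[geno_frac[(g, "total")]].mean(axis=1)
                               for g in genotypes})
        table = agoload.loading_efficiency(rpm_ip, rpm_in, cfg.wt_genotype,
                                           cfg.top_n)
        table.efficiencies.to_csv(outdir / "loading_efficiency.tsv", sep="\t")
        table.tests.to_csv(outdir / "loading_tests.tsv", sep="\t", index=False)
        out["loading_tests"] = table.tests.to_dict(orient="records")
        out["median_efficiency"] = {
            g: float(table.efficiencies.loc[table.top_n, g].median())
            for g in genotypes}
    return out


def _chrom_lengths_from(bm) -> dict[str, int]:
    return (bm.units.groupby("chrom")["end"].max().astype(int).to_dict())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
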