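"""Shared fixtures: one session-scoped end-to-end study run plus the toy
genome, reused by module tests that need realistic placements/counts."""

from __future__ import annotations

import pandas as pd
import pytest

from roguesrna import io, pipeline, synthio

SEED = 11


@pytest.fixture(scope="session")
def toy_genome():
    return synthio.build_toy_genome(SEED)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full pipeline run: WT + mutant + risiRNA-free rescue, with AGO IP."""
    outdir = tmp_path_factory.mktemp("study_run")
    cfg = pipeline.RunConfig(outdir=str(outdir), seed=SEED,
                             genotypes=("WT", "fry1", "fry1_rdr6"),
                             depth=60_000, ip_depth=60_000)
    report = pipeline.run_all(cfg)
    return cfg, report


@pytest.fixture(scope="session")
def study_outdir(study_run):
    from pathlib import Path
    cfg, _ = study_run
    return Path(cfg.outdir)


@pytest.fixture(scope="session")
def study_placements(study_outdir):
    return pd.read_csv(study_outdir / "placements.tsv", sep="\t")


@pytest.fixture(scope="session")
def study_manifest(study_outdir):
    return io.read_manifest(study_outdir / "sim" / "manifest.tsv")


@pytest.fixture(scope="session")
def study_truth(study_outdir):
    sim = study_outdir / "sim"
    return dict(
        expected=pd.read_csv(sim / "truth_expected_counts.tsv", sep="\t"),
        hyper=pd.read_csv(sim / "truth_planted_hyper.tsv", sep="\t"),
        phased=pd.read_csv(sim / "truth_phased_loci.tsv", sep="\t"),
        loading=io.load_json(sim / "truth_loading.json"),
    )
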