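"""Shared fixtures: seeded simulations and full pipeline runs.

The heavy end-to-end runs are session-scoped so every test that inspects
calls reuses the same computation.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from tefuse.model import PipelineConfig
from tefuse.pipeline import run_call
from tefuse.simulate import SimConfig, simulate_all, simulate_wgs_reads

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


CLEAN_SEED = 11
ARTIFACT_SEED = 12


@pytest.fixture(scope="session")
def clean_sim():
    """Planted insertions with library artifacts switched off."""
    cfg = SimConfig(rng_seed=CLEAN_SEED, rate_two_mrna_chimera=0.0,
                    rate_polyA_artifact=0.0)
    sim = simulate_all(cfg)
    sim["config"] = cfg
    return sim


@pytest.fixture(scope="session")
def clean_run(clean_sim):
    return run_call(clean_sim["reads"], clean_sim["bundle"], PipelineConfig(),
                    mode="rnaseq", sample_id="clean")


@pytest.fixture(scope="session")
def artifact_sim():
    """Study conditions with template switching and poly-T read-through."""
    cfg = SimConfig(rng_seed=ARTIFACT_SEED)
    sim = simulate_all(cfg)
    sim["config"] = cfg
    return sim


@pytest.fixture(scope="session")
def artifact_run(artifact_sim):
    return run_call(artifact_sim["reads"], artifact_sim["bundle"],
                    PipelineConfig(), mode="rnaseq", sample_id="artifact")


@pytest.fixture(scope="session")
def artifact_run_nofilter(artifact_sim):
    """Same sample with the poly-T artifact filter disabled."""
    return run_call(artifact_sim["reads"], artifact_sim["bundle"],
                    PipelineConfig(), mode="rnaseq", sample_id="nofilter",
                    apply_polyT=False)


@pytest.fixture(scope="session")
def wgs_run(artifact_sim):
    """WGS reads over the same haplotypes as the artifact RNA sample."""
    cfg = SimConfig(rng_seed=ARTIFACT_SEED, depth=40)
    reads, _ = simulate_wgs_reads(artifact_sim["haplotypes"],
                                  artifact_sim["bundle"], cfg)
    return run_call(reads, artifact_sim["bundle"], PipelineConfig(),
                    mode="wgs", sample_id="wgs")


@pytest.fixture(scope="session")
def exonization_sim():
    """Intronic insertions whose transcripts splice exons onto the TE."""
    cfg = SimConfig(rng_seed=13, depth=150,
                    insertions=[("TE1", "gene0", "intron", "hom"),
                                ("TE2", "gene3", "intron", "hom")],
                    indel_events=[], rate_two_mrna_chimera=0.0,
                    rate_polyA_artifact=0.0, rate_exonization=0.35)
    sim = simulate_all(cfg)
    sim["config"] = cfg
    return sim


@pytest.fixture(scope="session")
def exonization_run(exonization_sim):
    return run_call(exonization_sim["reads"], exonization_sim["bundle"],
                    PipelineConfig(), mode="rnaseq", sample_id="exo")


@pytest.fixture(scope="session")
def tiny_sim():
    """A small, fast simulation for plumbing and CLI tests."""
    cfg = SimConfig(rng_seed=5, chrom_length=60_000, n_genes=4, depth=30,
                    te_depth=10,
                    insertions=[("TE1", "gene1", "utr3", "hom")],
                    indel_events=[], rate_two_mrna_chimera=0.0,
                    rate_polyA_artifact=0.0)
    sim = simulate_all(cfg)
    sim["config"] = cfg
    return sim
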