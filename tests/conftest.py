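"""Shared fixtures: a small synthetic world reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from ricircle.candidate_detection import GenomeIndex, PipelineConfig
from ricircle.synthetic_data import SimConfig, generate_gene_models, generate_genome


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(
        n_chroms=2,
        chrom_len=60_000,
        n_genes=8,
        exons_per_gene=(4, 8),
        intron_len=(60, 400),
        n_designed_sites=40,
        n_datasets=2,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def world(sim_cfg):
    """(genome, models, index) built once for the whole session."""
    genome = generate_genome(sim_cfg)
    genome, models = generate_gene_models(genome, sim_cfg)
    index = GenomeIndex(genome, 20)
    return genome, models, index


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def unique_window(index: GenomeIndex, genome, chrom: str, start: int,
                  length: int = 20) -> int:
    """First position >= start whose anchor-length word is genome-unique."""
    seq = genome[chrom]
    pos = start
    while pos + length <= len(seq):
        if index.hit_count(seq[pos:pos + length]) == 1:
            return pos
        pos += 1
    raise AssertionError("no unique window found")
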