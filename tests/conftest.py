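"""Shared fixtures: a small simulated corpus and one pipeline run on it."""

from __future__ import annotations

import pytest

from abyssotu.pipeline import PipelineConfig, run_pipeline
from abyssotu.synthdata import SimParams, make_reference, simulate_reads


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    # 4 samples, 2 regions, modest depth: big enough to exercise every
    # stage, small enough to keep the suite quick
    return SimParams(
        n_taxa=25,
        reads_per_sample=800,
        samples=(
            ("S1", "ANT"), ("S2", "ANT"), ("S3", "ARC"), ("S4", "ARC"),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_params):
    bundle = make_reference(small_params)
    reads, truth = simulate_reads(small_params, bundle)
    return small_params, bundle, reads, truth


@pytest.fixture(scope="session")
def small_report(small_corpus):
    params, bundle, reads, truth = small_corpus
    config = PipelineConfig(
        primers=params.primers,
        region_map={s: r for s, r in params.samples},
    )
    return run_pipeline(reads, bundle.combined_db, bundle.env_db, config)
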