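"""Shared fixtures: seeded synthetic databases and pipeline runs.

Heavy artifacts (simulated databases, full pipeline runs) are memoized per
seed so that property tests across modules reuse them instead of
regenerating.
"""

from __future__ import annotations

import functools

import pytest

from metaprofiler.pipeline import PipelineConfig, run_metabarcoding
from metaprofiler.synthetic import SimConfig, simulate_reads, simulate_reference_db


@functools.lru_cache(maxsize=None)
def simulated_db(seed: int, **overrides):
    cfg = SimConfig(seed=seed, **overrides)
    records, manifest = simulate_reference_db(cfg)
    return cfg, records, manifest


@functools.lru_cache(maxsize=None)
def clean_run(seed: int):
    """A zero-error, chimera-free, contaminant-free pipeline run."""
    cfg, records, manifest = simulated_db(seed, error_rate=0.0)
    pairs, index_table = simulate_reads(manifest, cfg)
    result = run_metabarcoding(
        pairs, index_table, cfg.fwd_primer, records,
        PipelineConfig(max_len=450),
    )
    return cfg, records, manifest, result


@pytest.fixture(scope="session")
def default_db():
    """One default-condition synthetic reference database."""
    return simulated_db(11)


@pytest.fixture(scope="session")
def pipeline_cfg():
    """Pipeline settings matched to the synthetic read geometry (445 bp
    post-demultiplex templates need the size ceiling at 450)."""
    return PipelineConfig(max_len=450)
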