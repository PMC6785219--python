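"""Shared fixtures: hand-built reads and a small simulated library."""

from __future__ import annotations

import pytest

from mirstack.io import AlignedRead
from mirstack.simulate import SimulationConfig, simulate


def read(
    chrom="chr1",
    start=0,
    length=22,
    strand="+",
    seq=None,
    dup=1,
    nh=1,
    rid=None,
):
    """Terse AlignedRead builder for unit tests."""
    seq = seq if seq is not None else "A" * length
    end = start + len(seq)
    return AlignedRead(
        read_id=rid or f"r{chrom}:{start}:{strand}:{seq[:4]}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        seq=seq,
        dup_count=dup,
        hit_count=nh,
    )


@pytest.fixture(scope="session")
def small_fixture():
    """A modest simulated library used across module tests (20 hairpins,
    100 noise loci) — session-scoped, deterministic."""
    return simulate(
        SimulationConfig(
            rng_seed=42, n_hairpins=20, n_noise_loci=100, genome_length=120_000
        )
    )


@pytest.fixture(scope="session")
def trained_models(small_fixture):
    """MPRF + HPRF trained on the small fixture (for scoring tests)."""
    from mirstack import pipeline

    cfg = pipeline.PipelineConfig(seed=5)
    mprf, hprf = pipeline.run_train(
        list(small_fixture.reads),
        small_fixture.genome,
        small_fixture.annotations,
        cfg,
    )
    return mprf, hprf, cfg
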