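"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from virinflux.align import AlignmentRecord
from virinflux.synth import (
    SimulationConfig,
    generate_host_contigs,
    generate_viral_genome,
    simulate_population,
)


def make_record(
    read_id="r1",
    mate=1,
    subject_id="s",
    subject_kind="virus",
    read_start=1,
    read_end=50,
    subject_start=1,
    subject_end=None,
    score=None,
    identity=100.0,
):
    length = read_end - read_start + 1
    if subject_end is None:
        subject_end = subject_start + length - 1
    return AlignmentRecord(
        read_id=read_id,
        mate=mate,
        subject_id=subject_id,
        subject_kind=subject_kind,
        read_start=read_start,
        read_end=read_end,
        subject_start=subject_start,
        subject_end=subject_end,
        score=float(length if score is None else score),
        identity=identity,
        aln_length=length,
    )


def expected_detection(x_end: int, y_start: int, L: int, min_aln=28,
                       min_excl=16, min_total=95) -> bool:
    """Truth-table oracle for whether a junction-spanning read passes the
    intra-read criteria: maximal first-part alignment ends at x_end, second
    part starts at y_start (read frame, 0-based)."""
    x = min(max(x_end, 0), L)
    y = min(max(y_start, 0), L)
    first_only = y
    second_only = L - x
    ov = x - y
    if min(x, L - y) < min_aln:  # either alignment too short to report
        return False
    return (
        first_only >= min_excl
        and second_only >= min_excl
        and first_only + second_only + ov >= min_total
        and -2 <= ov <= 20
    )


@pytest.fixture(scope="session")
def small_population():
    """A deterministic mid-size population used by several test modules."""
    cfg = SimulationConfig(
        seed=11,
        genome_length=20_000,
        n_genomes=400,
        lambda_insertions=0.15,
        target_depth=1.5,
        n_te_families=2,
        n_unknown_contigs=1,
        transposition_fraction=0.5,
        error_rate=0.0,
    )
    genome = generate_viral_genome(cfg)
    contigs = generate_host_contigs(cfg)
    pop = simulate_population(genome, contigs, cfg)
    return cfg, pop


@pytest.fixture(scope="session")
def small_pipeline(small_population):
    from virinflux.pipeline import run_pipeline

    cfg, pop = small_population
    return cfg, pop, run_pipeline(pop, cfg)
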