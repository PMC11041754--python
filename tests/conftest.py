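"""Shared fixtures: one default synthetic hybrid genome per session."""

import numpy as np
import pytest

import polyarch as pa

FIXTURE_SEED = 20260927


@pytest.fixture(scope="session")
def fixture():
    """(progenitors, truth, reads, oracle PAF) at the default scale."""
    return pa.default_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def progenitors(fixture):
    return fixture[0]


@pytest.fixture(scope="session")
def truth(fixture):
    return fixture[1]


@pytest.fixture(scope="session")
def reads(fixture):
    return fixture[2]


@pytest.fixture(scope="session")
def oracle_paf(fixture):
    return fixture[3]


@pytest.fixture(scope="session")
def chrom_lengths(truth):
    return {name: len(seq) for name, seq in truth.assembly.items()}


@pytest.fixture(scope="session")
def kmer_sets(progenitors):
    return pa.extract_diagnostic_kmers(progenitors.seq_a, progenitors.seq_b, k=27)


@pytest.fixture(scope="session")
def window_paints(truth, kmer_sets):
    return pa.paint_windows(truth.assembly, kmer_sets, window=10_000)


@pytest.fixture(scope="session")
def depth_windows(oracle_paf, chrom_lengths):
    wins = pa.window_depth(oracle_paf, chrom_lengths, window=10_000)
    anchor = pa.estimate_single_copy_depth(wins)
    pa.classify_depth(wins, median_override=anchor)
    return wins
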