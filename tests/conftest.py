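from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracle imports

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from bubblecall import (  # noqa: E402
    count_sample,
    merge_samples,
    build_graph,
    compute_degrees,
    simulate_sample_pair,
)


def graph_from_reads(reads_a, reads_b, k, tau=1):
    """Shared helper: filtered, merged, degree-annotated graph."""
    from bubblecall import filter_low_coverage

    ta = filter_low_coverage(count_sample(reads_a, k), tau)
    tb = filter_low_coverage(count_sample(reads_b, k), tau)
    return compute_degrees(build_graph(merge_samples(ta, tb)))


@pytest.fixture(scope="session")
def planted_small():
    """One clean planted SNP, full-length error-free 'reads', k=7."""
    k = 7
    reads_a, reads_b, truth = simulate_sample_pair(
        genome_length=120, n_snps=1, k=k, read_len=120, coverage=1.0,
        error_rate=0.0, seed=11,
    )
    # coverage 1 with read_len == genome length gives exactly one read per
    # sample, possibly reverse-complemented; the graph is strand-closed
    # either way
    graph = graph_from_reads(reads_a, reads_b, k)
    return graph, truth, k, reads_a, reads_b


@pytest.fixture(scope="session")
def medium_fixture():
    """Small shotgun dataset used by determinism/invariance tests."""
    reads_a, reads_b, truth = simulate_sample_pair(
        genome_length=2_000, n_snps=10, k=15, read_len=100, coverage=20.0,
        error_rate=0.0, seed=5, margin=100,
    )
    return reads_a, reads_b, truth
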