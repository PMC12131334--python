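import itertools

import pytest
from hypothesis import given, strategies as st

from bubblecall import (
    Bubble,
    cluster_partition,
    detect_bubbles,
    hash_partition,
    hierarchical_cluster,
    jaccard,
    lpt_bin,
    xcross_histogram,
)
from bubblecall.partition import UndefinedSimilarityError, _PairCache, _kmer_set, select_representative
from bubblecall.simulate import simulate_genome
from conftest import graph_from_reads


# ---------------------------------------------------------------- jaccard

def test_jaccard_examples():
    assert jaccard("ACGTA", "ACGTA", 3) == 1.0
    assert jaccard("AAAA", "CCCC", 3) == 0.0
    # A = {ACG, CGT, GTA}, B = {ACG, CGT, GTC}: 2 shared of 4 distinct
    assert jaccard("ACGTA", "ACGTC", 3) == 0.5


def test_jaccard_undefined_for_kmerless_read():
    with pytest.raises(UndefinedSimilarityError):
        jaccard("NNNN", "ACGT", 3)


@given(st.text(alphabet="ACGT", min_size=5, max_size=30),
       st.text(alphabet="ACGT", min_size=5, max_size=30))
def test_jaccard_symmetric_and_bounded(a, b):
    j = jaccard(a, b, 4)
    assert 0.0 <= j <= 1.0
    assert j == jaccard(b, a, 4)
    assert jaccard(a, a, 4) == 1.0


def test_jaccard_substitution_robustness():
    """Reads differing by one substitution over length L share at least
    L - 2k + 1 of their k-mers."""
    k, L = 5, 40
    for seed in range(5):
        g = simulate_genome(L, seed)
        mut = g[:20] + ("A" if g[20] != "A" else "C") + g[21:]
        shared = len(_kmer_set(g, k) & _kmer_set(mut, k))
        assert shared >= L - 2 * k + 1


# ------------------------------------------------------------- clustering

def _three_read_fixture():
    base = simulate_genome(40, 99)
    r1 = base
    r2 = base[:39] + ("A" if base[39] != "A" else "C")  # near-identical
    r3 = simulate_genome(40, 123)  # unrelated
    assert jaccard(r1, r3, 5) == 0.0
    return [r1, r2, r3]


def test_cluster_threshold_extremes():
    reads = _three_read_fixture()
    singletons = hierarchical_cluster(reads, 5, c=1.1)
    assert [c.members for c in singletons] == [(0,), (1,), (2,)]
    allinone = hierarchical_cluster(reads, 5, c=0.0)
    assert [c.members for c in allinone] == [(0, 1, 2)]


def test_cluster_pair_plus_outlier():
    clusters = hierarchical_cluster(_three_read_fixture(), 5, c=0.5)
    assert sorted(c.members for c in clusters) == [(0, 1), (2,)]


def test_cluster_weight_and_kmer_set():
    reads = _three_read_fixture()
    (pair, single) = sorted(
        hierarchical_cluster(reads, 5, c=0.5), key=lambda c: c.members
    )
    assert pair.weight == sum(max(0, len(reads[m]) - 5) for m in pair.members)
    assert pair.kmer_set == _kmer_set(reads[0], 5) | _kmer_set(reads[1], 5)
    assert single.representative == 2


def test_representative_selection():
    reads = _three_read_fixture()
    sim = _PairCache([_kmer_set(r, 5) for r in reads])
    assert select_representative((2,), sim) == 2
    # two members: symmetric mean similarity, tie broken to the lower id
    assert select_representative((0, 1), sim) == 0
    # hub read most similar to both others
    base = simulate_genome(60, 7)
    hub, left, right = base[10:50], base[0:40], base[20:60]
    sim3 = _PairCache([_kmer_set(r, 5) for r in (left, hub, right)])
    assert select_representative((0, 1, 2), sim3) == 1


def test_cluster_determinism():
    reads = [simulate_genome(50, s) for s in range(8)]
    a = hierarchical_cluster(reads, 5, c=0.2)
    b = hierarchical_cluster(reads, 5, c=0.2)
    assert [c.members for c in a] == [c.members for c in b]
    assert [c.representative for c in a] == [c.representative for c in b]


# -------------------------------------------------------------------- LPT

def _brute_force_makespan(weights, B):
    best = sum(weights)
    n = len(weights)

    def rec(i, loads):
        nonlocal best
        if max(loads) >= best:
            return
        if i == n:
            best = max(loads)
            return
        seen = set()
        for b in range(B):
            if loads[b] in seen:  # identical machines: skip symmetric bins
                continue
            seen.add(loads[b])
            loads[b] += weights[i]
            rec(i + 1, loads)
            loads[b] -= weights[i]

    rec(0, [0] * B)
    return best


def test_lpt_examples():
    assert lpt_bin([5, 4, 3, 2, 1], 2).makespan == 8
    assert lpt_bin([5, 4, 3], 1).makespan == 12
    assert lpt_bin([5, 4, 3], 5).makespan == 5
    with pytest.raises(ValueError):
        lpt_bin([1], 0)


def test_lpt_assignment_is_a_partition():
    a = lpt_bin([7, 3, 3, 2], 2)
    jobs = sorted(itertools.chain.from_iterable(a.bins))
    assert jobs == [0, 1, 2, 3]
    assert sorted(a.loads, reverse=True)[0] == a.makespan


@given(st.lists(st.integers(0, 20), min_size=1, max_size=9),
       st.integers(1, 4))
def test_lpt_bounds(weights, B):
    a = lpt_bin(weights, B)
    assert a.makespan >= max(weights)
    assert a.makespan >= -(-sum(weights) // B)
    opt = _brute_force_makespan(weights, B)
    assert a.makespan <= (4 / 3 - 1 / (3 * B)) * opt or a.makespan == opt


# ----------------------------------------------------------- partitioning

def test_hash_partition_properties(planted_small):
    graph, *_ = planted_small
    one = hash_partition(graph, 1)
    assert set(one.values()) == {0}
    m1 = hash_partition(graph, 7)
    m2 = hash_partition(graph, 7)
    assert m1 == m2
    assert all(0 <= p < 7 for p in m1.values())


def test_cluster_partition_single_cluster(planted_small):
    graph, _, k, reads_a, reads_b = planted_small
    reads = reads_a + reads_b
    clusters = hierarchical_cluster(reads, k, c=0.0)  # force one cluster
    assert len(clusters) == 1
    a = cluster_partition(graph, clusters, reads, B=4)
    assert set(a.vertex_to_bin.values()) == {0}
    assert sum(1 for l in a.loads if l == 0) == 3


def test_cluster_partition_disjoint_genomes_separate_bins():
    k = 7
    g1, g2 = simulate_genome(80, 1), simulate_genome(80, 2)
    reads = [g1, g2]
    graph = graph_from_reads([g1], [g2], k)
    clusters = hierarchical_cluster(reads, k, c=0.5)
    assert len(clusters) == 2
    a = cluster_partition(graph, clusters, reads, B=2)
    bins_used = {a.vertex_to_bin[c] for c in graph.vertices}
    assert bins_used == {0, 1}
    # all k-mers of one genome (either strand) share that genome's bin
    from bubblecall.kmers import _window_codes, revcomp_code

    for gen, cid in ((g1, 0), (g2, 1)):
        codes = set(_window_codes([gen], k).tolist())
        bins = {a.vertex_to_bin[c] for c in codes}
        bins |= {a.vertex_to_bin[revcomp_code(c, k)] for c in codes}
        assert len(bins) == 1


# -------------------------------------------------------------- x-cross

def test_xcross_histogram_extremes(planted_small):
    graph, _, k, *_ = planted_small
    bubbles = detect_bubbles(graph, k)
    all_one = {c: 0 for c in graph.vertices}
    h = xcross_histogram(bubbles, all_one)
    assert h.loc[0, "span"] == 1 and h.loc[0, "percent"] == 100.0
    # every vertex its own partition -> span = 2k + 2
    distinct = {c: i for i, c in enumerate(graph.vertices)}
    h2 = xcross_histogram(bubbles, distinct)
    assert list(h2["span"]) == [2 * k + 2]
    assert abs(h2["percent"].sum() - 100.0) < 1e-9


def test_xcross_unmapped_vertex_is_an_error(planted_small):
    graph, _, k, *_ = planted_small
    bubbles = detect_bubbles(graph, k)
    with pytest.raises(ValueError):
        xcross_histogram(bubbles, {})
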