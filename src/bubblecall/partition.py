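"""Graph partitioning: baseline hash strategy, cluster-driven strategy and
the x-cross diagnostic.

The cluster-driven strategy groups reads by bottom-up hierarchical
clustering under the Jaccard index over their k-mer sets, then packs the
clusters into B bins with the LPT (longest processing time first) rule for
the P||C_max makespan problem, and finally maps every graph vertex to the
bin of the cluster that contributed it most often.  Bubbles whose vertices
all land in one bin are traversable without cross-partition messages; the
span histogram quantifies how often that happens under each strategy.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bubbles import Bubble
from .graph import DeBruijnGraph
from .kmers import _window_codes, revcomp_code


class UndefinedSimilarityError(ValueError):
    """A read yields no valid k-mer, so its Jaccard index is undefined."""


def _kmer_set(read: str, k: int) -> frozenset[int]:
    return frozenset(_window_codes([read], k).tolist())


def jaccard(read_a: str, read_b: str, k: int) -> float:
    """|A ∩ B| / |A ∪ B| over the distinct k-mer sets of two reads."""
    sa, sb = _kmer_set(read_a, k), _kmer_set(read_b, k)
    if not sa or not sb:
        raise UndefinedSimilarityError("read yields no valid k-mer")
    return len(sa & sb) / len(sa | sb)


@dataclass
class ReadCluster:
    """A group of read ids with a representative and an LPT weight p_j."""

    members: tuple[int, ...]  # sorted read ids
    representative: int
    kmer_set: frozenset[int]
    weight: int  # number of (k+1)-mers extracted from member reads


@dataclass
class BinAssignment:
    bins: list[list[int]]  # cluster/job ids per bin
    loads: list[int]
    makespan: int
    job_to_bin: dict[int, int]
    vertex_to_bin: dict[int, int] = field(default_factory=dict)


class _PairCache:
    """Lazy symmetric cache of read-read Jaccard values."""

    def __init__(self, sets: list[frozenset[int]]):
        self.sets = sets
        self.cache: dict[tuple[int, int], float] = {}

    def __call__(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        key = (i, j) if i < j else (j, i)
        val = self.cache.get(key)
        if val is None:
            sa, sb = self.sets[key[0]], self.sets[key[1]]
            val = len(sa & sb) / len(sa | sb)
            self.cache[key] = val
        return val


def select_representative(members: tuple[int, ...], sim: _PairCache) -> int:
    """Member with maximal mean Jaccard to its co-members (lower id on ties)."""
    if len(members) == 1:
        return members[0]
    best, best_mean = members[0], -1.0
    for m in members:
        mean = sum(sim(m, o) for o in members if o != m) / (len(members) - 1)
        if mean > best_mean:
            best, best_mean = m, mean
    return best


def hierarchical_cluster(reads: list[str], k: int, c: float) -> list[ReadCluster]:
    """Bottom-up clustering of reads with a greedy similarity stop.

    Starts from singletons; each round merges the pair of clusters whose
    representatives' k-mer sets have the highest Jaccard index, stopping as
    soon as the best similarity drops below ``c`` (strict) or one cluster
    remains.  Ties are broken toward the pair with the lexicographically
    smallest (min member id, max member id), so the result is a pure
    function of the read order.
    """
    if not reads:
        raise ValueError("no reads to cluster")
    sets = [_kmer_set(r, k) for r in reads]
    for i, s in enumerate(sets):
        if not s:
            raise UndefinedSimilarityError(f"read {i} yields no valid {k}-mer")
    sim = _PairCache(sets)
    n = len(reads)

    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    rep: dict[int, int] = {i: i for i in range(n)}
    alive = set(range(n))
    # heap entries: (-similarity, min member id, max member id, cid_a, cid_b);
    # cluster ids are never reused, so stale entries are self-invalidating
    heap: list[tuple[float, int, int, int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            heap.append((-sim(i, j), i, j, i, j))
    heapq.heapify(heap)

    next_cid = n
    while len(alive) > 1 and heap:
        negsim, _, _, ca, cb = heapq.heappop(heap)
        if ca not in alive or cb not in alive:
            continue
        if -negsim < c:
            break
        merged = tuple(sorted(members[ca] + members[cb]))
        alive.discard(ca)
        alive.discard(cb)
        cid = next_cid
        next_cid += 1
        members[cid] = merged
        rep[cid] = select_representative(merged, sim)
        for other in alive:
            s = sim(rep[cid], rep[other])
            lo = min(merged[0], members[other][0])
            hi = max(merged[-1], members[other][-1])
            heapq.heappush(heap, (-s, lo, hi, min(cid, other), max(cid, other)))
        alive.add(cid)

    clusters = []
    for cid in sorted(alive, key=lambda c_: members[c_]):
        mem = members[cid]
        kset = frozenset().union(*(sets[m] for m in mem))
        weight = sum(max(0, len(reads[m]) - k) for m in mem)
        clusters.append(ReadCluster(mem, rep[cid], kset, weight))
    return clusters


def lpt_bin(weights: list[int], B: int) -> BinAssignment:
    """Longest-processing-time-first packing of jobs into B identical bins.

    Jobs are taken in non-increasing weight order (lower job id first on
    ties) and each goes to the currently least-loaded bin (lower bin id on
    ties).  Returns the assignment and the makespan C_max.
    """
    if B < 1:
        raise ValueError(f"number of bins must be >= 1, got {B}")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    order = sorted(range(len(weights)), key=lambda j: (-weights[j], j))
    loads = [0] * B
    bins: list[list[int]] = [[] for _ in range(B)]
    job_to_bin: dict[int, int] = {}
    pq = [(0, i) for i in range(B)]
    heapq.heapify(pq)
    for j in order:
        load, i = heapq.heappop(pq)
        bins[i].append(j)
        job_to_bin[j] = i
        load += weights[j]
        loads[i] = load
        heapq.heappush(pq, (load, i))
    return BinAssignment(bins, loads, max(loads) if loads else 0, job_to_bin)


def _splitmix64(x: int) -> int:
    """Stable 64-bit mix (splitmix64 finaliser); independent of PYTHONHASHSEED."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def hash_partition(graph: DeBruijnGraph, P: int) -> dict[int, int]:
    """Uniform, deterministic assignment: partition = hash(code) mod P."""
    if P < 1:
        raise ValueError(f"number of partitions must be >= 1, got {P}")
    vmap = {}
    for code, v in graph.vertices.items():
        pid = _splitmix64(code) % P
        v.partition = pid
        vmap[code] = pid
    for (src, dst) in graph.triplets:
        graph.triplets[(src, dst)] = _splitmix64(_splitmix64(src) ^ dst) % P
    return vmap


def cluster_partition(
    graph: DeBruijnGraph,
    clusters: list[ReadCluster],
    reads: list[str],
    B: int,
) -> BinAssignment:
    """Map every vertex to the bin of the cluster that contributed it most.

    Cluster weights (number of (k+1)-mers in member reads, computed at the
    graph's k) are LPT-packed into B bins.  Each vertex goes to the bin of
    the cluster with the most occurrences of its k-mer (ties: lowest bin
    id); a backward-strand vertex seen in no read inherits the bin of its
    reverse complement.
    """
    k = graph.k
    weights = [
        sum(max(0, len(reads[m]) - k) for m in cl.members) for cl in clusters
    ]
    assignment = lpt_bin(weights, B)

    # per-vertex occurrence tally per cluster
    tally: dict[int, Counter] = {}
    for cid, cl in enumerate(clusters):
        counts: Counter = Counter()
        for m in cl.members:
            counts.update(_window_codes([reads[m]], k).tolist())
        for code, cnt in counts.items():
            if code in graph.vertices:
                tally.setdefault(code, Counter())[cid] += cnt

    vertex_to_bin: dict[int, int] = {}
    for code, cnts in tally.items():
        best = max(
            cnts.items(),
            key=lambda it: (it[1], -assignment.job_to_bin[it[0]], -it[0]),
        )
        vertex_to_bin[code] = assignment.job_to_bin[best[0]]
    for code in graph.vertices:
        if code not in vertex_to_bin:
            rc = revcomp_code(code, k)
            if rc in vertex_to_bin:
                vertex_to_bin[code] = vertex_to_bin[rc]
            else:  # unreachable for read-derived graphs; stay total anyway
                vertex_to_bin[code] = 0
    for code, v in graph.vertices.items():
        v.partition = vertex_to_bin[code]
    for (src, dst) in graph.triplets:
        graph.triplets[(src, dst)] = vertex_to_bin[src]
    assignment.vertex_to_bin = vertex_to_bin
    return assignment


def bubble_span(bubble: Bubble, vertex_to_partition: dict[int, int]) -> int:
    """Number of distinct partitions hosting the bubble's vertices."""
    codes = (bubble.start, bubble.end) + bubble.path_a + bubble.path_b
    try:
        return len({vertex_to_partition[c] for c in codes})
    except KeyError as exc:
        raise ValueError(f"vertex {exc.args[0]} has no partition assigned") from exc


def xcross_histogram(
    bubbles: list[Bubble], vertex_to_partition: dict[int, int]
) -> pd.DataFrame:
    """Distribution of partitions-spanned-per-bubble, as percentages.

    A bubble spanning s partitions needs s computing units (and s-1 x-cross
    hops) to be traversed; columns are span, count, percent (summing 100).
    """
    spans = Counter(bubble_span(b, vertex_to_partition) for b in bubbles)
    total = sum(spans.values())
    rows = [
        {"span": s, "count": n, "percent": 100.0 * n / total}
        for s, n in sorted(spans.items())
    ]
    return pd.DataFrame(rows, columns=["span", "count", "percent"])


def histogram_to_tsv(hist: pd.DataFrame, path: str | Path) -> None:
    hist.to_csv(path, sep="\t", index=False, float_format="%.6f")
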