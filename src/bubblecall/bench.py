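"""Partitioning benchmark on a multi-region fixture.

Builds a deliberately well-separated instance — many short independent
genomic regions, one isolated SNP each, shotgun reads per region — so that
read clustering can isolate regions.  The de Bruijn graph and its bubbles
are computed once (partitioning never changes them); the hash and the
cluster-driven strategies are then compared through the distribution of
partitions spanned per bubble: fewer partitions per bubble means fewer
x-cross messages during traversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import partition as pt
from . import simulate as sim
from .pipeline import PipelineConfig, run_pipeline


@dataclass
class BenchReport:
    n_bubbles: int
    mean_span_hash: float
    mean_span_cluster: float
    pct_single_hash: float
    pct_single_cluster: float
    hist_hash: pd.DataFrame
    hist_cluster: pd.DataFrame


def build_region_fixture(
    n_regions: int,
    region_length: int,
    k: int,
    read_len: int,
    coverage: float,
    seed: int,
) -> tuple[list[str], list[str], sim.PlantedTruth]:
    """Error-free reads from ``n_regions`` disjoint single-SNP regions.

    Each region is an independent random genome, so reads from different
    regions share (almost) no k-mers; SNPs sit away from region edges.
    Returns the pooled per-sample read lists and the pooled truth.
    """
    margin = max(k + 1, (region_length - 2 * k - 2) // 2)
    reads_a: list[str] = []
    reads_b: list[str] = []
    positions, alleles, contexts = [], [], []
    children = np.random.SeedSequence(seed).spawn(n_regions)
    for i, child in enumerate(children):
        g_ss, s_ss, ra_ss, rb_ss = child.spawn(4)
        genome = sim.simulate_genome(region_length, sim._seq_to_seed(g_ss))
        alt, truth = sim.plant_snps(
            genome, 1, k, sim._seq_to_seed(s_ss), margin=margin
        )
        reads_a.extend(
            sim.simulate_reads(genome, read_len, coverage, 0.0, sim._seq_to_seed(ra_ss))
        )
        reads_b.extend(
            sim.simulate_reads(alt, read_len, coverage, 0.0, sim._seq_to_seed(rb_ss))
        )
        positions.append(i * region_length + truth.positions[0])
        alleles.append(truth.alleles[0])
        contexts.append(truth.contexts[0])
    pooled = sim.PlantedTruth(tuple(positions), tuple(alleles), tuple(contexts), k)
    return reads_a, reads_b, pooled


def run_partition_bench(
    n_regions: int = 60,
    region_length: int = 160,
    k: int = 15,
    read_len: int = 100,
    coverage: float = 10.0,
    units: int = 2,
    bins_per_unit: int = 4,
    cluster_threshold: float = 0.3,
    seed: int = 1,
    out_dir: Path | None = None,
) -> BenchReport:
    reads_a, reads_b, _ = build_region_fixture(
        n_regions, region_length, k, read_len, coverage, seed
    )
    n_parts = bins_per_unit * units  # equal partition count for both sides
    result = run_pipeline(reads_a, reads_b, PipelineConfig(k=k, tau=1))
    bubbles = result.bubbles
    if not bubbles:
        raise RuntimeError("benchmark fixture produced no bubbles")

    hash_map = pt.hash_partition(result.graph, n_parts)
    hist_hash = pt.xcross_histogram(bubbles, hash_map)
    spans_hash = [pt.bubble_span(b, hash_map) for b in bubbles]

    clusters = pt.hierarchical_cluster(reads_a + reads_b, k, cluster_threshold)
    assignment = pt.cluster_partition(
        result.graph, clusters, reads_a + reads_b, n_parts
    )
    hist_cluster = pt.xcross_histogram(bubbles, assignment.vertex_to_bin)
    spans_cluster = [pt.bubble_span(b, assignment.vertex_to_bin) for b in bubbles]

    def pct_single(spans: list[int]) -> float:
        return 100.0 * sum(1 for s in spans if s == 1) / len(spans)

    report = BenchReport(
        n_bubbles=len(bubbles),
        mean_span_hash=float(np.mean(spans_hash)),
        mean_span_cluster=float(np.mean(spans_cluster)),
        pct_single_hash=pct_single(spans_hash),
        pct_single_cluster=pct_single(spans_cluster),
        hist_hash=hist_hash,
        hist_cluster=hist_cluster,
    )
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        pt.histogram_to_tsv(hist_hash, out_dir / "xcross_hash.tsv")
        pt.histogram_to_tsv(hist_cluster, out_dir / "xcross_cluster.tsv")
    return report
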