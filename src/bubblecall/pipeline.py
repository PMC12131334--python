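"""End-to-end orchestration: count -> filter -> merge -> graph -> bubbles,
with optional partition diagnostics and per-stage logging.

Partition assignment never influences the bubble set — the superstep
emulation is deterministic by construction — so diagnostics can be turned
on or off (and the partition count varied) without changing the calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import bubbles as bb
from . import graph as gr
from . import kmers as km
from . import partition as pt

logger = logging.getLogger("bubblecall")


@dataclass
class PipelineConfig:
    k: int
    tau: int = 1
    partitioner: str = "hash"  # "hash" | "cluster"
    partitions: int = 1  # computing units P (hash) / units for binning
    bins_per_unit: int = 4  # B = bins_per_unit * partitions (cluster mode)
    cluster_threshold: float | None = None  # required in cluster mode
    cluster_k: int | None = None  # defaults to k
    out_dir: Path | None = None
    output_format: str = "tsv"  # "tsv" | "fasta"

    def validate(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError(f"k must be in [1, 31], got {self.k}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.partitioner not in ("hash", "cluster"):
            raise ValueError(f"unknown partitioner {self.partitioner!r}")
        if self.partitions < 1:
            raise ValueError("partitions must be >= 1")
        if self.partitioner == "cluster" and self.cluster_threshold is None:
            raise ValueError("cluster partitioner requires cluster_threshold")


@dataclass
class PipelineResult:
    bubbles: list[bb.Bubble]
    graph: gr.DeBruijnGraph
    stats: dict[str, int] = field(default_factory=dict)
    vertex_to_partition: dict[int, int] = field(default_factory=dict)
    histogram: Optional[pd.DataFrame] = None  # set when diagnostics ran
    outputs: dict[str, Path] = field(default_factory=dict)

    def call_pairs(self) -> set[tuple[str, str]]:
        return {(b.seq_a, b.seq_b) for b in self.bubbles}


def run_pipeline(
    reads_a: list[str],
    reads_b: list[str],
    config: PipelineConfig,
) -> PipelineResult:
    config.validate()
    k, tau = config.k, config.tau

    ta = km.count_sample(reads_a, k, "A")
    tb = km.count_sample(reads_b, k, "B")
    windows_total = ta.total() + tb.total()
    logger.info("windows extracted: %d (A=%d, B=%d)", windows_total, ta.total(), tb.total())

    fa = km.filter_low_coverage(ta, tau)
    fb = km.filter_low_coverage(tb, tau)
    surviving = fa.total() + fb.total()
    logger.info(
        "windows surviving tau=%d: %d (distinct A=%d, B=%d)",
        tau, surviving, len(fa), len(fb),
    )

    merged = km.merge_samples(fa, fb)
    if not merged.counts:
        logger.warning("no (k+1)-mer survived tau=%d; emitting empty outputs", tau)
    graph = gr.build_graph(merged)
    gr.compute_degrees(graph)
    logger.info("graph: %d vertices, %d edges", graph.n_vertices(), graph.n_edges())

    starts = bb.find_starting_vertices(graph)
    logger.info("starting vertices (outDegree > 1): %d", len(starts))
    found = bb.detect_bubbles(graph, k)
    logger.info("simple bubbles detected: %d", len(found))

    result = PipelineResult(bubbles=found, graph=graph)
    result.stats = {
        "windows_extracted": windows_total,
        "windows_surviving": surviving,
        "distinct_windows": len(merged),
        "vertices": graph.n_vertices(),
        "edges": graph.n_edges(),
        "starting_vertices": len(starts),
        "bubbles": len(found),
    }

    if config.partitioner == "hash":
        result.vertex_to_partition = pt.hash_partition(graph, config.partitions)
    else:
        ck = config.cluster_k if config.cluster_k is not None else k
        clusters = pt.hierarchical_cluster(
            reads_a + reads_b, ck, config.cluster_threshold
        )
        logger.info("read clusters: %d", len(clusters))
        B = config.bins_per_unit * config.partitions
        assignment = pt.cluster_partition(graph, clusters, reads_a + reads_b, B)
        logger.info("LPT makespan over %d bins: %d", B, assignment.makespan)
        result.vertex_to_partition = assignment.vertex_to_bin
    if found and result.vertex_to_partition:
        result.histogram = pt.xcross_histogram(found, result.vertex_to_partition)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.output_format == "fasta":
            p = out / "bubbles.fasta"
            bb.bubbles_to_fasta(found, p)
        else:
            p = out / "bubbles.tsv"
            bb.bubbles_to_tsv(found, k, p)
        result.outputs["bubbles"] = p
        if result.histogram is not None:
            hp = out / "xcross_histogram.tsv"
            pt.histogram_to_tsv(result.histogram, hp)
            result.outputs["histogram"] = hp
    return result
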