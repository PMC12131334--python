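"""Bidirected de Bruijn graph built from surviving (k+1)-mers.

Each surviving (k+1)-mer contributes one directed edge from its length-k
prefix to its length-k suffix, and a second edge for its reverse complement,
so both strands are present as distinct vertices (no canonical collapsing).
Parallel edges collapse to one: bubble detection needs topology only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .kmers import CountTable, decode, revcomp_code


@dataclass
class Vertex:
    """A k-mer vertex with its two centrality indices and partition id."""

    code: int
    in_degree: int = 0
    out_degree: int = 0
    partition: int = 0


@dataclass
class DeBruijnGraph:
    k: int
    vertices: dict[int, Vertex] = field(default_factory=dict)
    # triplet store: (source code, destination code) -> partition id
    triplets: dict[tuple[int, int], int] = field(default_factory=dict)
    _succ: dict[int, tuple[int, ...]] | None = None

    def successors(self, code: int) -> tuple[int, ...]:
        if self._succ is None:
            succ: dict[int, list[int]] = {}
            for (src, dst) in self.triplets:
                succ.setdefault(src, []).append(dst)
            self._succ = {s: tuple(sorted(d)) for s, d in succ.items()}
        return self._succ.get(code, ())

    def n_vertices(self) -> int:
        return len(self.vertices)

    def n_edges(self) -> int:
        return len(self.triplets)


def build_graph(merged: CountTable) -> DeBruijnGraph:
    """Construct the graph from a merged, filtered (k+1)-mer table.

    For each window w: edge prefix(w) -> suffix(w) plus the corresponding
    edge of revcomp(w).  A palindromic window contributes a single edge.
    """
    k = merged.k1 - 1
    g = DeBruijnGraph(k=k)
    mask = (1 << (2 * k)) - 1
    vertices = g.vertices
    edges = g.triplets
    for w in merged.counts:
        for code in (w, revcomp_code(w, k + 1)):
            src = code >> 2
            dst = code & mask
            if src not in vertices:
                vertices[src] = Vertex(src)
            if dst not in vertices:
                vertices[dst] = Vertex(dst)
            edges[(src, dst)] = 0
    return g


def compute_degrees(graph: DeBruijnGraph) -> DeBruijnGraph:
    """Annotate every vertex with inDegree/outDegree from the triplet store."""
    for v in graph.vertices.values():
        v.in_degree = 0
        v.out_degree = 0
    for (src, dst) in graph.triplets:
        graph.vertices[src].out_degree += 1
        graph.vertices[dst].in_degree += 1
    return graph


def write_edgelist(graph: DeBruijnGraph, path: str | Path) -> None:
    """Debug dump: one 'SRC<TAB>DST' line per edge, lexicographic order."""
    k = graph.k
    lines = sorted((decode(s, k), decode(d, k)) for (s, d) in graph.triplets)
    with open(path, "w") as fh:
        for src, dst in lines:
            fh.write(f"{src}\t{dst}\n")


def write_dot(graph: DeBruijnGraph, path: str | Path) -> None:
    k = graph.k
    with open(path, "w") as fh:
        fh.write("digraph dbg {\n")
        for src, dst in sorted(
            (decode(s, k), decode(d, k)) for (s, d) in graph.triplets
        ):
            fh.write(f'  "{src}" -> "{dst}";\n')
        fh.write("}\n")
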