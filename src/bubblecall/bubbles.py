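"""Simple-bubble (isolated SNP) detection by barrier-synchronised supersteps.

An isolated SNP — a substitution at least k bases away from any other
variant — shows up in the de Bruijn graph as a *simple bubble*: two
vertex-disjoint directed paths with k internal vertices each, sharing one
start vertex (outDegree > 1) and one end vertex.  The two assembled branch
sequences have length 2k+1 and differ at exactly the middle position.

Detection mimics a vertex-centric (Pregel-style) message workflow but runs
deterministically: path-building messages are seeded at every vertex with
outDegree > 1 and forwarded along out-edges for k+1 supersteps.  During
supersteps 1..k a message is delivered only to vertices with
inDegree == outDegree == 1 (the interior of a clean branch); superstep k+1
delivers unconditionally, landing on the merge vertex.  The schedule is
fixed by the structure of an isolated SNP: each branch has exactly k
internal vertices, hence k+1 edges to cross.

Message merge order never affects the result — inboxes are processed in
sorted vertex order and the final bubble set is canonicalised — so the
output is identical for any partition count or assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .graph import DeBruijnGraph, compute_degrees
from .kmers import decode, revcomp_seq


@dataclass(frozen=True)
class PathMessage:
    """Payload forwarded along out-edges while a branch path is being built."""

    start: int
    path: tuple[int, ...]  # starting vertex first; len(path) == iteration
    iteration: int


@dataclass(frozen=True)
class Bubble:
    start: int
    end: int
    path_a: tuple[int, ...]  # internal vertices of the branch yielding seq_a
    path_b: tuple[int, ...]
    seq_a: str  # lexicographically <= seq_b
    seq_b: str


def assemble_sequence(path: list[int] | tuple[int, ...], k: int) -> str:
    """Spell the nucleotide string of a walk of k-mer vertex codes.

    Consecutive codes must overlap by k-1 bases; the result has length
    k + (len(path) - 1).
    """
    if not path:
        raise ValueError("empty path")
    mask_km1 = (1 << (2 * (k - 1))) - 1
    seq = [decode(path[0], k)]
    prev = path[0]
    for cur in path[1:]:
        if (prev & mask_km1) != (cur >> 2):
            raise ValueError(
                f"overlap violation: {decode(prev, k)} !~ {decode(cur, k)}"
            )
        seq.append("ACGT"[cur & 3])
        prev = cur
    return "".join(seq)


def find_starting_vertices(graph: DeBruijnGraph) -> set[int]:
    """Vertices where at least two distinct paths originate (outDegree > 1)."""
    return {c for c, v in graph.vertices.items() if v.out_degree > 1}


def run_superstep(
    graph: DeBruijnGraph,
    inbox: dict[int, list[PathMessage]],
    step: int,
    k: int,
    states: dict[int, int] | None = None,
) -> dict[int, list[PathMessage]]:
    """One barrier-synchronised round of message forwarding.

    Every message held by a vertex is forwarded along all its out-edges.
    A message crossing u -> v is delivered iff the degree gate passes
    (supersteps 1..k require inDegree == outDegree == 1 at v; superstep
    k+1 has no gate) and v is not already on the message's path (loop
    protection for repeats).  A delivering vertex appends itself to the
    path, increments the iteration number and records it in its state.
    """
    if states is None:
        states = {}
    new_inbox: dict[int, list[PathMessage]] = {}
    final = step == k + 1
    for u in sorted(inbox):
        for msg in inbox[u]:
            for v in graph.successors(u):
                if not final:
                    vv = graph.vertices[v]
                    if vv.in_degree != 1 or vv.out_degree != 1:
                        continue
                if v in msg.path:
                    continue
                out = PathMessage(msg.start, msg.path + (v,), msg.iteration + 1)
                new_inbox.setdefault(v, []).append(out)
                states[v] = out.iteration
    return new_inbox


def detect_bubbles(graph: DeBruijnGraph, k: int | None = None) -> list[Bubble]:
    """All simple bubbles, strand-deduplicated, in canonical order.

    Seeds a message at every starting vertex, runs k+1 supersteps, then
    pairs up equal-length vertex-disjoint paths that reached the same
    terminal from the same start.  A bubble and its reverse-complement
    mirror are the same SNP; the representative kept is the orientation
    whose sorted sequence pair is lexicographically smallest.
    """
    if k is None:
        k = graph.k
    compute_degrees(graph)
    starts = find_starting_vertices(graph)
    inbox: dict[int, list[PathMessage]] = {
        s: [PathMessage(s, (s,), 1)] for s in sorted(starts)
    }
    states: dict[int, int] = {}
    for step in range(1, k + 2):
        inbox = run_superstep(graph, inbox, step, k, states)
        if not inbox:
            break

    # group surviving full-length paths by (terminal, start)
    groups: dict[tuple[int, int], list[tuple[int, ...]]] = {}
    for terminal in sorted(inbox):
        for msg in inbox[terminal]:
            if len(msg.path) == k + 2:
                groups.setdefault((terminal, msg.start), []).append(msg.path)

    chosen: dict[tuple[str, str], Bubble] = {}
    for (terminal, start), paths in sorted(groups.items()):
        paths = sorted(set(paths))
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                pa, pb = paths[i], paths[j]
                ia, ib = set(pa[1:-1]), set(pb[1:-1])
                if ia & ib:
                    continue
                sa = assemble_sequence(pa, k)
                sb = assemble_sequence(pb, k)
                if sb < sa:
                    sa, sb = sb, sa
                    pa, pb = pb, pa
                pair = (sa, sb)
                mirror = tuple(sorted((revcomp_seq(sa), revcomp_seq(sb))))
                canon = min(pair, mirror)
                bub = Bubble(start, terminal, pa[1:-1], pb[1:-1], sa, sb)
                prev = chosen.get(canon)
                if prev is None:
                    chosen[canon] = bub
                else:
                    # prefer the orientation matching the canonical pair,
                    # then the smallest (start, end) for determinism
                    def rank(b: Bubble) -> tuple:
                        return ((b.seq_a, b.seq_b) != canon, b.start, b.end)

                    if rank(bub) < rank(prev):
                        chosen[canon] = bub
    return [chosen[key] for key in sorted(chosen)]


def canonical_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Strand-neutral representative of an unordered sequence pair."""
    pair = tuple(sorted((seq_a.upper(), seq_b.upper())))
    mirror = tuple(sorted((revcomp_seq(seq_a), revcomp_seq(seq_b))))
    return min(pair, mirror)


def bubbles_to_tsv(bubbles: list[Bubble], k: int, path: str | Path) -> None:
    """bubble_id, seq_a, seq_b, start_kmer, end_kmer — one row per SNP."""
    with open(path, "w") as fh:
        fh.write("bubble_id\tseq_a\tseq_b\tstart_kmer\tend_kmer\n")
        for i, b in enumerate(bubbles):
            fh.write(
                f"{i}\t{b.seq_a}\t{b.seq_b}\t{decode(b.start, k)}\t{decode(b.end, k)}\n"
            )


def bubbles_to_fasta(bubbles: list[Bubble], path: str | Path) -> None:
    """Paired-FASTA output: records '<n>_a' and '<n>_b' per bubble."""
    with open(path, "w") as fh:
        for i, b in enumerate(bubbles):
            fh.write(f">{i}_a\n{b.seq_a}\n>{i}_b\n{b.seq_b}\n")
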