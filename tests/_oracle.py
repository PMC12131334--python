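"""Independent brute-force oracle for simple-bubble enumeration.

Works directly on the triplet (edge) set with its own degree counting,
path enumeration, sequence assembly and strand canonicalisation — no code
shared with the superstep implementation beyond the 2-bit decode table.
"""

from __future__ import annotations

from itertools import combinations

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _decode(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _assemble(path: tuple[int, ...], k: int) -> str:
    seq = _decode(path[0], k)
    for code in path[1:]:
        seq += _BASES[code & 3]
    return seq


def canonical(seq_a: str, seq_b: str) -> tuple[str, str]:
    fwd = tuple(sorted((seq_a, seq_b)))
    rev = tuple(sorted((_revcomp(seq_a), _revcomp(seq_b))))
    return min(fwd, rev)


def brute_force_bubbles(edges, k: int) -> set[tuple[str, str]]:
    """Canonical sequence pairs of all simple bubbles in an edge set.

    A simple bubble is an unordered pair of vertex-disjoint directed paths
    with exactly k internal vertices (each internal vertex having
    inDegree == outDegree == 1) from a vertex with outDegree > 1 to a
    common terminal, deduplicated across strands.
    """
    edges = set(edges)
    indeg: dict[int, int] = {}
    outdeg: dict[int, int] = {}
    succ: dict[int, list[int]] = {}
    for src, dst in edges:
        outdeg[src] = outdeg.get(src, 0) + 1
        indeg[dst] = indeg.get(dst, 0) + 1
        indeg.setdefault(src, 0)
        outdeg.setdefault(dst, 0)
        succ.setdefault(src, []).append(dst)

    def paths_from(start: int):
        # yields full paths start -> (k internal, clean) -> end
        stack = [(start,)]
        while stack:
            path = stack.pop()
            n_internal = len(path) - 1
            for v in succ.get(path[-1], ()):
                if v in path:
                    continue
                if n_internal < k:
                    if indeg.get(v, 0) == 1 and outdeg.get(v, 0) == 1:
                        stack.append(path + (v,))
                else:
                    yield path + (v,)

    found: set[tuple[str, str]] = set()
    for start, d in outdeg.items():
        if d <= 1:
            continue
        by_end: dict[int, list[tuple[int, ...]]] = {}
        for path in paths_from(start):
            by_end.setdefault(path[-1], []).append(path)
        for end, paths in by_end.items():
            for pa, pb in combinations(sorted(set(paths)), 2):
                if set(pa[1:-1]) & set(pb[1:-1]):
                    continue
                found.add(canonical(_assemble(pa, k), _assemble(pb, k)))
    return found
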