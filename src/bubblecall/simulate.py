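"""Seeded two-sample read simulator with planted isolated SNPs.

Emulates the two-individual design used to benchmark reference-free SNP
callers: sample A is sequenced from a reference genome, sample B from an
alternative genome that differs at n planted positions, every pair of which
is more than k bases apart so each SNP forms a clean simple bubble.  Reads
are sampled uniformly, from either strand, with optional i.i.d. base
substitution errors; truth contexts (the two length-(2k+1) windows centred
on each SNP) are recorded for precision/recall scoring.

All stages draw from independent child seeds of one master seed, so the
genome, the SNP placement and each read set vary independently and every
output is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kmers import revcomp_seq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Requested SNP density cannot satisfy the isolation constraint."""


@dataclass(frozen=True)
class PlantedTruth:
    """Machine-readable ground truth for one simulated sample pair."""

    positions: tuple[int, ...]  # 0-based, sorted
    alleles: tuple[tuple[str, str], ...]  # (ref_base, alt_base) per position
    contexts: tuple[tuple[str, str], ...]  # (ref, alt) length-(2k+1) windows
    k: int


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def simulate_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. ACGT string of the given length."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def plant_snps(
    genome: str,
    n: int,
    k: int,
    seed: int,
    margin: int | None = None,
) -> tuple[str, PlantedTruth]:
    """Plant n isolated substitutions (pairwise distance > k) in ``genome``.

    Positions are rejection-sampled from [margin, L-1-margin]; ``margin``
    defaults to k so every SNP has a full 2k+1 context.  A larger margin
    (e.g. the read length) keeps SNPs away from the coverage drop-off at
    the genome ends.  Raises :class:`PlacementError` when the density is
    infeasible after bounded retries.
    """
    L = len(genome)
    if margin is None:
        margin = k
    margin = max(margin, k)
    if L < 2 * k + 1:
        raise ValueError(f"genome length {L} < 2k+1 = {2 * k + 1}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n == 0:
        return genome, PlantedTruth((), (), (), k)
    lo, hi = margin, L - 1 - margin
    if hi < lo:
        raise PlacementError("genome too short for the requested margin")

    positions: list[int] = []
    for _ in range(1000 * max(n, 1)):
        p = int(rng.integers(lo, hi + 1))
        if all(abs(p - q) > k for q in positions):
            positions.append(p)
            if len(positions) == n:
                break
    else:
        raise PlacementError(
            f"could not place {n} SNPs with spacing > {k} in {L} bases"
        )
    positions.sort()

    alt = list(genome)
    alleles = []
    for p in positions:
        ref = genome[p]
        choices = [b for b in "ACGT" if b != ref]
        alleles.append((ref, choices[int(rng.integers(0, 3))]))
        alt[p] = alleles[-1][1]
    alt_genome = "".join(alt)
    contexts = tuple(
        (genome[p - k : p + k + 1], alt_genome[p - k : p + k + 1])
        for p in positions
    )
    return alt_genome, PlantedTruth(tuple(positions), tuple(alleles), contexts, k)


def simulate_reads(
    genome: str,
    read_len: int,
    coverage: float,
    error_rate: float,
    seed: int,
) -> list[str]:
    """Uniform shotgun reads: ceil(coverage*L/read_len) reads, either strand.

    Each base is substituted to a uniformly chosen different base with
    probability ``error_rate``.
    """
    L = len(genome)
    if read_len > L:
        raise ValueError(f"read length {read_len} exceeds genome length {L}")
    n_reads = math.ceil(coverage * L / read_len)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads = []
    for s, rc in zip(starts.tolist(), strands.tolist()):
        seq = genome[s : s + read_len]
        if rc:
            seq = revcomp_seq(seq)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(read_len) < error_rate)
            if hits.size:
                # shift by 1..3 in base space: always a different base
                vals = np.searchsorted(_BASES, arr[hits])
                vals = (vals + rng.integers(1, 4, size=hits.size)) % 4
                arr[hits] = _BASES[vals]
                seq = arr.tobytes().decode("ascii")
        reads.append(seq)
    return reads


def simulate_sample_pair(
    genome_length: int,
    n_snps: int,
    k: int,
    read_len: int,
    coverage: float,
    error_rate: float,
    seed: int,
    margin: int | None = None,
) -> tuple[list[str], list[str], PlantedTruth]:
    """Full two-individual experiment: (reads_a, reads_b, truth)."""
    g_rng, s_rng, ra_rng, rb_rng = np.random.SeedSequence(seed).spawn(4)
    genome = simulate_genome(genome_length, _seq_to_seed(g_rng))
    alt, truth = plant_snps(genome, n_snps, k, _seq_to_seed(s_rng), margin=margin)
    reads_a = simulate_reads(genome, read_len, coverage, error_rate, _seq_to_seed(ra_rng))
    reads_b = simulate_reads(alt, read_len, coverage, error_rate, _seq_to_seed(rb_rng))
    return reads_a, reads_b, truth


def _seq_to_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(reads: list[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f">{prefix}_{i}\n{seq}\n")


def write_fastq(reads: list[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """TSV: pos, ref, alt, context_ref, context_alt."""
    with open(path, "w") as fh:
        fh.write("pos\tref\talt\tcontext_ref\tcontext_alt\n")
        for p, (ref, alt), (cr, ca) in zip(
            truth.positions, truth.alleles, truth.contexts
        ):
            fh.write(f"{p}\t{ref}\t{alt}\t{cr}\t{ca}\n")


def read_truth(path: str | Path) -> PlantedTruth:
    positions, alleles, contexts = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pos\t"):
            raise ValueError(f"{path}: not a truth TSV")
        for line in fh:
            p, ref, alt, cr, ca = line.rstrip("\n").split("\t")
            positions.append(int(p))
            alleles.append((ref, alt))
            contexts.append((cr, ca))
    k = (len(contexts[0][0]) - 1) // 2 if contexts else 0
    return PlantedTruth(tuple(positions), tuple(alleles), tuple(contexts), k)
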