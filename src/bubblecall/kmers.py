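"""2-bit k-mer encoding, window extraction and coverage-filtered counting.

Every k-mer (and (k+1)-mer) is packed into a single unsigned integer using
two bits per base (A=0, C=1, G=2, T=3), with the 5' end of the sequence in
the most significant bits.  A window of up to 32 bases therefore fits one
64-bit word, which caps the usable graph order at k <= 31 because edges are
represented by (k+1)-mers.

Counting is vectorised with numpy: all reads of a sample are joined with a
sentinel character, base values are looked up in a table, window codes are
accumulated with shifts, and windows touching a non-ACGT character are
masked out before the final ``np.unique`` tally.
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

MAX_LENGTH = 32  # one 64-bit word at 2 bits/base

_BASE_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_BASE = "ACGT"

# byte value -> 2-bit base code, 255 for anything not ACGT/acgt
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in _BASE_BITS.items():
    _LUT[ord(_b)] = _v
    _LUT[ord(_b.lower())] = _v


class KmerSizeError(ValueError):
    """Sequence length outside the representable range [1, 32]."""


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T}."""


@dataclass(frozen=True, order=True)
class KmerRecord:
    """A fixed-width nucleotide word: packed 2-bit code plus its length."""

    code: int
    length: int

    def __post_init__(self) -> None:
        if not 1 <= self.length <= MAX_LENGTH:
            raise KmerSizeError(f"length {self.length} outside [1, {MAX_LENGTH}]")
        if not 0 <= self.code < (1 << (2 * self.length)):
            raise ValueError(f"code {self.code} does not fit {self.length} bases")

    def __str__(self) -> str:
        return decode(self.code, self.length)


def encode_kmer(sequence: str) -> KmerRecord:
    """Pack an ACGT string (case-insensitive) into a :class:`KmerRecord`."""
    n = len(sequence)
    if not 1 <= n <= MAX_LENGTH:
        raise KmerSizeError(f"sequence length {n} outside [1, {MAX_LENGTH}]")
    code = 0
    for ch in sequence.upper():
        try:
            code = (code << 2) | _BASE_BITS[ch]
        except KeyError:
            raise AlphabetError(f"non-ACGT character {ch!r} in {sequence!r}") from None
    return KmerRecord(code, n)


def decode(code: int, length: int) -> str:
    """Inverse of :func:`encode_kmer` on a raw (code, length) pair."""
    chars = []
    for shift in range(2 * (length - 1), -1, -2):
        chars.append(_BITS_BASE[(code >> shift) & 3])
    return "".join(chars)


def decode_kmer(kmer: KmerRecord) -> str:
    return decode(kmer.code, kmer.length)


def revcomp_code(code: int, length: int) -> int:
    """Reverse complement on the packed representation (A<->T, C<->G)."""
    out = 0
    for _ in range(length):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def reverse_complement(kmer: KmerRecord) -> KmerRecord:
    return KmerRecord(revcomp_code(kmer.code, kmer.length), kmer.length)


def revcomp_seq(sequence: str) -> str:
    """Reverse complement of a plain string (any length, ACGT only)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[ch] for ch in reversed(sequence.upper()))


# ---------------------------------------------------------------------------
# window extraction and counting
# ---------------------------------------------------------------------------


def _window_codes(reads: Iterable[str], w: int) -> np.ndarray:
    """All valid length-``w`` window codes across ``reads``, in read order.

    Reads are joined with a sentinel byte so a single vectorised pass covers
    the whole sample; windows containing the sentinel or any non-ACGT
    character are dropped.
    """
    if not 1 <= w <= MAX_LENGTH:
        raise KmerSizeError(f"window length {w} outside [1, {MAX_LENGTH}]")
    blob = "\n".join(reads)
    if len(blob) < w:
        return np.empty(0, dtype=np.uint64)
    vals = _LUT[np.frombuffer(blob.encode("ascii"), dtype=np.uint8)]
    n = vals.size - w + 1
    bad = (vals > 3).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    clean = (cum[w:] - cum[:-w]) == 0  # no bad base inside the window
    v64 = (vals & 3).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(w):
        codes = (codes << np.uint64(2)) | v64[j : j + n]
    return codes[clean]


def extract_windows(read: str, w: int) -> list[KmerRecord]:
    """All length-``w`` substrings of ``read`` left to right.

    Windows overlapping a non-ACGT character are skipped, so an N-free read
    of length L yields exactly max(0, L - w + 1) records.
    """
    return [KmerRecord(int(c), w) for c in _window_codes([read], w)]


@dataclass
class CountTable:
    """Frequencies of (k+1)-mers observed in one sample (or a merged pool)."""

    k1: int
    counts: dict[int, int] = field(default_factory=dict)
    sample_label: str = ""

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())


def count_sample(reads: Sequence[str], k: int, sample_label: str = "") -> CountTable:
    """Count every (k+1)-mer window across all reads of one sample."""
    if not 1 <= k <= MAX_LENGTH - 1:
        raise KmerSizeError(f"k {k} outside [1, {MAX_LENGTH - 1}]")
    w = k + 1
    codes = _window_codes(reads, w)
    if codes.size == 0:
        return CountTable(w, {}, sample_label)
    uniq, freq = np.unique(codes, return_counts=True)
    return CountTable(w, dict(zip(uniq.tolist(), freq.tolist())), sample_label)


def filter_low_coverage(table: CountTable, tau: int) -> CountTable:
    """Drop windows observed fewer than ``tau`` times (sequencing errors)."""
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    kept = {c: f for c, f in table.counts.items() if f >= tau}
    return CountTable(table.k1, kept, table.sample_label)


def merge_samples(a: CountTable, b: CountTable) -> CountTable:
    """Pool two per-sample tables: key union, frequencies summed."""
    if a.k1 != b.k1:
        raise ValueError(f"window length mismatch: {a.k1} != {b.k1}")
    merged = dict(a.counts)
    for code, freq in b.counts.items():
        merged[code] = merged.get(code, 0) + freq
    label = "+".join(s for s in (a.sample_label, b.sample_label) if s)
    return CountTable(a.k1, merged, label)


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------


def read_sequences(path: str | Path) -> list[str]:
    """Load reads from FASTA or FASTQ, plain or gzip; qualities are ignored."""
    path = Path(path)
    name = path.name.lower()
    gz = name.endswith(".gz")
    stem = name[:-3] if gz else name
    if stem.endswith((".fq", ".fastq")):
        fmt = "fastq"
    elif stem.endswith((".fa", ".fasta", ".fna")):
        fmt = "fasta"
    else:
        raise ValueError(f"cannot infer FASTA/FASTQ format from {path.name!r}")
    opener = gzip.open if gz else open
    with opener(path, "rt") as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]
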