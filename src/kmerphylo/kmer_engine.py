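"""k-mer counting and dinucleotide-based partition of the k-mer universe.

k-mers are indexed by the canonical 2-bit encoding A=0, C=1, G=2, T=3 with
the most significant base first, i.e. lexicographic order over the 4^k
universe. Counting slides a window of k bp with step 1 bp over each record
(forward strand; windows never span record boundaries; any window touching
a non-ACGT base is skipped).

Every k-mer is assigned to a class by the number of occurrences of an
ordered dinucleotide XY it contains, overlaps counted: class 0 (none),
class 1 (exactly one), class 2 (two or more). At k=8 this gives the subset
sizes (40545, 21468, 3523) for X≠Y and (44631, 14931, 5974) for X=Y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genome_io import Genome

__all__ = [
    "BASES",
    "KmerCountVector",
    "SubsetPartition",
    "encode_kmer",
    "decode_kmer",
    "count_kmers",
    "dinucleotide_occurrences",
    "partition_by_dinucleotide",
    "minimum_k",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte -> 2-bit code; 255 marks anything that is not an unambiguous base
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i


class NoCountableWindowsError(ValueError):
    """Genome contains no window of k unambiguous bases."""


@dataclass(frozen=True)
class KmerCountVector:
    """Dense occurrence counts over the full 4^k k-mer universe."""

    k: int
    taxon_id: str
    counts: np.ndarray  # int64, length 4^k, lexicographic k-mer order
    total_windows: int

    def __post_init__(self) -> None:
        if self.counts.shape != (4**self.k,):
            raise ValueError("counts length must be 4^k")
        if int(self.counts.sum()) != self.total_windows:
            raise ValueError("sum of counts must equal total_windows")


@dataclass(frozen=True)
class SubsetPartition:
    """Class (0/1/2) of every k-mer for one ordered dinucleotide XY."""

    k: int
    xy: str
    class_of: np.ndarray  # uint8, length 4^k
    sizes: tuple[int, int, int]

    def members(self, class_i: int) -> np.ndarray:
        """Sorted k-mer indices belonging to class ``class_i``."""
        if class_i not in (0, 1, 2):
            raise ValueError("class must be 0, 1 or 2")
        return np.flatnonzero(self.class_of == class_i)


def encode_kmer(s: str) -> int:
    """Map a k-length ACGT string to its index in [0, 4^k)."""
    idx = 0
    for ch in s:
        try:
            idx = (idx << 2) | _BASE_INDEX[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {s!r}") from None
    return idx


def decode_kmer(index: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= index < 4**k:
        raise ValueError(f"index {index} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(index >> shift) & 3])
    return "".join(out)


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _record_codes(sequence: str) -> np.ndarray:
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def count_kmers(genome: Genome, k: int = 8) -> KmerCountVector:
    """Count k-mer occurrences by sliding a k bp window with step 1 bp.

    Counts are aggregated over all records; windows never span record
    boundaries; windows containing any non-ACGT character are skipped and
    excluded from ``total_windows``. Forward strand only.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    total = 0
    for rec in genome.records:
        if rec.length < k:
            continue
        codes = _record_codes(rec.sequence)
        valid = codes < 4
        n = rec.length - k + 1
        window_codes = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        safe = np.where(valid, codes, 0).astype(np.int64)
        for j in range(k):
            window_codes = (window_codes << 2) | safe[j : j + n]
            ok &= valid[j : j + n]
        kept = window_codes[ok]
        counts += np.bincount(kept, minlength=4**k)
        total += int(ok.sum())
    if total == 0:
        raise NoCountableWindowsError(
            f"genome {genome.taxon_id!r}: no countable windows at k={k}"
        )
    return KmerCountVector(k=k, taxon_id=genome.taxon_id, counts=counts, total_windows=total)


def dinucleotide_occurrences(kmer: str, xy: str) -> int:
    """Number of (possibly overlapping) occurrences of XY in a k-mer."""
    if len(xy) != 2 or any(c not in _BASE_INDEX for c in xy):
        raise ValueError(f"xy must be an ordered dinucleotide over ACGT, got {xy!r}")
    if any(c not in _BASE_INDEX for c in kmer):
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    return sum(1 for p in range(len(kmer) - 1) if kmer[p : p + 2] == xy)


@lru_cache(maxsize=64)
def partition_by_dinucleotide(k: int, xy: str) -> SubsetPartition:
    """Classify all 4^k k-mers by their XY content: min(2, occurrences)."""
    if k < 2:
        raise ValueError("k must be >= 2 to contain a dinucleotide")
    if len(xy) != 2 or any(c not in _BASE_INDEX for c in xy):
        raise ValueError(f"xy must be an ordered dinucleotide over ACGT, got {xy!r}")
    idx = np.arange(4**k, dtype=np.int64)
    digits = np.empty((k, 4**k), dtype=np.uint8)
    for j in range(k):
        digits[j] = (idx >> (2 * (k - 1 - j))) & 3
    x, y = _BASE_INDEX[xy[0]], _BASE_INDEX[xy[1]]
    occ = np.zeros(4**k, dtype=np.int64)
    for j in range(k - 1):
        occ += (digits[j] == x) & (digits[j + 1] == y)
    class_of = np.minimum(occ, 2).astype(np.uint8)
    sizes = tuple(int((class_of == c).sum()) for c in (0, 1, 2))
    return SubsetPartition(k=k, xy=xy, class_of=class_of, sizes=sizes)


def minimum_k(L: int) -> int:
    """Minimum informative k for a sequence of length L bp: ceil(0.7·log4 L).

    Below this k the 4^k universe is small enough that k-mer frequencies
    saturate; above it some k-mers fail to occur at all. Yields k >= 8 for
    eukaryote-sized genomes and k >= 6 for prokaryote-sized ones.
    """
    if L < 2:
        raise ValueError("sequence length must be >= 2")
    val = 0.7 * (math.log2(L) / 2)
    # tiny back-off so exact integer values (L a power of 4) are not pushed
    # up by float representation error
    return math.ceil(val - 1e-9)
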