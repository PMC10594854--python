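"""Rank ("relative frequency") feature vectors and RMSE distance matrices.

The members of a named 8-mer feature set are sorted by their actual
occurrence counts from small to large, and the numerical order (1-based
rank) is the feature value: the relative frequency. Distances between two
genomes a, b over a shared feature set of size N are

    D_ab = sqrt( Σ_i (x_ai − x_bi)² / N )

the root-mean-square difference of feature values — a Euclidean metric
scaled by 1/√N.

Presets: CG12 (CG1 ∪ CG2, the evolution-correlated CG-containing 8-mers,
N = 24,991 at k = 8), TA12 (its TA counterpart, same size), CG0
(N = 40,545) and TOTAL (all 4^k).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .kmer_engine import KmerCountVector, partition_by_dinucleotide

__all__ = [
    "FeatureSetSpec",
    "FeatureVector",
    "DistanceMatrix",
    "PRESET_FEATURE_SETS",
    "build_feature_set",
    "relative_frequency",
    "pairwise_distance",
    "distance_matrix",
    "write_phylip",
    "read_phylip",
]

PRESET_FEATURE_SETS = {
    "CG12": ("CG", (1, 2)),
    "TA12": ("TA", (1, 2)),
    "CG0": ("CG", (0,)),
    "TOTAL": None,
}


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named subset of the k-mer universe used as the feature space."""

    name: str
    k: int
    member_indices: np.ndarray  # sorted, strictly increasing
    member_classes: np.ndarray | None = None  # class label per member (for per-class ranking)

    @property
    def size(self) -> int:
        return int(self.member_indices.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureSetSpec):
            return NotImplemented
        return (
            self.name == other.name
            and self.k == other.k
            and np.array_equal(self.member_indices, other.member_indices)
        )


@dataclass(frozen=True)
class FeatureVector:
    """Per-genome ranks over a feature set, aligned to its member order."""

    taxon_id: str
    spec: FeatureSetSpec
    ranks: np.ndarray  # float64; a permutation of 1..N under the ordinal policy
    tie_policy: str
    rank_scope: str = "union"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric taxon-by-taxon distance matrix with zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match the number of taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels in distance matrix")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def build_feature_set(
    k: int,
    name_or_custom: str | tuple[str, Iterable[int]],
) -> FeatureSetSpec:
    """Resolve a preset name (CG12, TA12, CG0, TOTAL) or a custom (xy, classes)."""
    if isinstance(name_or_custom, str):
        name = name_or_custom.upper()
        if name not in PRESET_FEATURE_SETS:
            raise ValueError(
                f"unknown feature set {name_or_custom!r}; "
                f"presets are {sorted(PRESET_FEATURE_SETS)}"
            )
        if name == "TOTAL":
            idx = np.arange(4**k, dtype=np.int64)
            return FeatureSetSpec(name="TOTAL", k=k, member_indices=idx,
                                  member_classes=np.zeros(idx.size, dtype=np.uint8))
        xy, classes = PRESET_FEATURE_SETS[name]
    else:
        xy, classes = name_or_custom
        classes = tuple(sorted(set(int(c) for c in classes)))
        if not classes or any(c not in (0, 1, 2) for c in classes):
            raise ValueError("custom classes must be a non-empty subset of {0,1,2}")
        name = xy.upper() + "".join(str(c) for c in classes)
    partition = partition_by_dinucleotide(k, xy.upper())
    mask = np.isin(partition.class_of, list(classes))
    idx = np.flatnonzero(mask).astype(np.int64)
    return FeatureSetSpec(
        name=name, k=k, member_indices=idx,
        member_classes=partition.class_of[idx].copy(),
    )


def _rank_ascending(values: np.ndarray, indices: np.ndarray, tie_policy: str) -> np.ndarray:
    if tie_policy == "ordinal":
        # sort by (count, k-mer index); lexsort keys are last-key-primary
        order = np.lexsort((indices, values))
        ranks = np.empty(values.size, dtype=np.float64)
        ranks[order] = np.arange(1, values.size + 1, dtype=np.float64)
        return ranks
    if tie_policy == "average":
        return rankdata(values, method="average")
    raise ValueError(f"tie_policy must be 'ordinal' or 'average', got {tie_policy!r}")


def relative_frequency(
    counts: KmerCountVector,
    spec: FeatureSetSpec,
    tie_policy: str = "ordinal",
    rank_scope: str = "union",
) -> FeatureVector:
    """Transform member counts into ascending 1-based ranks.

    Under the default ordinal policy, count ties are broken by ascending
    k-mer index, so the ranks are a deterministic permutation of 1..N.
    The average policy assigns the mean rank within each tie group.
    ``rank_scope='per-class'`` ranks each partition class separately
    (1..N_c within class c) instead of jointly over the union.
    """
    if spec.k != counts.k:
        raise ValueError(f"feature set has k={spec.k} but counts have k={counts.k}")
    member_counts = counts.counts[spec.member_indices].astype(np.float64)
    if rank_scope == "union":
        ranks = _rank_ascending(member_counts, spec.member_indices, tie_policy)
    elif rank_scope == "per-class":
        if spec.member_classes is None:
            raise ValueError("per-class ranking needs class labels in the feature set")
        ranks = np.empty(member_counts.size, dtype=np.float64)
        for c in np.unique(spec.member_classes):
            sel = spec.member_classes == c
            ranks[sel] = _rank_ascending(
                member_counts[sel], spec.member_indices[sel], tie_policy
            )
    else:
        raise ValueError(f"rank_scope must be 'union' or 'per-class', got {rank_scope!r}")
    return FeatureVector(
        taxon_id=counts.taxon_id, spec=spec, ranks=ranks,
        tie_policy=tie_policy, rank_scope=rank_scope,
    )


def _check_comparable(fa: FeatureVector, fb: FeatureVector) -> None:
    if fa.spec != fb.spec or fa.tie_policy != fb.tie_policy or fa.rank_scope != fb.rank_scope:
        raise ValueError(
            f"feature vectors are not comparable: "
            f"{fa.taxon_id!r} ({fa.spec.name}, {fa.tie_policy}, {fa.rank_scope}) vs "
            f"{fb.taxon_id!r} ({fb.spec.name}, {fb.tie_policy}, {fb.rank_scope})"
        )


def pairwise_distance(fa: FeatureVector, fb: FeatureVector) -> float:
    """Root-mean-square rank difference between two genomes."""
    _check_comparable(fa, fb)
    diff = fa.ranks - fb.ranks
    return float(np.sqrt(np.mean(diff * diff)))


def distance_matrix(features: Sequence[FeatureVector]) -> DistanceMatrix:
    """All-pairs RMSE distances; input taxon order is preserved."""
    if len(features) < 3:
        raise ValueError("need at least 3 taxa to build a distance matrix")
    taxa = tuple(f.taxon_id for f in features)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon_id among feature vectors")
    for f in features[1:]:
        _check_comparable(features[0], f)
    n = len(features)
    d = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(features[i], features[j])
    return DistanceMatrix(taxa=taxa, d=d)


_PHYLIP_NAME_RE = re.compile(r"^\S{1,50}$")


def write_phylip(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    """Write a square (full) relaxed-PHYLIP distance matrix, 6 decimals."""
    for name in dm.taxa:
        if not _PHYLIP_NAME_RE.match(name):
            raise ValueError(
                f"taxon name {name!r} is not a valid relaxed-PHYLIP name "
                "(1-50 characters, no whitespace)"
            )
    width = max(10, max(len(t) for t in dm.taxa) + 2)
    with open(path, "w") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for name, row in zip(dm.taxa, dm.d):
            cells = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{name:<{width}}{cells}\n")


def read_phylip(path: str | os.PathLike) -> DistanceMatrix:
    """Read a square relaxed-PHYLIP distance matrix."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty PHYLIP file: {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"malformed PHYLIP header line: {lines[0]!r}") from None
    if len(lines) - 1 != n:
        raise ValueError(f"expected {n} matrix rows, found {len(lines) - 1}")
    taxa, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(f"row has {len(parts) - 1} distances, expected {n}: {ln!r}")
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    d = np.asarray(rows, dtype=np.float64)
    d = (d + d.T) / 2  # fold away printed-precision asymmetry
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa=tuple(taxa), d=d)
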