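"""Subset spectra (relative motif number) and separability δ.

For a genome's k-mer counts and an XYi subset, the spectrum is the
histogram N_i = number of subset k-mers occurring exactly i times,
expressed relative to the universe as RMN = N_i / 4^k. The random center
x̄ = total_windows / 4^k is the mean count over all k-mers; the
separability of a subset is

    δ_XYi = x̄ / x̄_XYi

where x̄_XYi is the subset's mean count (zero-count members included in
the denominator, so all 48 values stay well defined). δ > 1 places the
subset at the low-frequency end of the spectrum; δ = 1 means it sits on
the random center.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmer_engine import BASES, KmerCountVector, SubsetPartition, partition_by_dinucleotide

__all__ = [
    "Spectrum",
    "SeparabilityTable",
    "ALL_DINUCLEOTIDES",
    "rmn_spectrum",
    "global_mean",
    "subset_mean",
    "separability",
    "separability_table",
]

#: The 16 ordered dinucleotides, each defining 3 subset classes (48 subsets).
ALL_DINUCLEOTIDES = tuple(a + b for a, b in itertools.product(BASES, repeat=2))


class EmptySubsetError(ValueError):
    """Subset has no members (possible only at small k)."""


@dataclass(frozen=True)
class Spectrum:
    """Occurrence histogram of one XYi subset in one genome."""

    taxon_id: str
    xy: str
    class_i: int
    subset_size: int
    histogram: dict[int, int]  # occurrence count -> N_i (N_0 included)
    rmn: dict[int, float]  # occurrence count -> N_i / 4^k


@dataclass(frozen=True)
class SeparabilityTable:
    """δ for all 48 XYi subsets of one genome."""

    taxon_id: str
    global_mean: float
    entries: pd.DataFrame  # columns: xy, class, subset_size, subset_mean, delta


def _check_compatible(counts: KmerCountVector, partition: SubsetPartition) -> None:
    if counts.k != partition.k:
        raise ValueError(
            f"counts have k={counts.k} but partition has k={partition.k}"
        )


def rmn_spectrum(
    counts: KmerCountVector, partition: SubsetPartition, class_i: int
) -> Spectrum:
    """Histogram of exact occurrence counts over one subset's members.

    Members absent from the genome contribute to the zero bin.
    """
    _check_compatible(counts, partition)
    members = partition.members(class_i)
    if members.size == 0:
        raise EmptySubsetError(f"subset {partition.xy}{class_i} is empty at k={counts.k}")
    member_counts = counts.counts[members]
    values, freqs = np.unique(member_counts, return_counts=True)
    universe = 4**counts.k
    histogram = {int(v): int(f) for v, f in zip(values, freqs)}
    rmn = {int(v): int(f) / universe for v, f in zip(values, freqs)}
    return Spectrum(
        taxon_id=counts.taxon_id,
        xy=partition.xy,
        class_i=class_i,
        subset_size=int(members.size),
        histogram=histogram,
        rmn=rmn,
    )


def global_mean(counts: KmerCountVector) -> float:
    """The random center x̄: mean occurrence count over all 4^k k-mers."""
    return counts.total_windows / 4**counts.k


def subset_mean(
    counts: KmerCountVector, partition: SubsetPartition, class_i: int
) -> float:
    """Mean occurrence count over subset members, zero counts included."""
    _check_compatible(counts, partition)
    members = partition.members(class_i)
    if members.size == 0:
        raise EmptySubsetError(f"subset {partition.xy}{class_i} is empty at k={counts.k}")
    return float(counts.counts[members].sum()) / members.size


def separability(
    counts: KmerCountVector, partition: SubsetPartition, class_i: int
) -> float | None:
    """δ_XYi = x̄ / x̄_XYi; ``None`` (undefined, not ∞) for an all-zero subset."""
    mean_i = subset_mean(counts, partition, class_i)
    if mean_i == 0.0:
        warnings.warn(
            f"subset {partition.xy}{class_i} has zero mean count in "
            f"{counts.taxon_id!r}; δ undefined",
            stacklevel=2,
        )
        return None
    return global_mean(counts) / mean_i


def separability_table(counts: KmerCountVector) -> SeparabilityTable:
    """δ for every (xy, class) pair: 48 entries in 16 dinucleotide groups."""
    if counts.k < 2:
        raise ValueError("separability requires k >= 2")
    xbar = global_mean(counts)
    rows = []
    for xy in ALL_DINUCLEOTIDES:
        partition = partition_by_dinucleotide(counts.k, xy)
        for class_i in (0, 1, 2):
            size = partition.sizes[class_i]
            if size == 0:
                rows.append(
                    {"xy": xy, "class": class_i, "subset_size": 0,
                     "subset_mean": np.nan, "delta": np.nan}
                )
                continue
            mean_i = subset_mean(counts, partition, class_i)
            delta = xbar / mean_i if mean_i > 0 else np.nan
            if mean_i == 0:
                warnings.warn(
                    f"subset {xy}{class_i} has zero mean count in "
                    f"{counts.taxon_id!r}; δ undefined",
                    stacklevel=2,
                )
            rows.append(
                {"xy": xy, "class": class_i, "subset_size": size,
                 "subset_mean": mean_i, "delta": delta}
            )
    entries = pd.DataFrame(rows, columns=["xy", "class", "subset_size", "subset_mean", "delta"])
    return SeparabilityTable(taxon_id=counts.taxon_id, global_mean=xbar, entries=entries)
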