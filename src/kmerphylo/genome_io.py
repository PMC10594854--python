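"""FASTA input and tabular output.

A genome is one FASTA file: every record (chromosome, contig, scaffold) of
one taxon. Sequences are sanitized to uppercase on read; soft-masked
(lowercase) bases are kept. IUPAC ambiguity codes other than A/C/G/T are
retained here and skipped later by the counting engine.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastaFormatError",
    "GenomeRecord",
    "Genome",
    "read_fasta",
    "write_fasta",
    "write_tsv_table",
    "IUPAC_DNA",
]

#: Valid characters after uppercasing: the four bases plus IUPAC ambiguity codes.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")


class FastaFormatError(ValueError):
    """Raised for empty, malformed or non-IUPAC FASTA input."""


@dataclass(frozen=True)
class GenomeRecord:
    """One sequence record (chromosome/contig) of a genome."""

    record_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """An ordered collection of records belonging to one taxon."""

    taxon_id: str
    records: tuple[GenomeRecord, ...]

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")
        if not self.records:
            raise ValueError(f"genome {self.taxon_id!r} has no records")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)


def _sanitize(record_id: str, raw: str) -> str:
    seq = raw.upper()
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_DNA:
            raise FastaFormatError(
                f"record {record_id!r}: invalid character {ch!r} "
                f"at position {pos + 1}"
            )
    return seq


def read_fasta(
    path: str | os.PathLike,
    taxon_id: str | None = None,
    exclude_records: Iterable[str] | None = None,
) -> Genome:
    """Read a (possibly multi-record) FASTA file as one genome.

    Parameters
    ----------
    path
        FASTA file; wrapped lines and multiple records are allowed.
    taxon_id
        Taxon label; defaults to the file stem.
    exclude_records
        Record ids to drop (e.g. sex chromosomes, which users may wish to
        exclude by name; no automatic exclusion is attempted).

    Raises
    ------
    FastaFormatError
        If the file contains no sequence records, a record is empty, or a
        sequence contains characters outside the IUPAC DNA alphabet.
    """
    path = Path(path)
    excluded = set(exclude_records or ())
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in excluded:
            continue
        seq = _sanitize(rec.id, str(rec.seq))
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} in {path} has no sequence")
        records.append(GenomeRecord(record_id=rec.id, sequence=seq))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return Genome(taxon_id=taxon_id or path.stem, records=tuple(records))


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    """Write a genome back to FASTA (one record per input record, in order)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="")
        for r in genome.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def write_tsv_table(rows: pd.DataFrame | Sequence[dict], path: str | os.PathLike) -> None:
    """Write tabular data as a UTF-8 TSV with a header line.

    Integer columns are rendered as integers; floating-point columns (δ,
    RMN, distances) with 6 significant digits.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")
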