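"""Peptide data model and FASTA/CSV readers and writers.

Every pipeline stage consumes :class:`PeptideRecord` objects: a short
identifier, an uppercase sequence over the 20 canonical amino acids, and an
optional cancer-type label in ``0..8`` (gastric, breast, cervical, colon,
hepatocellular, histiocytic-lymphoma, leukemia, lung, prostate).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids in fixed alphabetical order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

N_CLASSES = 9


class SequenceValidationError(ValueError):
    """Raised when a sequence contains a non-canonical character."""


@dataclass
class PeptideRecord:
    id: str
    sequence: str
    label: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if self.label is not None:
            self.label = int(self.label)
            if not 0 <= self.label < N_CLASSES:
                raise ValueError(
                    f"label {self.label} outside 0..{N_CLASSES - 1} for record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(raw: str) -> str:
    """Return the canonical (uppercase, stripped) form of ``raw``.

    Raises :class:`SequenceValidationError` naming the first offending
    character and its 1-based position if any character falls outside the
    20-letter canonical alphabet (B, J, O, U, X, Z, digits and gap symbols
    are all rejected).
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise SequenceValidationError("empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _ALPHABET_SET:
            raise SequenceValidationError(
                f"non-canonical residue {ch!r} at position {pos}"
            )
    return seq


def read_peptides(path: str | Path, format: str | None = None) -> list[PeptideRecord]:
    """Read peptides from FASTA or labeled CSV (columns id, sequence[, label])."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "fasta":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise ValueError(f"malformed FASTA header in {path}")
            records.append(
                PeptideRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    source=rec.description.split(None, 1)[1]
                    if len(rec.description.split(None, 1)) > 1
                    else None,
                )
            )
        return records
    if fmt == "csv":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "sequence" not in reader.fieldnames:
                raise ValueError(f"CSV {path} lacks a 'sequence' column")
            if "id" not in reader.fieldnames:
                raise ValueError(f"CSV {path} lacks an 'id' column")
            for row in reader:
                label = row.get("label")
                label = int(label) if label not in (None, "") else None
                records.append(
                    PeptideRecord(
                        id=row["id"],
                        sequence=row["sequence"],
                        label=label,
                        source=row.get("source") or None,
                    )
                )
        return records
    raise ValueError(f"unknown format {fmt!r}")


def write_peptides(
    records: Sequence[PeptideRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records to FASTA (unwrapped) or CSV; round-trip safe."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "fasta":
        seq_records = [
            SeqRecord(Seq(r.sequence), id=r.id, description=r.source or "")
            for r in records
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
            writer.write_file(seq_records)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "sequence", "label"])
            for r in records:
                writer.writerow([r.id, r.sequence, "" if r.label is None else r.label])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".faa"}:
        return "fasta"
    if suffix in {".csv", ".tsv"}:
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")
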