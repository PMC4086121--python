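"""Protein sequence input/output and residue-alphabet validation.

Sequences enter the package as FASTA records; only the 20 canonical
amino-acid letters are admitted to analysis.  Records carrying ambiguous
or non-standard residues (B, X, U, Z, J, O, gaps, stops, ...) are removed
as whole records and reported with the offending residue and position.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL_AA)


class EmptyInputError(ValueError):
    """Raised when a FASTA file parses but contains zero records."""


@dataclass(frozen=True)
class ProteinSequence:
    """One FASTA record: identifier, free-text description, residue string.

    ``residues`` is stored uppercased; validity against the canonical
    alphabet is checked separately by :func:`validate_sequence` so that
    raw (possibly invalid) records can still be carried around and
    reported.
    """

    id: str
    description: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into raw (unvalidated) records, order preserved.

    Residues are uppercased; the description is everything after the first
    whitespace on the header line.  Raises :class:`EmptyInputError` if the
    file contains no records, and the usual OS errors if unreadable.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                ProteinSequence(id=rec.id, description=desc,
                                residues=str(rec.seq).upper())
            )
    if not records:
        raise EmptyInputError(f"no FASTA records found in {path}")
    return records


def validate_sequence(record: ProteinSequence) -> tuple[bool, str | None]:
    """Check that every residue is one of the 20 canonical letters.

    Returns ``(True, None)`` for a valid record, else ``(False, reason)``
    where the reason names the first offending residue and its 1-based
    position.  The empty string is invalid with reason ``"empty"``.
    """
    if not record.residues:
        return False, "empty"
    for i, c in enumerate(record.residues):
        if c not in CANONICAL_SET:
            return False, f"non-canonical residue {c!r} at position {i + 1}"
    return True, None


def partition_valid(
    records: Iterable[ProteinSequence],
) -> tuple[list[ProteinSequence], list[tuple[ProteinSequence, str]]]:
    """Split records into (valid, removed-with-reason) preserving order."""
    valid: list[ProteinSequence] = []
    removed: list[tuple[ProteinSequence, str]] = []
    for rec in records:
        ok, reason = validate_sequence(rec)
        if ok:
            valid.append(rec)
        else:
            removed.append((rec, reason or "invalid"))
    return valid, removed


def write_fasta(records: Sequence[ProteinSequence], path: str | Path) -> None:
    """Write records back out as FASTA (wrap at 60 columns)."""
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecs, handle, "fasta")


#: Fixed column order of the prediction-result table.
RESULT_COLUMNS = (
    "id",
    "prob_random_forest",
    "prob_gradient_boosting",
    "prob_linear_svm",
    "prob_minimal_tree",
    "call_random_forest",
    "call_gradient_boosting",
    "call_linear_svm",
    "call_minimal_tree",
    "overall_call",
    "n_models_agreeing",
    "internal_score",
    "sp_call",
    "high_quality",
)


def write_results(records: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write prediction records as a TSV/CSV table with a fixed header.

    ``records`` are objects exposing :meth:`as_dict` with the keys of
    :data:`RESULT_COLUMNS` (see :class:`neuropid.pipeline.PredictionRecord`).
    An empty list yields a header-only file.  Probabilities and the
    Internal Score are printed with 6 decimal places.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    delim = "\t" if format == "tsv" else ","
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delim, lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for rec in records:
            row = rec.as_dict() if hasattr(rec, "as_dict") else dict(rec)
            out = []
            for col in RESULT_COLUMNS:
                val = row[col]
                if isinstance(val, bool):
                    out.append(str(val))
                elif isinstance(val, float):
                    out.append(f"{val:.6f}")
                else:
                    out.append(str(val))
            writer.writerow(out)
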