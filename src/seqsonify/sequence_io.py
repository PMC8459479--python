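"""FASTA / aligned-FASTA input and the sequence domain model.

Two value types are defined here: :class:`ProteinSequence` for single
protein sequences and :class:`Alignment` for rectangular multiple sequence
alignments with ``'-'`` gaps.  Readers normalise case ('mkv' -> 'MKV') and
the ``'.'`` gap dialect to ``'-'``; coordinates are 0-based internally and
1-based in all user-facing messages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

from seqsonify.errors import (
    AlignmentShapeError,
    FastaParseError,
    ResidueValidationError,
)

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Alignment gap character (canonical form; '.' is normalised to this).
GAP = "-"


class ResiduePolicy(str, enum.Enum):
    """How to treat residues outside the 20-letter standard alphabet.

    ``STRICT`` (default) rejects them at parse time; ``PERMISSIVE`` admits
    them and downstream algorithms render them as silent rests.
    """

    STRICT = "strict"
    PERMISSIVE = "permissive"


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence with identifier.

    ``residues`` is an uppercase string; under the strict policy every
    character is one of the 20 standard codes, so any downstream pitch
    lookup is guaranteed to succeed.
    """

    id: str
    residues: str
    description: str = ""
    policy: ResiduePolicy = ResiduePolicy.STRICT

    def __post_init__(self):
        if len(self.residues) < 1:
            raise FastaParseError(f"empty sequence for record '{self.id}'")
        norm = self.residues.upper()
        object.__setattr__(self, "residues", norm)
        if self.policy is ResiduePolicy.STRICT:
            for i, res in enumerate(norm):
                if res not in STANDARD_RESIDUES:
                    raise ResidueValidationError(res, i + 1, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple sequence alignment over residues and gaps."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    descriptions: tuple[str, ...] = ()
    policy: ResiduePolicy = ResiduePolicy.STRICT

    def __post_init__(self):
        if not self.rows:
            raise FastaParseError("alignment must contain at least one sequence")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if not self.descriptions:
            object.__setattr__(self, "descriptions", ("",) * len(self.rows))
        norm = tuple(r.upper().replace(".", GAP) for r in self.rows)
        object.__setattr__(self, "rows", norm)
        lengths = {rid: len(r) for rid, r in zip(self.ids, norm)}
        if len(set(lengths.values())) > 1:
            raise AlignmentShapeError(lengths)
        if norm[0] == "" or len(norm[0]) < 1:
            raise FastaParseError("alignment must contain at least one column")
        if self.policy is ResiduePolicy.STRICT:
            allowed = STANDARD_RESIDUES | {GAP}
            for rid, row in zip(self.ids, norm):
                for i, res in enumerate(row):
                    if res not in allowed:
                        raise ResidueValidationError(res, i + 1, rid)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        """Return column ``index`` (0-based) as a string of length n_rows."""
        return "".join(row[index] for row in self.rows)

    def columns(self) -> Iterable[str]:
        for i in range(self.n_cols):
            yield self.column(i)


def _parse_records(path: Union[str, Path]):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        head = handle.read(1)
        if head == "":
            raise FastaParseError(f"{path}: empty file")
        if head != ">":
            raise FastaParseError(f"{path}: not FASTA (first character is not '>')")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record '{rec.id}' has an empty sequence")
    return records


def _description_of(rec) -> str:
    # Bio.SeqIO keeps the full header line in rec.description; strip the id.
    desc = rec.description
    if desc.startswith(rec.id):
        desc = desc[len(rec.id) :].strip()
    return desc


def read_fasta(
    path: Union[str, Path],
    policy: ResiduePolicy = ResiduePolicy.STRICT,
) -> list[ProteinSequence]:
    """Read every record of a FASTA file as a :class:`ProteinSequence`.

    Raises :class:`FastaParseError` on malformed input and, under the
    strict policy, :class:`ResidueValidationError` naming the offending
    character and 1-based position.
    """
    policy = ResiduePolicy(policy)
    return [
        ProteinSequence(
            id=rec.id,
            residues=str(rec.seq),
            description=_description_of(rec),
            policy=policy,
        )
        for rec in _parse_records(path)
    ]


def read_alignment(
    path: Union[str, Path],
    policy: ResiduePolicy = ResiduePolicy.STRICT,
) -> Alignment:
    """Read an aligned-FASTA file into a rectangular :class:`Alignment`.

    Ragged rows raise :class:`AlignmentShapeError` reporting each row length.
    """
    policy = ResiduePolicy(policy)
    records = _parse_records(path)
    return Alignment(
        ids=tuple(rec.id for rec in records),
        rows=tuple(str(rec.seq) for rec in records),
        descriptions=tuple(_description_of(rec) for rec in records),
        policy=policy,
    )


def write_fasta(sequences: Iterable[ProteinSequence], path: Union[str, Path],
                width: int = 60) -> None:
    """Write sequences as FASTA (wrapped at ``width`` columns)."""
    seqs = [sequences] if isinstance(sequences, ProteinSequence) else list(sequences)
    with open(path, "w") as out:
        for seq in seqs:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            out.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                out.write(seq.residues[i : i + width] + "\n")


def write_alignment(alignment: Alignment, path: Union[str, Path],
                    width: int = 60) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as out:
        for rid, desc, row in zip(
            alignment.ids, alignment.descriptions, alignment.rows
        ):
            header = rid if not desc else f"{rid} {desc}"
            out.write(f">{header}\n")
            for i in range(0, len(row), width):
                out.write(row[i : i + width] + "\n")
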