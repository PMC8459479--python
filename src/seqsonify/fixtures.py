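"""Seed-deterministic synthetic data generators.

Two generators reproduce the geometry of the listening tasks used to
evaluate the algorithms: a protein with a short motif repeated in tandem
(default: length 253 with an 8-residue motif in 4 adjacent copies) and a
small alignment with conserved low-entropy domain blocks on a variable
background (default: 5 sequences, three domains under 50 columns each).
Only the geometric/conservation structure is emulated — no real protein or
alignment is reproduced.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from seqsonify.errors import FixtureGeometryError
from seqsonify.sequence_io import GAP, Alignment, ProteinSequence

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

MAX_DOMAIN_LEN = 49  # conserved domains stay "short" (< 50 columns)


@dataclass(frozen=True)
class RepeatProtein:
    """A generated tandem-repeat protein plus its ground truth."""

    sequence: ProteinSequence
    motif: str
    start: int  # 0-based position of the first motif copy
    n_repeats: int

    @property
    def repeat_region(self) -> tuple[int, int]:
        """0-based half-open interval covered by the tandem block."""
        return (self.start, self.start + len(self.motif) * self.n_repeats)

    def metadata_lines(self) -> list[str]:
        s, e = self.repeat_region
        return [
            f"motif = {self.motif}",
            f"motif_start = {self.start + 1}",  # 1-based for display
            f"n_repeats = {self.n_repeats}",
            f"repeat_region = {s + 1}..{e}",
            f"total_length = {len(self.sequence)}",
        ]


@dataclass(frozen=True)
class DomainMsa:
    """A generated alignment plus its domain ground truth."""

    alignment: Alignment
    domains: tuple[tuple[int, int], ...]  # (0-based start, length) per domain

    def metadata_lines(self) -> list[str]:
        lines = [
            f"n_seqs = {self.alignment.n_rows}",
            f"n_cols = {self.alignment.n_cols}",
        ]
        for i, (start, length) in enumerate(self.domains, start=1):
            lines.append(f"domain{i} = {start + 1}..{start + length}")
        return lines


def make_repeat_protein(
    total_len: int = 253,
    motif_len: int = 8,
    n_repeats: int = 4,
    seed: int = 0,
    seq_id: str = "repeat_protein",
) -> RepeatProtein:
    """Generate a random protein containing a tandem amino-acid repeat.

    Residues are uniform over the 20-letter alphabet; a random motif of
    ``motif_len`` is written as ``n_repeats`` adjacent copies at a seeded
    uniform position.  Identical seeds give identical output.
    """
    block = motif_len * n_repeats
    if motif_len < 1 or n_repeats < 1 or total_len < 1:
        raise FixtureGeometryError("lengths and counts must be positive")
    if block > total_len:
        raise FixtureGeometryError(
            f"motif block of {block} residues does not fit in length {total_len}"
        )
    rng = random.Random(seed)
    residues = [rng.choice(_ALPHABET) for _ in range(total_len)]
    motif = "".join(rng.choice(_ALPHABET) for _ in range(motif_len))
    start = rng.randrange(total_len - block + 1)
    for rep in range(n_repeats):
        offset = start + rep * motif_len
        residues[offset : offset + motif_len] = motif
    seq = ProteinSequence(id=seq_id, residues="".join(residues))
    return RepeatProtein(
        sequence=seq, motif=motif, start=start, n_repeats=n_repeats
    )


def make_domain_msa(
    n_seqs: int = 5,
    n_cols: int = 200,
    domains: Sequence[tuple[int, int]] = ((20, 40), (80, 40), (150, 30)),
    gap_rate: float = 0.0,
    seed: int = 0,
    substitution_rate: float = 0.05,
    max_domain_len: int = MAX_DOMAIN_LEN,
) -> DomainMsa:
    """Generate an alignment with conserved domain blocks.

    Inside each ``(start, length)`` domain every column has a consensus
    residue with i.i.d. substitutions at ``substitution_rate``; outside,
    cells are independent uniform residues, replaced by gaps at
    ``gap_rate``.  Domains must not overlap and each must be shorter than
    ``max_domain_len + 1`` columns.
    """
    if n_seqs < 1 or n_cols < 1:
        raise FixtureGeometryError("n_seqs and n_cols must be positive")
    if not 0.0 <= gap_rate <= 1.0:
        raise FixtureGeometryError("gap_rate must be a probability")
    ordered = sorted((int(s), int(l)) for s, l in domains)
    prev_end = 0
    for start, length in ordered:
        if length < 1 or start < 0:
            raise FixtureGeometryError("domain start/length must be positive")
        if length > max_domain_len:
            raise FixtureGeometryError(
                f"domain length {length} exceeds the {max_domain_len}-column cap"
            )
        if start < prev_end:
            raise FixtureGeometryError("domains overlap")
        if start + length > n_cols:
            raise FixtureGeometryError("domain extends past the alignment")
        prev_end = start + length
    rng = random.Random(seed)
    in_domain = [False] * n_cols
    for start, length in ordered:
        for col in range(start, start + length):
            in_domain[col] = True
    consensus = [rng.choice(_ALPHABET) for _ in range(n_cols)]
    rows = []
    for _ in range(n_seqs):
        cells = []
        for col in range(n_cols):
            if in_domain[col]:
                if rng.random() < substitution_rate:
                    cells.append(rng.choice(_ALPHABET))
                else:
                    cells.append(consensus[col])
            elif rng.random() < gap_rate:
                cells.append(GAP)
            else:
                cells.append(rng.choice(_ALPHABET))
        rows.append("".join(cells))
    aln = Alignment(
        ids=tuple(f"seq{i + 1}" for i in range(n_seqs)),
        rows=tuple(rows),
    )
    return DomainMsa(alignment=aln, domains=tuple(ordered))


def write_metadata(lines: Sequence[str], path: Union[str, Path]) -> None:
    """Write ground-truth metadata as a key-value sidecar file."""
    Path(path).write_text("\n".join(lines) + "\n")
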