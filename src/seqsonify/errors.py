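"""Exception hierarchy shared across the package."""


class SeqSonifyError(Exception):
    """Base class for all package errors."""


class FastaParseError(SeqSonifyError):
    """Raised for malformed FASTA input (missing header, empty record)."""


class ResidueValidationError(SeqSonifyError):
    """Raised under the strict policy for a residue outside the 20-letter
    standard alphabet.  Positions in the message are 1-based."""

    def __init__(self, residue: str, position: int, seq_id: str = ""):
        self.residue = residue
        self.position = position  # 1-based
        self.seq_id = seq_id
        where = f" in sequence '{seq_id}'" if seq_id else ""
        super().__init__(
            f"non-standard residue {residue!r} at position {position}{where}"
        )


class AlignmentShapeError(SeqSonifyError):
    """Raised for ragged (non-rectangular) alignment input."""

    def __init__(self, lengths):
        self.lengths = dict(lengths)
        detail = ", ".join(f"{rid}={n}" for rid, n in lengths.items())
        super().__init__(f"alignment rows have unequal lengths: {detail}")


class PitchLookupError(SeqSonifyError, KeyError):
    """Raised when a residue has no entry in a pitch mapping."""


class RenderError(SeqSonifyError):
    """Raised for rendering failures (e.g. too many voices for MIDI)."""


class FixtureGeometryError(SeqSonifyError, ValueError):
    """Raised for impossible synthetic-data geometry (motif too long,
    overlapping domains, ...)."""
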