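"""Per-column Shannon entropy of an alignment and its pitch standardisation.

Entropy is computed in bits over the distinct symbols present in a column,
with the gap character counted as an ordinary symbol.  The profile is
mapped to MIDI pitches by z-score standardisation across all columns
(sample standard deviation, n-1 divisor), scaled by 10 and centred on
middle C (60), then floored to integers and clamped into [0, 127].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from seqsonify.sequence_io import Alignment

#: Pitch-scale spread and centre of the standardisation transform.
SPREAD = 10.0
CENTRE = 60.0


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column Shannon entropies (bits) with their mean and sample SD."""

    values: tuple[float, ...]
    mean: float
    sd: float

    def __len__(self) -> int:
        return len(self.values)

    def export_csv(self, path: Union[str, Path]) -> None:
        """Two-column CSV: 1-based column index, entropy in bits."""
        with open(path, "w") as out:
            out.write("column,entropy_bits\n")
            for i, h in enumerate(self.values, start=1):
                out.write(f"{i},{h!r}\n")


@dataclass(frozen=True)
class MidiProfile:
    """Integer MIDI pitches per column plus the pre-floor real values."""

    pitches: tuple[int, ...]
    pre_floor: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.pitches)

    def export_csv(self, path: Union[str, Path]) -> None:
        """Two-column CSV: 1-based column index, MIDI pitch."""
        with open(path, "w") as out:
            out.write("column,midi_pitch\n")
            for i, p in enumerate(self.pitches, start=1):
                out.write(f"{i},{p}\n")


def column_entropy(column: Sequence[str]) -> float:
    """Shannon entropy (bits) of one alignment column.

    ``H = -sum(p * log2(p))`` over the distinct symbols present, with
    ``p = count / len(column)``; the gap ``'-'`` counts like any residue.
    """
    n = len(column)
    if n == 0:
        raise ValueError("column must be non-empty")
    counts = Counter(column)
    return -sum(
        (c / n) * math.log2(c / n) for c in counts.values()
    )


def entropy_profile(alignment: Alignment) -> EntropyProfile:
    """Entropy of every column of ``alignment``, in column order."""
    values = tuple(column_entropy(col) for col in alignment.columns())
    mean = sum(values) / len(values)
    if len(values) > 1:
        sd = math.sqrt(
            sum((h - mean) ** 2 for h in values) / (len(values) - 1)
        )
    else:
        sd = 0.0
    return EntropyProfile(values=values, mean=mean, sd=sd)


def entropy_to_midi(profile: EntropyProfile) -> MidiProfile:
    """Standardise an entropy profile to integer MIDI pitches.

    ``pre_floor_i = (H_i - mean) / sd * 10 + 60``; the pitch is its
    mathematical floor clamped into [0, 127].  A degenerate profile
    (``sd == 0``, e.g. a perfectly conserved alignment) maps every column
    to 60 since there is no deviation to scale.
    """
    if len(profile) < 1:
        raise ValueError("profile must contain at least one column")
    if profile.sd == 0.0:
        pre = tuple(CENTRE for _ in profile.values)
        return MidiProfile(pitches=tuple(60 for _ in pre), pre_floor=pre)
    pre = tuple(
        (h - profile.mean) / profile.sd * SPREAD + CENTRE for h in profile.values
    )
    pitches = tuple(min(127, max(0, math.floor(x))) for x in pre)
    return MidiProfile(pitches=pitches, pre_floor=pre)
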