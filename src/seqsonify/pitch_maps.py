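"""Residue-to-pitch mappings.

Two mappings are housed here:

* the GES (Goldman-Engelman-Steitz) hydrophobicity pitch scale, ordering
  the 20 amino acids from most hydrophobic (F, MIDI 50) to most
  hydrophilic (R, MIDI 77); and
* the four-group reduced alphabet with one pitch and one instrument per
  hydrophobicity group.

The canonical GES scale hard-codes the published MIDI numbers.  The
published construction rule (previous pitch plus GES-score increment,
rounded up) is implemented separately in :func:`derive_scale_from_scores`
so it can be checked against the canonical numbers; the two disagree in a
single cell (Q: rule gives 67, published value is 66) and the canonical
scale deliberately keeps the published value.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

from seqsonify.errors import PitchLookupError

# (residue, GES score, increment from predecessor, MIDI number), ordered
# from most hydrophobic to most hydrophilic.  The MIDI numbers are the
# published values and are authoritative.
_GES_TABLE: tuple[tuple[str, float, float, int], ...] = (
    ("F", -3.7, 0.0, 50),
    ("M", -3.4, 0.3, 51),
    ("I", -3.1, 0.3, 52),
    ("L", -2.8, 0.3, 53),
    ("V", -2.6, 0.2, 54),
    ("C", -2.0, 0.6, 55),
    ("W", -1.9, 0.1, 56),
    ("A", -1.6, 0.3, 57),
    ("T", -1.2, 0.4, 58),
    ("G", -1.0, 0.2, 59),
    ("S", -0.6, 0.4, 60),
    ("P", 0.2, 0.8, 61),
    ("Y", 0.7, 0.5, 62),
    ("H", 3.0, 2.3, 65),
    ("Q", 4.1, 1.1, 66),  # rule would give 67; published value kept
    ("N", 4.8, 0.7, 67),
    ("E", 8.2, 3.4, 71),
    ("K", 8.8, 0.6, 72),
    ("D", 9.2, 0.4, 73),
    ("R", 12.3, 3.1, 77),
)

#: Residue whose published MIDI number deviates from the construction rule.
RULE_DISCREPANCY_RESIDUE = "Q"


@dataclass(frozen=True)
class PitchScaleEntry:
    residue: str
    ges_score: float
    increment: float
    midi_pitch: int


class PitchScale:
    """An injective, ordered residue -> MIDI pitch mapping."""

    def __init__(self, entries: Sequence[PitchScaleEntry]):
        if len(entries) != 20:
            raise ValueError(f"pitch scale needs 20 entries, got {len(entries)}")
        pitches = [e.midi_pitch for e in entries]
        if len(set(pitches)) != len(pitches):
            raise ValueError("pitch scale must be injective (one-to-one)")
        if any(p < 0 or p > 127 for p in pitches):
            raise ValueError("MIDI pitches must lie in [0, 127]")
        if any(b.midi_pitch <= a.midi_pitch for a, b in zip(entries, entries[1:])):
            raise ValueError("MIDI pitches must strictly increase along the ordering")
        self._entries = tuple(entries)
        self._by_residue = {e.residue: e for e in self._entries}

    @property
    def entries(self) -> tuple[PitchScaleEntry, ...]:
        return self._entries

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(e.residue for e in self._entries)

    @property
    def min_pitch(self) -> int:
        return self._entries[0].midi_pitch

    @property
    def max_pitch(self) -> int:
        return self._entries[-1].midi_pitch

    def pitch(self, residue: str) -> int:
        """MIDI pitch of ``residue``; raises PitchLookupError if unmapped."""
        try:
            return self._by_residue[residue.upper()].midi_pitch
        except KeyError:
            raise PitchLookupError(f"no pitch mapping for residue {residue!r}")

    def __contains__(self, residue: str) -> bool:
        return residue.upper() in self._by_residue

    def __getitem__(self, residue: str) -> int:
        return self.pitch(residue)

    def entry(self, residue: str) -> PitchScaleEntry:
        try:
            return self._by_residue[residue.upper()]
        except KeyError:
            raise PitchLookupError(f"no pitch mapping for residue {residue!r}")

    def export_csv(self, path: Union[str, Path]) -> None:
        """Write the scale as CSV (residue, ges_score, increment, midi_pitch)."""
        with open(path, "w", newline="") as out:
            writer = csv.writer(out)
            writer.writerow(["residue", "ges_score", "increment", "midi_pitch"])
            for e in self._entries:
                writer.writerow([e.residue, e.ges_score, e.increment, e.midi_pitch])


_CANONICAL: PitchScale | None = None


def ges_scale() -> PitchScale:
    """The canonical 20-entry GES hydrophobicity pitch scale (F=50 ... R=77)."""
    global _CANONICAL
    if _CANONICAL is None:
        _CANONICAL = PitchScale(
            [PitchScaleEntry(*row) for row in _GES_TABLE]
        )
    return _CANONICAL


def ges_scores() -> dict[str, float]:
    """The GES hydrophobicity scores keyed by residue, in scale order."""
    return {res: score for res, score, _, _ in _GES_TABLE}


def packaged_scale_csv() -> str:
    """Contents of the machine-readable scale table shipped as package data."""
    return (
        resources.files("seqsonify").joinpath("data/ges_scale.csv").read_text()
    )


def derive_scale_from_scores(
    scores: Mapping[str, float], start_pitch: int = 50
) -> PitchScale:
    """Build a pitch scale from hydrophobicity scores by the published rule.

    Residues are ordered by ascending score (most hydrophobic first); the
    first gets ``start_pitch`` and each subsequent residue gets the ceiling
    of the previous pitch plus the score increment.  A would-be collision
    (increment rounding to zero) is bumped by +1 to keep the mapping
    one-to-one.

    This documents and verifies the construction rule; it is *not* the
    canonical scale (see module docstring for the Q discrepancy).
    """
    if len(scores) != 20:
        raise ValueError(
            f"score mapping must cover all 20 residues, got {len(scores)}"
        )
    missing = set("ACDEFGHIKLMNPQRSTVWY") - {r.upper() for r in scores}
    if missing:
        raise ValueError(f"score mapping missing residues: {sorted(missing)}")
    ordered = sorted(scores.items(), key=lambda kv: kv[1])
    entries: list[PitchScaleEntry] = []
    prev_score = ordered[0][1]
    prev_pitch = start_pitch
    for i, (res, score) in enumerate(ordered):
        inc = score - prev_score
        if i == 0:
            pitch = start_pitch
        else:
            pitch = math.ceil(prev_pitch + inc)
            if pitch <= prev_pitch:  # injectivity bump
                pitch = prev_pitch + 1
        entries.append(PitchScaleEntry(res.upper(), score, round(inc, 10), pitch))
        prev_score, prev_pitch = score, pitch
    return PitchScale(entries)


def rule_agreement(scale: PitchScale | None = None) -> dict[str, bool]:
    """Check the construction rule cell by cell against a pitch scale.

    For each residue after the first, tests whether its pitch equals the
    ceiling of its *predecessor's published pitch* plus the score increment
    (with the +1 injectivity bump).  On the canonical scale this holds for
    19 of 20 residues; the lone failure is Q, whose published 66 falls one
    short of the rule's 67.  (Because the published table chains onwards
    from its own Q value, a fully self-chained derivation additionally
    shifts every residue after Q by +1; the cell-wise view isolates the
    single deviating cell.)
    """
    if scale is None:
        scale = ges_scale()
    agreement: dict[str, bool] = {scale.entries[0].residue: True}
    for prev, entry in zip(scale.entries, scale.entries[1:]):
        expected = math.ceil(prev.midi_pitch + entry.increment)
        if expected <= prev.midi_pitch:
            expected = prev.midi_pitch + 1
        agreement[entry.residue] = entry.midi_pitch == expected
    return agreement


# ---------------------------------------------------------------------------
# Reduced alphabet (four hydrophobicity groups)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedGroup:
    label: str
    residues: frozenset[str]
    midi_pitch: int
    instrument: str


class ReducedAlphabet:
    """Partition of the 20 amino acids into four hydrophobicity groups,
    each with a fixed MIDI pitch and a synthesiser/instrument label."""

    def __init__(self, groups: Sequence[ReducedGroup]):
        union: set[str] = set()
        for g in groups:
            if union & g.residues:
                raise ValueError("reduced-alphabet groups must be disjoint")
            union |= g.residues
        if union != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("reduced-alphabet groups must cover all 20 residues")
        if len({g.midi_pitch for g in groups}) != len(groups):
            raise ValueError("group pitches must be distinct")
        self._groups = tuple(groups)
        self._by_residue = {
            res: g for g in self._groups for res in g.residues
        }

    @property
    def groups(self) -> tuple[ReducedGroup, ...]:
        return self._groups

    def group_of(self, residue: str) -> ReducedGroup:
        try:
            return self._by_residue[residue.upper()]
        except KeyError:
            raise PitchLookupError(f"no reduced-alphabet group for {residue!r}")

    def pitch(self, residue: str) -> int:
        return self.group_of(residue).midi_pitch

    def instrument(self, residue: str) -> str:
        return self.group_of(residue).instrument


_REDUCED: ReducedAlphabet | None = None


def reduced_alphabet() -> ReducedAlphabet:
    """The canonical four-group reduced alphabet.

    The pitches are the first four notes of a C-major pentatonic scale;
    the instruments are the synthesiser allocation used when pitch already
    carries the fine-grained hydrophobicity signal.
    """
    global _REDUCED
    if _REDUCED is None:
        _REDUCED = ReducedAlphabet(
            [
                ReducedGroup("FILVWY", frozenset("FILVWY"), 67, "piano"),
                ReducedGroup("ACGMP", frozenset("ACGMP"), 64, "sine"),
                ReducedGroup("KQST", frozenset("KQST"), 62, "pluck"),
                ReducedGroup("DEHNR", frozenset("DEHNR"), 60, "tb303"),
            ]
        )
    return _REDUCED


def reduced_pitch(residue: str) -> int:
    """Group pitch (67/64/62/60) of the group containing ``residue``."""
    return reduced_alphabet().pitch(residue)


def reduced_instrument(residue: str) -> str:
    """Instrument label (piano/sine/pluck/tb303) of ``residue``'s group."""
    return reduced_alphabet().instrument(residue)
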