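"""The five sonification algorithms.

Every algorithm maps sequence/alignment position to time: one note-slot per
residue (Algorithms I-III) or per alignment column (IV-V).  The outputs are
:class:`SonificationTrack` objects -- ordered collections of
:class:`NoteEvent` -- which the render module serialises to MIDI or
Sonic Pi code.

Algorithm summary:

* I   ``sonify_hydrophobicity`` -- GES pitch per residue, sine voice.
* II  ``sonify_reduced`` -- four-group reduced-alphabet pitch, sine voice.
* III ``sonify_combined`` -- GES pitch, instrument per reduced group.
* IV  ``sonify_msa_entropy`` -- monophonic, one note per column, pitch from
  standardised column entropy, saw voice.
* V   ``sonify_msa_hydrophobicity`` -- polyphonic, one note per distinct
  non-gap residue per column, GES pitch, volume scaled by residue count,
  saw voice; gaps are silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from seqsonify.entropy import CENTRE, entropy_profile, entropy_to_midi
from seqsonify.errors import PitchLookupError
from seqsonify.pitch_maps import PitchScale, ReducedAlphabet, ges_scale, reduced_alphabet
from seqsonify.sequence_io import GAP, Alignment, ProteinSequence, ResiduePolicy

VOICES = ("sine", "saw", "piano", "pluck", "tb303")

DEFAULT_NOTE_DURATION = 0.25  # seconds per slot; rate is not data-bearing
DEFAULT_VELOCITY = 100  # constant loudness where volume is not a channel
DEFAULT_V_MIN = 30  # Algorithm V: quietest (single residue in a gappy column)
DEFAULT_V_MAX = 127  # Algorithm V: consensus loudness


@dataclass(frozen=True)
class NoteEvent:
    """One scheduled sound.

    ``onset`` and ``duration`` are in note-slots (one slot per residue or
    column); ``source_position`` is the 1-based residue/column index the
    event came from, kept as provenance for display.
    """

    onset: int
    midi_pitch: int
    velocity: int = DEFAULT_VELOCITY
    duration: int = 1
    voice: str = "sine"
    source_position: int = 0
    source_symbol: str = ""

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration < 1:
            raise ValueError("duration must be >= 1 slot")
        if not 0 <= self.midi_pitch <= 127:
            raise ValueError("midi_pitch must lie in [0, 127]")
        if not 1 <= self.velocity <= 127:
            raise ValueError("velocity must lie in [1, 127]")


@dataclass(frozen=True)
class SonificationTrack:
    """Ordered note events plus algorithm/tempo metadata."""

    algorithm_id: str  # "I" .. "V"
    events: tuple[NoteEvent, ...]
    slots_total: int
    input_id: str
    note_duration_seconds: float = DEFAULT_NOTE_DURATION

    def __post_init__(self):
        if any(
            b.onset < a.onset for a, b in zip(self.events, self.events[1:])
        ):
            raise ValueError("events must be sorted by onset")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def voices(self) -> tuple[str, ...]:
        """Distinct voices in first-appearance order."""
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.voice, None)
        return tuple(seen)

    @property
    def duration_seconds(self) -> float:
        return self.slots_total * self.note_duration_seconds


@dataclass(frozen=True)
class SonificationParams:
    """Run parameters shared by all algorithms.

    ``invert_polarity`` flips the pitch direction (high pitch then means
    high hydrophobicity / high conservation) without leaving each
    algorithm's pitch vocabulary.
    """

    note_duration_seconds: float = DEFAULT_NOTE_DURATION
    velocity: int = DEFAULT_VELOCITY
    v_min: int = DEFAULT_V_MIN
    v_max: int = DEFAULT_V_MAX
    invert_polarity: bool = False
    residue_policy: ResiduePolicy = ResiduePolicy.STRICT

    def __post_init__(self):
        if self.note_duration_seconds <= 0:
            raise ValueError("note_duration_seconds must be positive")
        if not 1 <= self.v_min < self.v_max <= 127:
            raise ValueError("need 1 <= v_min < v_max <= 127")


def _rank_inverter(pitches: tuple[int, ...]) -> Callable[[int], int]:
    """Map each pitch of a vocabulary to its mirror by rank (low<->high)."""
    ordered = sorted(set(pitches))
    table = {p: q for p, q in zip(ordered, reversed(ordered))}
    return lambda p: table[p]


def _pitch_fn(scale: PitchScale, invert: bool) -> Callable[[str], Optional[int]]:
    inverter = _rank_inverter(tuple(e.midi_pitch for e in scale.entries))

    def fn(residue: str) -> Optional[int]:
        if residue not in scale:
            return None
        p = scale.pitch(residue)
        return inverter(p) if invert else p

    return fn


def _sequence_track(
    seq: ProteinSequence,
    params: SonificationParams,
    algorithm_id: str,
    pitch_of: Callable[[str], Optional[int]],
    voice_of: Callable[[str], str],
) -> SonificationTrack:
    """Shared one-note-per-residue construction for Algorithms I-III.

    Unmapped residues raise under the strict policy; under the permissive
    policy the slot stays silent so position->time is undisturbed.
    """
    events = []
    for i, res in enumerate(seq.residues):
        pitch = pitch_of(res)
        if pitch is None:
            if params.residue_policy is ResiduePolicy.STRICT:
                raise PitchLookupError(
                    f"residue {res!r} at position {i + 1} has no pitch mapping"
                )
            continue  # silent rest, slot preserved
        events.append(
            NoteEvent(
                onset=i,
                midi_pitch=pitch,
                velocity=params.velocity,
                voice=voice_of(res),
                source_position=i + 1,
                source_symbol=res,
            )
        )
    return SonificationTrack(
        algorithm_id=algorithm_id,
        events=tuple(events),
        slots_total=len(seq),
        input_id=seq.id,
        note_duration_seconds=params.note_duration_seconds,
    )


def sonify_hydrophobicity(
    seq: ProteinSequence, params: SonificationParams = SonificationParams()
) -> SonificationTrack:
    """Algorithm I: one sine note per residue, pitch from the GES scale."""
    pitch_of = _pitch_fn(ges_scale(), params.invert_polarity)
    return _sequence_track(seq, params, "I", pitch_of, lambda r: "sine")


def sonify_reduced(
    seq: ProteinSequence, params: SonificationParams = SonificationParams()
) -> SonificationTrack:
    """Algorithm II: one sine note per residue, pitch from the four-group
    reduced alphabet (67/64/62/60)."""
    reduced = reduced_alphabet()
    inverter = _rank_inverter(tuple(g.midi_pitch for g in reduced.groups))

    def pitch_of(res: str) -> Optional[int]:
        try:
            p = reduced.pitch(res)
        except PitchLookupError:
            return None
        return inverter(p) if params.invert_polarity else p

    return _sequence_track(seq, params, "II", pitch_of, lambda r: "sine")


def sonify_combined(
    seq: ProteinSequence, params: SonificationParams = SonificationParams()
) -> SonificationTrack:
    """Algorithm III: GES pitch (as Algorithm I) with the instrument chosen
    by the residue's reduced-alphabet group."""
    reduced = reduced_alphabet()
    pitch_of = _pitch_fn(ges_scale(), params.invert_polarity)

    def voice_of(res: str) -> str:
        return reduced.instrument(res)

    return _sequence_track(seq, params, "III", pitch_of, voice_of)


def sonify_msa_entropy(
    aln: Alignment, params: SonificationParams = SonificationParams()
) -> SonificationTrack:
    """Algorithm IV: monophonic saw track, one note per column, pitch from
    the standardised column-entropy profile (higher variety = higher pitch,
    unless polarity is inverted)."""
    profile = entropy_profile(aln)
    midi = entropy_to_midi(profile)
    events = []
    for i, pitch in enumerate(midi.pitches):
        if params.invert_polarity:
            # mirror the z-score around the centre, re-floor and clamp
            pre = 2 * CENTRE - midi.pre_floor[i]
            pitch = min(127, max(0, math.floor(pre)))
        events.append(
            NoteEvent(
                onset=i,
                midi_pitch=pitch,
                velocity=params.velocity,
                voice="saw",
                source_position=i + 1,
                source_symbol=f"H={profile.values[i]:.4f}",
            )
        )
    input_id = aln.ids[0] if len(aln.ids) == 1 else f"msa[{aln.n_rows}]"
    return SonificationTrack(
        algorithm_id="IV",
        events=tuple(events),
        slots_total=aln.n_cols,
        input_id=input_id,
        note_duration_seconds=params.note_duration_seconds,
    )


def count_velocity(count: int, n_rows: int, v_min: int = DEFAULT_V_MIN,
                   v_max: int = DEFAULT_V_MAX) -> int:
    """Algorithm V loudness: linear in the fraction of rows sharing the
    residue, so a full-column consensus hits ``v_max`` and a singleton in a
    deep alignment stays near ``v_min``."""
    if not 1 <= count <= n_rows:
        raise ValueError("count must lie in [1, n_rows]")
    return round(v_min + (count / n_rows) * (v_max - v_min))


def sonify_msa_hydrophobicity(
    aln: Alignment, params: SonificationParams = SonificationParams()
) -> SonificationTrack:
    """Algorithm V: polyphonic saw track.  Per column, one note per distinct
    non-gap residue at the GES pitch, velocity increasing with the residue's
    count in the column; all-gap columns are silent."""
    pitch_of = _pitch_fn(ges_scale(), params.invert_polarity)
    events = []
    for i in range(aln.n_cols):
        column = aln.column(i)
        counts: dict[str, int] = {}
        for res in column:
            if res == GAP:
                continue
            counts[res] = counts.get(res, 0) + 1
        for res in sorted(counts):  # deterministic order within a slot
            pitch = pitch_of(res)
            if pitch is None:
                if params.residue_policy is ResiduePolicy.STRICT:
                    raise PitchLookupError(
                        f"residue {res!r} in column {i + 1} has no pitch mapping"
                    )
                continue
            events.append(
                NoteEvent(
                    onset=i,
                    midi_pitch=pitch,
                    velocity=count_velocity(
                        counts[res], aln.n_rows, params.v_min, params.v_max
                    ),
                    voice="saw",
                    source_position=i + 1,
                    source_symbol=res,
                )
            )
    return SonificationTrack(
        algorithm_id="V",
        events=tuple(events),
        slots_total=aln.n_cols,
        input_id=f"msa[{aln.n_rows}]",
        note_duration_seconds=params.note_duration_seconds,
    )
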