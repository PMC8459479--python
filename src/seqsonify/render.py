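"""Serialisation of sonification tracks.

Three output formats: Standard MIDI File (format 1, one track+channel per
voice), Sonic Pi source code (synth/play/sleep statements mirroring the
original code-generation pipeline), and a plain-text event table.

MIDI output is bit-for-bit deterministic: fixed 120 BPM tempo, 480
pulses-per-quarter resolution, and note durations converted from seconds
to ticks.  Notes use zero attack (immediate note-on).  Reading MIDI back
is deliberately *not* implemented here; the independent parser lives in
:mod:`seqsonify.smf` and exists only to verify round-trips.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

from seqsonify.algorithms import SonificationTrack
from seqsonify.errors import RenderError

#: General-MIDI program defaults for the Sonic Pi synth labels.  The synths
#: have no GM identity; these are the closest common timbres and are
#: presentation-layer only (overridable via RenderParams/config).
DEFAULT_PROGRAMS: dict[str, int] = {
    "sine": 79,   # ocarina: pure-toned
    "saw": 81,    # sawtooth lead
    "piano": 0,   # acoustic grand
    "pluck": 45,  # pizzicato strings
    "tb303": 87,  # bass+lead
}

PPQ = 480  # ticks per quarter note
TEMPO_BPM = 120  # fixed; reproducibility over configurability
MAX_CHANNELS = 16


@dataclass(frozen=True)
class RenderParams:
    """Rendering options: the voice -> GM program map."""

    programs: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PROGRAMS)
    )

    def program_for(self, voice: str) -> int:
        return self.programs.get(voice, DEFAULT_PROGRAMS.get(voice, 0))


# ---------------------------------------------------------------------------
# Standard MIDI File writing
# ---------------------------------------------------------------------------

def _vlq(value: int) -> bytes:
    """Encode a MIDI variable-length quantity."""
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def _chunk(tag: bytes, payload: bytes) -> bytes:
    return tag + len(payload).to_bytes(4, "big") + payload


def _meta_track() -> bytes:
    tempo_us = 60_000_000 // TEMPO_BPM
    data = b"\x00\xff\x51\x03" + tempo_us.to_bytes(3, "big")  # set tempo
    data += b"\x00\xff\x58\x04\x04\x02\x18\x08"  # 4/4 time signature
    data += b"\x00\xff\x2f\x00"  # end of track
    return _chunk(b"MTrk", data)


def _slot_ticks(note_duration_seconds: float) -> int:
    ticks_per_second = PPQ * TEMPO_BPM / 60.0
    ticks = round(note_duration_seconds * ticks_per_second)
    if ticks < 1:
        raise RenderError(
            f"note duration {note_duration_seconds}s is below one MIDI tick"
        )
    return ticks


def _voice_track(track: SonificationTrack, voice: str, channel: int,
                 program: int) -> bytes:
    ticks = _slot_ticks(track.note_duration_seconds)
    name = voice.encode("ascii")
    data = b"\x00\xff\x03" + _vlq(len(name)) + name  # track name
    data += bytes([0x00, 0xC0 | channel, program & 0x7F])  # program change
    # (tick, order, message): note-offs sort before note-ons at equal tick
    messages: list[tuple[int, int, bytes]] = []
    for ev in track.events:
        if ev.voice != voice:
            continue
        on = ev.onset * ticks
        off = (ev.onset + ev.duration) * ticks
        messages.append(
            (on, 1, bytes([0x90 | channel, ev.midi_pitch, ev.velocity]))
        )
        messages.append((off, 0, bytes([0x80 | channel, ev.midi_pitch, 0])))
    messages.sort(key=lambda m: (m[0], m[1]))
    cursor = 0
    for tick, _, msg in messages:
        data += _vlq(tick - cursor) + msg
        cursor = tick
    data += b"\x00\xff\x2f\x00"
    return _chunk(b"MTrk", data)


def write_midi(
    track: SonificationTrack,
    path: Union[str, Path],
    render_params: RenderParams = RenderParams(),
) -> None:
    """Write ``track`` as a format-1 Standard MIDI File.

    One MIDI track and channel per distinct voice (plus a leading tempo
    track).  Identical inputs produce byte-identical files.  More distinct
    voices than MIDI channels raises :class:`RenderError`.
    """
    voices = track.voices
    if len(voices) > MAX_CHANNELS:
        raise RenderError(
            f"{len(voices)} voices exceed the {MAX_CHANNELS} MIDI channels"
        )
    header = (
        (1).to_bytes(2, "big")
        + (1 + len(voices)).to_bytes(2, "big")
        + PPQ.to_bytes(2, "big")
    )
    blob = _chunk(b"MThd", header) + _meta_track()
    for channel, voice in enumerate(voices):
        blob += _voice_track(
            track, voice, channel, render_params.program_for(voice)
        )
    _atomic_write_bytes(Path(path), blob)


# ---------------------------------------------------------------------------
# Sonic Pi code emission
# ---------------------------------------------------------------------------

def emit_sonic_pi(track: SonificationTrack, path: Union[str, Path]) -> None:
    """Write ``track`` as a Sonic Pi program.

    One ``play`` statement per note event (synth = voice label, amp =
    velocity/127, zero attack) and one ``sleep`` of the note duration per
    slot, so position maps to time exactly as in the MIDI output.
    """
    lines = [
        "# Sonic Pi sonification generated by seqsonify",
        f"# algorithm: {track.algorithm_id}  input: {track.input_id}  "
        f"slots: {track.slots_total}",
        f"note_duration = {track.note_duration_seconds}",
        "",
    ]
    by_onset: dict[int, list] = {}
    for ev in track.events:
        by_onset.setdefault(ev.onset, []).append(ev)
    current_synth = None
    for slot in range(track.slots_total):
        for ev in by_onset.get(slot, ()):
            if ev.voice != current_synth:
                lines.append(f"use_synth :{ev.voice}")
                current_synth = ev.voice
            amp = round(ev.velocity / 127, 4)
            sustain = ev.duration
            lines.append(
                f"play {ev.midi_pitch}, amp: {amp}, attack: 0, "
                f"sustain: {sustain} * note_duration"
            )
        lines.append("sleep note_duration")
    _atomic_write_text(Path(path), "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Plain-text event table
# ---------------------------------------------------------------------------

EVENT_TABLE_COLUMNS = (
    "onset", "duration", "pitch", "velocity", "voice",
    "source_position", "source_symbol",
)


def write_event_table(track: SonificationTrack, path: Union[str, Path]) -> None:
    """Write the track as a TSV event table (one row per note event)."""
    lines = [
        f"# algorithm={track.algorithm_id} input={track.input_id} "
        f"slots={track.slots_total} "
        f"note_duration={track.note_duration_seconds}",
        "\t".join(EVENT_TABLE_COLUMNS),
    ]
    for ev in track.events:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    ev.onset, ev.duration, ev.midi_pitch, ev.velocity,
                    ev.voice, ev.source_position, ev.source_symbol,
                )
            )
        )
    _atomic_write_text(Path(path), "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Config + atomic writes
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> dict[str, str]:
    """Parse a simple ``key = value`` config file ('#' starts a comment).

    Recognised keys: ``program.<voice>`` (GM program override),
    ``note_duration``, ``velocity``, ``v_min``, ``v_max``.
    """
    conf: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        conf[key] = value
    return conf


def render_params_from_config(conf: Mapping[str, str]) -> RenderParams:
    programs = dict(DEFAULT_PROGRAMS)
    for key, value in conf.items():
        if key.startswith("program."):
            voice = key[len("program.") :]
            program = int(value)
            if not 0 <= program <= 127:
                raise ValueError(f"program for {voice!r} out of range: {program}")
            programs[voice] = program
    return RenderParams(programs=programs)


def _atomic_write_bytes(path: Path, blob: bytes) -> None:
    tmp = path.with_name(path.name + ".tmp")
    try:
        tmp.write_bytes(blob)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    try:
        tmp.write_text(text)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()
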