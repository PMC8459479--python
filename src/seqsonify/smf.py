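"""Minimal Standard MIDI File reader.

This exists solely as an independent round-trip oracle for
:func:`seqsonify.render.write_midi`: it parses the binary format from the
byte level up and shares no code with the writer.  It handles format 0/1
files, running status, and the meta/sysex events needed to skip them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union


@dataclass(frozen=True)
class ParsedNote:
    track_index: int
    channel: int
    start_tick: int
    end_tick: int
    pitch: int
    velocity: int


@dataclass(frozen=True)
class ParsedMidi:
    format: int
    division: int
    n_tracks: int
    tempo_us_per_quarter: int
    notes: tuple[ParsedNote, ...]  # ordered by (track, start_tick, pitch)
    programs: dict[int, int]  # channel -> last program change
    track_names: tuple[str, ...]


class _Cursor:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def read(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ValueError("truncated MIDI data")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.read(1)[0]

    def vlq(self) -> int:
        value = 0
        while True:
            byte = self.u8()
            value = (value << 7) | (byte & 0x7F)
            if not byte & 0x80:
                return value

    @property
    def done(self) -> bool:
        return self.pos >= len(self.data)


def read_midi(path: Union[str, Path]) -> ParsedMidi:
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File (missing MThd)")
    header_len = int.from_bytes(data[4:8], "big")
    fmt = int.from_bytes(data[8:10], "big")
    n_tracks = int.from_bytes(data[10:12], "big")
    division = int.from_bytes(data[12:14], "big")
    if division & 0x8000:
        raise ValueError("SMPTE time division not supported")
    pos = 8 + header_len

    tempo = 500_000  # MIDI default
    notes: list[ParsedNote] = []
    programs: dict[int, int] = {}
    track_names: list[str] = []

    for track_index in range(n_tracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError(f"track {track_index}: missing MTrk chunk")
        length = int.from_bytes(data[pos + 4 : pos + 8], "big")
        cur = _Cursor(data[pos + 8 : pos + 8 + length])
        pos += 8 + length

        tick = 0
        running_status = None
        open_notes: dict[tuple[int, int], tuple[int, int]] = {}
        while not cur.done:
            tick += cur.vlq()
            byte = cur.u8()
            if byte == 0xFF:  # meta
                meta_type = cur.u8()
                meta_len = cur.vlq()
                payload = cur.read(meta_len)
                if meta_type == 0x51:
                    tempo = int.from_bytes(payload, "big")
                elif meta_type == 0x03:
                    track_names.append(payload.decode("latin-1"))
                elif meta_type == 0x2F:
                    break
                continue
            if byte in (0xF0, 0xF7):  # sysex
                cur.read(cur.vlq())
                running_status = None
                continue
            if byte & 0x80:
                status = byte
                running_status = status
                first = None
            else:
                if running_status is None:
                    raise ValueError("data byte without running status")
                status = running_status
                first = byte
            kind = status & 0xF0
            channel = status & 0x0F
            d1 = first if first is not None else cur.u8()
            if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                d2 = cur.u8()
            elif kind in (0xC0, 0xD0):
                d2 = None
            else:
                raise ValueError(f"unexpected status byte 0x{status:02x}")
            if kind == 0xC0:
                programs[channel] = d1
            elif kind == 0x90 and d2 > 0:
                open_notes[(channel, d1)] = (tick, d2)
            elif kind == 0x80 or (kind == 0x90 and d2 == 0):
                start = open_notes.pop((channel, d1), None)
                if start is None:
                    raise ValueError(
                        f"note-off without matching note-on "
                        f"(channel {channel}, pitch {d1})"
                    )
                notes.append(
                    ParsedNote(
                        track_index=track_index,
                        channel=channel,
                        start_tick=start[0],
                        end_tick=tick,
                        pitch=d1,
                        velocity=start[1],
                    )
                )
        if open_notes:
            raise ValueError(f"track {track_index}: unterminated notes")

    notes.sort(key=lambda n: (n.track_index, n.start_tick, n.pitch))
    return ParsedMidi(
        format=fmt,
        division=division,
        n_tracks=n_tracks,
        tempo_us_per_quarter=tempo,
        notes=tuple(notes),
        programs=programs,
        track_names=tuple(track_names),
    )


def note_sequence(parsed: ParsedMidi) -> list[tuple[int, int, int]]:
    """All notes across tracks as (start_tick, pitch, velocity), in
    chronological order (ties broken by pitch) — the round-trip payload."""
    return [
        (n.start_tick, n.pitch, n.velocity)
        for n in sorted(parsed.notes, key=lambda n: (n.start_tick, n.pitch))
    ]
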