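"""Minimal Standard MIDI File (format 0) writer.

Only what the stimulus exporter needs: a single-track file of fixed-velocity
note events at millisecond-accurate onsets. Written from scratch because the
runtime environment pins no MIDI library.
"""

from __future__ import annotations

import struct
from typing import Sequence

__all__ = ["write_midi_file"]

#: ticks per quarter note; with the default tempo of 500000 us/quarter this
#: makes one tick exactly one millisecond.
_TPQ = 500
_TEMPO_US = 500_000


def _var_len(value: int) -> bytes:
    """MIDI variable-length quantity encoding."""
    if value < 0:
        raise ValueError("delta time must be non-negative")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def write_midi_file(
    path: str,
    notes: Sequence[tuple[int, int, int]],
    velocity: int = 80,
    program: int = 0,
) -> None:
    """Write note events to a format-0 SMF.

    Parameters
    ----------
    path : str
        Output file path.
    notes : sequence of (onset_ms, duration_ms, midi_note)
        Events; need not be sorted.
    velocity, program : int
        Constant velocity and program number for all events.
    """
    events: list[tuple[int, bytes]] = []
    events.append((0, bytes([0xC0, program & 0x7F])))
    events.append((0, b"\xff\x51\x03" + struct.pack(">I", _TEMPO_US)[1:]))
    for onset, duration, note in notes:
        if not 0 <= note <= 127:
            raise ValueError(f"MIDI note {note} out of range [0, 127]")
        events.append((int(onset), bytes([0x90, note, velocity & 0x7F])))
        events.append((int(onset + duration), bytes([0x80, note, 0])))
    events.sort(key=lambda e: e[0])

    track = bytearray()
    clock = 0
    for tick, payload in events:
        track += _var_len(tick - clock)
        track += payload
        clock = tick
    track += _var_len(0) + b"\xff\x2f\x00"  # end of track

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, _TPQ))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))
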