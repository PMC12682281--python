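"""Probe-melody generation and deviant construction.

Probe melodies are constrained pseudo-random walks over the members of one
mode of a set class, confined to a single span of the tuning. Each probe is
paired with a note deviant (one middle note shifted one step, landing on a
pitch absent from the probe) and a contour deviant (the two middle notes
swapped). Triplets are organized into counterbalanced session plans and
exported as MIDI (octave tunings only) or frequency timelines.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .midi import write_midi_file
from .settheory import OCTAVE_12, PitchClassSet, SetClass, TuningSystem, modes

__all__ = [
    "MelodySpec",
    "Melody",
    "TrialTriplet",
    "SessionConfig",
    "SessionPlan",
    "MidiExportError",
    "GenerationError",
    "NOTE_DURATION_MS",
    "NOTE_GAP_MS",
    "ONSET_INTERVAL_MS",
    "INTER_MELODY_GAP_MS",
    "OCTAVE_TRANSPOSITION_BASES",
    "middle_indices",
    "generate_probe",
    "make_contour_deviant",
    "make_note_deviant",
    "make_triplet",
    "assign_transposition",
    "build_session",
    "timeline_frame",
    "melodies_from_timeline",
    "export_midi",
]

NOTE_DURATION_MS = 250
NOTE_GAP_MS = 83
#: onset-to-onset spacing; 333 ms, i.e. 3 notes per second
ONSET_INTERVAL_MS = NOTE_DURATION_MS + NOTE_GAP_MS
#: silence between the three melodies of a trial
INTER_MELODY_GAP_MS = 1000

#: admissible MIDI pitches for step 0 after transposition in octave tuning:
#: F#3 (54) .. F#4 (66), so melodies span F#3-F#4 up to F#4-F#5.
OCTAVE_TRANSPOSITION_BASES = tuple(range(54, 67))

_RETRY_CAP = 1000


class GenerationError(RuntimeError):
    """Constrained walk or triplet construction exhausted its retry cap."""


class MidiExportError(ValueError):
    """MIDI export requested for a tuning it cannot represent."""


@dataclass(frozen=True)
class MelodySpec:
    """Parameters of the constrained random walk."""

    set_class: SetClass
    length: int = 12
    tuning: TuningSystem = OCTAVE_12
    leap_limit: int = 6
    repetition_gap: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError(f"length must be >= 4, got {self.length}")
        if self.leap_limit < 1:
            raise ValueError(f"leap_limit must be >= 1, got {self.leap_limit}")
        if self.repetition_gap != 1:
            raise ValueError(
                "only repetition_gap=1 (no immediate repetition) is supported"
            )
        if self.set_class.divisions != self.tuning.divisions:
            raise ValueError("set class and tuning disagree on divisions")

    @property
    def range_steps(self) -> tuple[int, int]:
        """Inclusive pitch range: one full span of the tuning."""
        return (0, self.tuning.divisions)


@dataclass(frozen=True)
class Melody:
    """A sequence of steps within one span, plus a transposition anchor.

    ``steps`` are untransposed positions in ``[0, divisions]`` (the span
    note ``divisions`` is allowed; its pitch class is 0).
    ``transposition`` offsets all steps; in octave 12-EDO it is the MIDI
    number of step 0.
    """

    steps: tuple[int, ...]
    tuning: TuningSystem = OCTAVE_12
    transposition: int = 0
    note_duration_ms: int = NOTE_DURATION_MS
    gap_ms: int = NOTE_GAP_MS

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def onset_interval_ms(self) -> int:
        return self.note_duration_ms + self.gap_ms

    @property
    def total_duration_ms(self) -> int:
        """From first onset to the end of the last note."""
        return (len(self.steps) - 1) * self.onset_interval_ms + self.note_duration_ms

    def onsets_ms(self) -> np.ndarray:
        return np.arange(len(self.steps)) * self.onset_interval_ms

    def absolute_steps(self) -> tuple[int, ...]:
        return tuple(s + self.transposition for s in self.steps)

    def frequencies(self) -> np.ndarray:
        return self.tuning.frequency(np.asarray(self.absolute_steps()))

    def transposed(self, offset: int) -> "Melody":
        return dataclasses.replace(self, transposition=self.transposition + offset)


def middle_indices(length: int) -> tuple[int, int]:
    """0-based positions of the two designated middle notes.

    For lengths 8/12/16 these are notes 4/5, 6/7 and 8/9 (1-based).
    """
    if length < 4:
        raise ValueError("melody too short to have middle notes")
    return (length // 2 - 1, length // 2)


def _mode_pitches(mode: PitchClassSet, divisions: int) -> list[int]:
    """Pitches in [0, divisions] whose pitch class belongs to the mode."""
    member = set(mode.steps)
    return [p for p in range(divisions + 1) if p % divisions in member]


def generate_probe(
    spec: MelodySpec,
    rng: np.random.Generator | None = None,
    retry_cap: int = _RETRY_CAP,
) -> Melody:
    """Constrained pseudo-random walk over one mode of the set class.

    One mode is drawn uniformly per probe and fixed for the whole melody.
    At each position the next pitch is drawn uniformly from the pitches
    that are in range, in the mode, differ from the previous pitch, and
    lie within the leap limit. Dead ends restart the walk; ``retry_cap``
    restarts raise :class:`GenerationError`.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    divisions = spec.tuning.divisions
    mode_list = modes(spec.set_class.representative)
    for _ in range(retry_cap):
        mode = mode_list[rng.integers(len(mode_list))]
        pitches = _mode_pitches(mode, divisions)
        walk = [pitches[rng.integers(len(pitches))]]
        ok = True
        while len(walk) < spec.length:
            prev = walk[-1]
            options = [
                p for p in pitches if p != prev and abs(p - prev) <= spec.leap_limit
            ]
            if not options:
                ok = False
                break
            walk.append(options[rng.integers(len(options))])
        if ok:
            return Melody(steps=tuple(walk), tuning=spec.tuning)
    raise GenerationError(
        f"no legal walk found in {retry_cap} attempts for {spec.set_class}"
    )


def make_contour_deviant(probe: Melody) -> Melody:
    """Swap the two designated middle notes; pitch multiset is preserved."""
    i, j = middle_indices(len(probe))
    steps = list(probe.steps)
    assert steps[i] != steps[j], "no-repetition invariant violated in probe"
    steps[i], steps[j] = steps[j], steps[i]
    return dataclasses.replace(probe, steps=tuple(steps))


def make_note_deviant(
    probe: Melody,
    direction: int,
    rng: np.random.Generator,
) -> tuple[Melody, int] | None:
    """Shift one middle note by ``direction`` (+1/-1) step.

    The shifted pitch must stay within the span range and must not occur
    anywhere in the probe. Returns ``(deviant, position)``, or ``None``
    when neither middle position admits a legal shift — the caller then
    regenerates the whole triplet.
    """
    if direction not in (-1, 1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    lo, hi = 0, probe.tuning.divisions
    present = set(probe.steps)
    candidates = []
    for pos in middle_indices(len(probe)):
        shifted = probe.steps[pos] + direction
        if lo <= shifted <= hi and shifted not in present:
            candidates.append(pos)
    if not candidates:
        return None
    pos = candidates[int(rng.integers(len(candidates)))]
    steps = list(probe.steps)
    steps[pos] += direction
    return dataclasses.replace(probe, steps=tuple(steps)), pos


@dataclass(frozen=True)
class TrialTriplet:
    """Probe melody plus its two test melodies and trial bookkeeping."""

    probe: Melody
    note_deviant: Melody
    contour_deviant: Melody
    deviant_position: int
    shift_direction: int
    presentation_order: str = "note_first"  # which test melody plays first
    condition: str = ""
    block: int = 0
    trial: int = 0

    def melodies(self) -> list[tuple[str, Melody]]:
        if self.presentation_order == "note_first":
            tests = [("note_deviant", self.note_deviant),
                     ("contour_deviant", self.contour_deviant)]
        else:
            tests = [("contour_deviant", self.contour_deviant),
                     ("note_deviant", self.note_deviant)]
        return [("probe", self.probe)] + tests


def make_triplet(
    spec: MelodySpec,
    direction: int,
    rng: np.random.Generator,
    retry_cap: int = _RETRY_CAP,
) -> TrialTriplet:
    """Generate probe + deviants, regenerating until the shift is legal."""
    for _ in range(retry_cap):
        probe = generate_probe(spec, rng)
        result = make_note_deviant(probe, direction, rng)
        if result is None:
            continue
        deviant, pos = result
        return TrialTriplet(
            probe=probe,
            note_deviant=deviant,
            contour_deviant=make_contour_deviant(probe),
            deviant_position=pos,
            shift_direction=direction,
        )
    raise GenerationError(
        f"no valid triplet in {retry_cap} attempts for {spec.set_class}"
    )


def assign_transposition(
    triplet: TrialTriplet,
    offset: int,
    admissible: Sequence[int] | None = None,
) -> TrialTriplet:
    """Apply one common transposition offset to all three melodies."""
    if admissible is None and triplet.probe.tuning.is_octave:
        admissible = OCTAVE_TRANSPOSITION_BASES
    if admissible is not None and offset not in admissible:
        raise ValueError(
            f"transposition base {offset} outside admissible band "
            f"[{min(admissible)}, {max(admissible)}]"
        )
    return dataclasses.replace(
        triplet,
        probe=triplet.probe.transposed(offset),
        note_deviant=triplet.note_deviant.transposed(offset),
        contour_deviant=triplet.contour_deviant.transposed(offset),
    )


@dataclass(frozen=True)
class SessionConfig:
    """Layout of one participant session.

    ``layout`` is either ``"within_block"`` (every block splits its trials
    evenly across all conditions) or ``"block_per_condition"`` (each block
    is devoted to a single condition, cycling through the condition list).
    """

    conditions: tuple[tuple[str, SetClass], ...]
    melody_length: int = 12
    tuning: TuningSystem = OCTAVE_12
    n_blocks: int = 6
    trials_per_block: int = 20
    layout: str = "within_block"
    leap_limit: int = 6
    transposition_bases: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.layout == "within_block":
            per = self.trials_per_block / len(self.conditions)
            if per != int(per):
                raise ValueError(
                    f"{self.trials_per_block} trials per block cannot be "
                    f"split evenly across {len(self.conditions)} conditions"
                )
        elif self.layout == "block_per_condition":
            if self.n_blocks % len(self.conditions) != 0:
                raise ValueError(
                    "block_per_condition layout needs n_blocks divisible "
                    "by the number of conditions"
                )
        else:
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def bases(self) -> tuple[int, ...]:
        if self.transposition_bases is not None:
            return self.transposition_bases
        if self.tuning.is_octave:
            return OCTAVE_TRANSPOSITION_BASES
        return tuple(range(self.tuning.divisions + 1))


@dataclass(frozen=True)
class SessionPlan:
    """Triplets organized into blocks, with counterbalancing applied."""

    config: SessionConfig
    blocks: tuple[tuple[TrialTriplet, ...], ...]
    block_transpositions: tuple[int, ...]
    seed: int | None = None

    def trials(self) -> list[TrialTriplet]:
        return [t for block in self.blocks for t in block]

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    def trials_per_condition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials():
            out[t.condition] = out.get(t.condition, 0) + 1
        return out


def _counterbalanced(values: Sequence, n: int, rng: np.random.Generator) -> list:
    """n items drawn as evenly as possible from ``values``, shuffled."""
    reps = -(-n // len(values))  # ceil
    pool = (list(values) * reps)[:n]
    return [pool[i] for i in rng.permutation(n)]


def build_session(
    config: SessionConfig, seed: int | None = None
) -> SessionPlan:
    """Build a counterbalanced session plan.

    Within each block, shift directions and presentation orders each occur
    equally often (per condition). Transposition bases are counterbalanced
    across blocks: a random draw without replacement from the admissible
    bases, one base per block.
    """
    rng = np.random.default_rng(seed)
    bases = config.bases()
    if config.n_blocks <= len(bases):
        order = rng.permutation(len(bases))[: config.n_blocks]
        block_bases = [int(bases[i]) for i in order]
    else:
        block_bases = _counterbalanced(bases, config.n_blocks, rng)

    blocks: list[tuple[TrialTriplet, ...]] = []
    trial_counter = 0
    for b in range(config.n_blocks):
        if config.layout == "within_block":
            cond_list = list(config.conditions)
            per_cond = config.trials_per_block // len(cond_list)
        else:
            cond_list = [config.conditions[b % len(config.conditions)]]
            per_cond = config.trials_per_block

        block_trials: list[TrialTriplet] = []
        for label, set_class in cond_list:
            spec = MelodySpec(
                set_class=set_class,
                length=config.melody_length,
                tuning=config.tuning,
                leap_limit=config.leap_limit,
            )
            directions = _counterbalanced([1, -1], per_cond, rng)
            orders = _counterbalanced(
                ["note_first", "contour_first"], per_cond, rng
            )
            for direction, order_label in zip(directions, orders):
                triplet = make_triplet(spec, direction, rng)
                triplet = assign_transposition(
                    triplet, block_bases[b], admissible=bases
                )
                triplet = dataclasses.replace(
                    triplet,
                    presentation_order=order_label,
                    condition=label,
                    block=b,
                )
                block_trials.append(triplet)
        # randomize trial order within the block
        block_trials = [
            block_trials[i] for i in rng.permutation(len(block_trials))
        ]
        block_trials = [
            dataclasses.replace(t, trial=trial_counter + i)
            for i, t in enumerate(block_trials)
        ]
        trial_counter += len(block_trials)
        blocks.append(tuple(block_trials))
    return SessionPlan(
        config=config,
        blocks=tuple(blocks),
        block_transpositions=tuple(block_bases),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# export


def timeline_frame(plan: SessionPlan) -> pd.DataFrame:
    """Frequency timeline of every note event in the plan.

    Within a trial, the probe and the two test melodies play in their
    presentation order, separated by a 1000 ms gap. Columns: trial_id,
    melody_role, note_index, onset_ms, duration_ms, step, frequency_hz.
    """
    rows = []
    for triplet in plan.trials():
        offset = 0
        for role, melody in triplet.melodies():
            onsets = melody.onsets_ms() + offset
            freqs = melody.frequencies()
            for i, step in enumerate(melody.steps):
                rows.append(
                    {
                        "trial_id": triplet.trial,
                        "block": triplet.block,
                        "condition": triplet.condition,
                        "melody_role": role,
                        "note_index": i,
                        "onset_ms": int(onsets[i]),
                        "duration_ms": melody.note_duration_ms,
                        "step": step,
                        "transposition": melody.transposition,
                        "frequency_hz": float(freqs[i]),
                    }
                )
            offset = int(onsets[-1]) + melody.note_duration_ms + INTER_MELODY_GAP_MS
    return pd.DataFrame(rows)


def melodies_from_timeline(
    frame: pd.DataFrame, tuning: TuningSystem
) -> dict[tuple[int, str], Melody]:
    """Rebuild Melody objects from an exported timeline (round-trip)."""
    out: dict[tuple[int, str], Melody] = {}
    for (trial, role), grp in frame.groupby(["trial_id", "melody_role"]):
        grp = grp.sort_values("note_index")
        out[(int(trial), str(role))] = Melody(
            steps=tuple(int(s) for s in grp["step"]),
            tuning=tuning,
            transposition=int(grp["transposition"].iloc[0]),
        )
    return out


def export_midi(melody: Melody, path: str) -> None:
    """Write one melody as a format-0 Standard MIDI File.

    Only octave 12-EDO melodies have a MIDI representation; any other
    tuning raises :class:`MidiExportError` (export a frequency timeline
    instead).
    """
    if not (melody.tuning.is_octave and melody.tuning.divisions == 12):
        raise MidiExportError(
            "MIDI can only represent octave 12-EDO stimuli; use "
            "timeline_frame() to export a frequency timeline for this tuning"
        )
    onsets = melody.onsets_ms()
    notes = [
        (int(onsets[i]), melody.note_duration_ms, int(p))
        for i, p in enumerate(melody.absolute_steps())
    ]
    write_midi_file(path, notes)
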