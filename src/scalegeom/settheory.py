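"""Pitch-class set algebra in generalized equal-division tuning systems.

Sets are subsets of the step positions of an equal division of a span
(octave, tritave, ...). Equivalence is transpositional only: two sets
belong to the same class iff one is a cyclic rotation of the other.
Inversional (TnI) equivalence is deliberately not implemented.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TuningSystem",
    "PitchClassSet",
    "SetClass",
    "IntervalVector",
    "EvennessScore",
    "OCTAVE_12",
    "TRITAVE_12",
    "enumerate_subsets",
    "enumerate_set_classes",
    "modes",
    "interval_vector",
    "evenness",
    "step_frequency",
    "set_class_table",
]

#: display tokens for steps 10 and 11 in compact set strings
_STEP_TOKENS = "0123456789TE"


@dataclass(frozen=True)
class TuningSystem:
    """An equal division of a frequency span into logarithmically equal steps.

    Parameters
    ----------
    divisions : int
        Number of equal steps per span (>= 2).
    span_ratio : float
        Frequency ratio of the span; 2.0 for an octave, 3.0 for a tritave.
    base_frequency : float
        Frequency in Hz assigned to step 0.
    """

    divisions: int
    span_ratio: float = 2.0
    base_frequency: float = 440.0

    def __post_init__(self) -> None:
        if self.divisions < 2:
            raise ValueError(f"divisions must be >= 2, got {self.divisions}")
        if not self.span_ratio > 1:
            raise ValueError(f"span_ratio must be > 1, got {self.span_ratio}")
        if not self.base_frequency > 0:
            raise ValueError(
                f"base_frequency must be > 0, got {self.base_frequency}"
            )

    def frequency(self, step: int | np.ndarray) -> float | np.ndarray:
        """Frequency of an arbitrary (possibly negative) step index."""
        return self.base_frequency * self.span_ratio ** (
            np.asarray(step, dtype=float) / self.divisions
        )

    @property
    def is_octave(self) -> bool:
        return self.span_ratio == 2.0


#: standard Western tuning, anchored so that step k is MIDI note k
#: (step 69 = A4 = 440 Hz).
OCTAVE_12 = TuningSystem(12, 2.0, base_frequency=440.0 * 2.0 ** (-69 / 12))

#: 12 logarithmically equal divisions of the 3:1 tritave, anchored at 110 Hz.
TRITAVE_12 = TuningSystem(12, 3.0, base_frequency=110.0)


def step_frequency(step: int, tuning: TuningSystem) -> float:
    """Frequency in Hz of ``step`` in ``tuning``."""
    return float(tuning.frequency(step))


def _parse_steps(text: str, divisions: int) -> tuple[int, ...]:
    if "," in text:
        return tuple(int(t) for t in text.split(","))
    if divisions <= 12:
        return tuple(_STEP_TOKENS.index(c) for c in text)
    raise ValueError(
        "compact set strings are only defined for divisions <= 12; "
        "use comma-separated steps"
    )


@dataclass(frozen=True)
class PitchClassSet:
    """A subset of step positions of an equal-division tuning.

    ``steps`` is strictly increasing with every element in
    ``[0, divisions)``.
    """

    steps: tuple[int, ...]
    divisions: int = 12

    def __post_init__(self) -> None:
        steps = tuple(int(s) for s in self.steps)
        object.__setattr__(self, "steps", steps)
        if len(set(steps)) != len(steps):
            raise ValueError(f"duplicate steps in {steps}")
        if any(not 0 <= s < self.divisions for s in steps):
            raise ValueError(
                f"steps must lie in [0, {self.divisions}), got {steps}"
            )
        if tuple(sorted(steps)) != steps:
            raise ValueError(f"steps must be strictly increasing, got {steps}")

    @classmethod
    def from_string(cls, text: str, divisions: int = 12) -> "PitchClassSet":
        """Parse a compact string like ``"02479"`` or ``"0,2,4,7,9"``."""
        return cls(_parse_steps(text, divisions), divisions)

    @property
    def cardinality(self) -> int:
        return len(self.steps)

    def transpose(self, offset: int) -> "PitchClassSet":
        """Cyclic transposition by ``offset`` steps."""
        moved = sorted((s + offset) % self.divisions for s in self.steps)
        return PitchClassSet(tuple(moved), self.divisions)

    def rotation_anchored(self, anchor: int) -> "PitchClassSet":
        """The rotation that moves ``anchor`` (a member) to step 0."""
        if anchor not in self.steps:
            raise ValueError(f"{anchor} is not a member of {self}")
        return self.transpose(-anchor)

    def canonical(self) -> "PitchClassSet":
        """Lexicographically least rotation anchored at 0 (normal order)."""
        if not self.steps:
            raise ValueError("empty set has no canonical form")
        candidates = [self.rotation_anchored(a).steps for a in self.steps]
        return PitchClassSet(min(candidates), self.divisions)

    def symmetry_order(self) -> int:
        """Number of transpositions mapping the set onto itself."""
        return sum(
            1
            for t in range(self.divisions)
            if self.transpose(t).steps == tuple(sorted(self.steps))
        )

    def __str__(self) -> str:
        if self.divisions <= 12:
            return "".join(_STEP_TOKENS[s] for s in self.steps)
        return ",".join(str(s) for s in self.steps)


@dataclass(frozen=True)
class SetClass:
    """Transpositional equivalence class of pitch-class sets."""

    representative: PitchClassSet
    members: tuple[PitchClassSet, ...]

    @classmethod
    def of(cls, pcs: PitchClassSet) -> "SetClass":
        rep = pcs.canonical()
        seen: dict[tuple[int, ...], PitchClassSet] = {}
        for t in range(pcs.divisions):
            m = rep.transpose(t)
            seen.setdefault(m.steps, m)
        members = tuple(sorted(seen.values(), key=lambda m: m.steps))
        return cls(representative=rep, members=members)

    @property
    def cardinality(self) -> int:
        return self.representative.cardinality

    @property
    def divisions(self) -> int:
        return self.representative.divisions

    @property
    def set_id(self) -> str:
        return str(self.representative)

    def __contains__(self, pcs: PitchClassSet) -> bool:
        return pcs.canonical().steps == self.representative.steps

    def __str__(self) -> str:
        return self.set_id


@dataclass(frozen=True)
class IntervalVector:
    """Counts of unordered pairs at each circular interval class."""

    counts: tuple[int, ...]

    def __getitem__(self, ic: int) -> int:
        # interval classes are 1-based (IC1 .. IC floor(n/2))
        return self.counts[ic - 1]

    def __iter__(self):
        return iter(self.counts)


@dataclass(frozen=True)
class EvennessScore:
    """Deviation of a set from the perfectly even template.

    ``sd_deviation`` is the population standard deviation, in step units,
    of element-wise differences from the even template, minimized over
    rotations re-anchored at 0. ``evenness`` is its negation so that
    larger values mean more even.
    """

    sd_deviation: float

    @property
    def evenness(self) -> float:
        return -self.sd_deviation


def enumerate_subsets(divisions: int, cardinality: int) -> list[PitchClassSet]:
    """All C(divisions, cardinality) subsets, in lexicographic order."""
    if not 1 <= cardinality <= divisions:
        raise ValueError(
            f"cardinality must be in [1, {divisions}], got {cardinality}"
        )
    return [
        PitchClassSet(combo, divisions)
        for combo in itertools.combinations(range(divisions), cardinality)
    ]


def enumerate_set_classes(divisions: int, cardinality: int) -> list[SetClass]:
    """Partition all subsets into transpositional classes.

    Returns one class per canonical representative, ordered by
    representative steps.
    """
    by_rep: dict[tuple[int, ...], SetClass] = {}
    for pcs in enumerate_subsets(divisions, cardinality):
        rep = pcs.canonical().steps
        if rep not in by_rep:
            by_rep[rep] = SetClass.of(pcs)
    return [by_rep[k] for k in sorted(by_rep)]


def modes(pcs: PitchClassSet) -> list[PitchClassSet]:
    """Distinct rotations of the set re-anchored to begin at 0.

    The count equals cardinality divided by the rotational symmetry order.
    """
    if not pcs.steps:
        raise ValueError("empty set has no modes")
    out: list[PitchClassSet] = []
    seen: set[tuple[int, ...]] = set()
    for anchor in pcs.steps:
        rot = pcs.rotation_anchored(anchor)
        if rot.steps not in seen:
            seen.add(rot.steps)
            out.append(rot)
    return out


def interval_vector(pcs: PitchClassSet) -> IntervalVector:
    """Tally every unordered pair at its circular interval class."""
    if pcs.cardinality < 2:
        raise ValueError("interval vector requires cardinality >= 2")
    n = pcs.divisions
    counts = [0] * (n // 2)
    for a, b in itertools.combinations(pcs.steps, 2):
        d = (b - a) % n
        ic = min(d, n - d)
        counts[ic - 1] += 1
    return IntervalVector(tuple(counts))


def evenness(pcs: PitchClassSet) -> EvennessScore:
    """Distance of the set from a perfectly even k-note template.

    The template places note i at ``i * divisions / cardinality``. Each
    rotation of the set is re-anchored at 0 and differenced element-wise
    against the template; the score is the minimum population SD over
    rotations, which makes it invariant under transposition and mode
    choice.
    """
    if pcs.cardinality < 2:
        raise ValueError("evenness requires cardinality >= 2")
    k = pcs.cardinality
    template = np.arange(k) * pcs.divisions / k
    best = math.inf
    for mode in modes(pcs):
        diffs = np.asarray(mode.steps, dtype=float) - template
        sd = float(np.std(diffs))  # population SD (divide by k)
        best = min(best, sd)
    return EvennessScore(sd_deviation=best)


def set_class_table(classes: Iterable[SetClass]) -> pd.DataFrame:
    """Tabulate set classes with interval vectors and evenness scores.

    Columns: set_id, representative, cardinality, ic1..ic{n//2},
    sd_deviation, evenness.
    """
    rows = []
    for sc in classes:
        iv = interval_vector(sc.representative)
        ev = evenness(sc.representative)
        row: dict[str, object] = {
            "set_id": sc.set_id,
            "representative": str(sc.representative),
            "cardinality": sc.cardinality,
        }
        for i, c in enumerate(iv.counts, start=1):
            row[f"ic{i}"] = c
        row["sd_deviation"] = ev.sd_deviation
        row["evenness"] = ev.evenness
        rows.append(row)
    return pd.DataFrame(rows)
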