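"""Experiment presets tying tuning systems, sets and session layouts together.

exp1: pentatonic vs chromatic, melody length 8/12/16 (per cohort), octave.
exp2: all 66 five-note set classes, 6 sets per participant, length 12.
exp3: fully diminished 7th {0,3,6,9} vs whole-tone {0,2,4,6,8,10}, 12/16.
exp4: tritave tuning, pentatonic {0,2,4,7,9} vs control {0,1,2,4,8}, 12.
"""

from __future__ import annotations

import numpy as np

from .settheory import (
    OCTAVE_12,
    TRITAVE_12,
    PitchClassSet,
    SetClass,
    TuningSystem,
    enumerate_set_classes,
)
from .simulate import CohortDesign, ResponseModel
from .stimuli import SessionConfig

__all__ = [
    "PRESETS",
    "preset_session_config",
    "preset_cohort_design",
    "default_response_model",
    "pentatonic",
    "chromatic",
    "diminished7",
    "whole_tone",
    "low_control",
]

PRESETS = ("exp1", "exp2", "exp3", "exp4")


def _sc(steps: tuple[int, ...], divisions: int = 12) -> SetClass:
    return SetClass.of(PitchClassSet(steps, divisions))


def pentatonic() -> SetClass:
    return _sc((0, 2, 4, 7, 9))


def chromatic() -> SetClass:
    return _sc(tuple(range(12)))


def diminished7() -> SetClass:
    return _sc((0, 3, 6, 9))


def whole_tone() -> SetClass:
    return _sc((0, 2, 4, 6, 8, 10))


def low_control() -> SetClass:
    return _sc((0, 1, 2, 4, 8))


_DEFAULT_LENGTHS = {"exp1": 12, "exp2": 12, "exp3": 12, "exp4": 12}
_ALLOWED_LENGTHS = {
    "exp1": (8, 12, 16),
    "exp2": (12,),
    "exp3": (12, 16),
    "exp4": (12,),
}


def preset_session_config(
    name: str,
    melody_length: int | None = None,
    seed: int | None = None,
) -> SessionConfig:
    """Session plan configuration for one participant of a preset.

    For exp2, six of the 66 set classes are drawn for this participant
    (seeded), one block each.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    length = melody_length or _DEFAULT_LENGTHS[name]
    if length not in _ALLOWED_LENGTHS[name]:
        raise ValueError(
            f"preset {name} supports melody lengths {_ALLOWED_LENGTHS[name]}"
        )
    if name == "exp1":
        return SessionConfig(
            conditions=(("pentatonic", pentatonic()), ("chromatic", chromatic())),
            melody_length=length,
        )
    if name == "exp2":
        rng = np.random.default_rng(seed)
        classes = enumerate_set_classes(12, 5)
        chosen = [classes[i] for i in rng.choice(len(classes), 6, replace=False)]
        return SessionConfig(
            conditions=tuple((c.set_id, c) for c in chosen),
            melody_length=length,
            layout="block_per_condition",
        )
    if name == "exp3":
        return SessionConfig(
            conditions=(
                ("diminished7", diminished7()),
                ("whole_tone", whole_tone()),
            ),
            melody_length=length,
        )
    # exp4
    return SessionConfig(
        conditions=(("pentatonic_ut", _sc((0, 2, 4, 7, 9))),
                    ("control_ut", low_control())),
        melody_length=length,
        tuning=TRITAVE_12,
    )


def preset_cohort_design(
    name: str, melody_length: int | None = None
) -> CohortDesign:
    """Cohort-level design for the synthetic-participant simulator."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    length = melody_length or _DEFAULT_LENGTHS[name]
    if length not in _ALLOWED_LENGTHS[name]:
        raise ValueError(
            f"preset {name} supports melody lengths {_ALLOWED_LENGTHS[name]}"
        )
    if name == "exp1":
        return CohortDesign(
            sets=(pentatonic(), chromatic()),
            trials_per_set=60,
            melody_length=length,
            cohort=f"exp1_len{length}",
        )
    if name == "exp2":
        return CohortDesign(
            sets=tuple(enumerate_set_classes(12, 5)),
            sets_per_participant=6,
            trials_per_set=20,
            melody_length=length,
            cohort="exp2",
        )
    if name == "exp3":
        return CohortDesign(
            sets=(diminished7(), whole_tone()),
            trials_per_set=60,
            melody_length=length,
            cohort=f"exp3_len{length}",
        )
    return CohortDesign(
        sets=(pentatonic(), low_control()),
        trials_per_set=60,
        melody_length=length,
        cohort="exp4",
    )


def default_response_model(seed: int | None = None) -> ResponseModel:
    """A plausible generative stand-in: bias rises with evenness, IC3 and
    IC5 counts and melody length, falls with IC1 and IC6 counts."""
    return ResponseModel(
        intercept=0.3,
        beta_evenness=0.4,
        beta_ic=(-0.12, 0.0, 0.08, 0.0, 0.12, -0.16),
        beta_length=0.05,
        sigma_u=0.5,
        lapse=0.05,
        no_diff_rate=0.05,
        seed=seed,
    )
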