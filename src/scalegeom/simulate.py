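"""Synthetic two-alternative forced-choice cohorts.

Generates per-trial response tables with the statistical structure the
analysis stage assumes: a logistic choice model over set-level geometric
features (evenness, interval-class counts) and melody length, Gaussian
participant random intercepts, a lapse rate (uniform note/contour guess)
and a no-difference rate. Everything is seed-deterministic and vectorized
so that hundreds of cohorts can be simulated in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .settheory import SetClass, evenness, interval_vector

__all__ = [
    "ResponseModel",
    "CohortDesign",
    "set_features",
    "simulate_cohort",
    "simulate_exclusion_features",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = [
    "participant_id",
    "cohort",
    "set_id",
    "melody_length",
    "block",
    "trial",
    "choice",
    "comprehension_rating",
    "years_training",
    "plays_instrument",
]


@dataclass(frozen=True)
class ResponseModel:
    """Generative parameters for one synthetic cohort.

    The probability of choosing the note deviant on a non-lapse,
    non-no-difference trial is
    ``logistic(intercept + u_i + beta_evenness*evenness
    + sum_k beta_ic[k]*ic_k + beta_length*(length - 8))``
    with ``u_i ~ N(0, sigma_u)`` per participant. Features are used raw
    (counts 0-6, evenness in step units) so fitted coefficients are
    directly comparable to the planted ones.
    """

    intercept: float = 0.0
    beta_evenness: float = 0.0
    beta_ic: tuple[float, ...] = (0.0,) * 6
    beta_length: float = 0.0
    sigma_u: float = 0.0
    lapse: float = 0.0
    no_diff_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lapse < 1 and 0 <= self.no_diff_rate < 1):
            raise ValueError("lapse and no_diff_rate must be in [0, 1)")
        if self.lapse + self.no_diff_rate >= 1:
            raise ValueError("lapse + no_diff_rate must be < 1")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if len(self.beta_ic) != 6:
            raise ValueError("beta_ic must have 6 entries (IC1..IC6)")


@dataclass(frozen=True)
class CohortDesign:
    """Which sets each participant sees and how many trials per set."""

    sets: tuple[SetClass, ...]
    sets_per_participant: int | None = None
    trials_per_set: int = 20
    melody_length: int = 12
    cohort: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("design names no sets")
        k = self.sets_per_participant
        if k is not None and not 1 <= k <= len(self.sets):
            raise ValueError(
                f"sets_per_participant must be in [1, {len(self.sets)}]"
            )


def set_features(set_class: SetClass) -> dict[str, float]:
    """Raw geometric features used by both simulator and analysis."""
    iv = interval_vector(set_class.representative)
    feats: dict[str, float] = {
        f"ic{i}": float(c) for i, c in enumerate(iv.counts, start=1)
    }
    feats["evenness"] = evenness(set_class.representative).evenness
    return feats


def _linear_predictor(
    model: ResponseModel, feats: Mapping[str, float], length: int
) -> float:
    eta = model.intercept + model.beta_evenness * feats["evenness"]
    for k in range(6):
        eta += model.beta_ic[k] * feats[f"ic{k + 1}"]
    eta += model.beta_length * (length - 8)
    return eta


def simulate_cohort(
    model: ResponseModel,
    design: CohortDesign,
    n_participants: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one cohort; returns a per-trial response table.

    Per trial: with probability ``no_diff_rate`` the participant reports
    no difference; with probability ``lapse`` they pick note/contour
    uniformly; otherwise they pick the note deviant with the logistic
    probability of the response model.
    """
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)
    n_sets = len(design.sets)
    k = design.sets_per_participant or n_sets
    trials = design.trials_per_set

    eta_set = np.array(
        [
            _linear_predictor(model, set_features(s), design.melody_length)
            for s in design.sets
        ]
    )
    set_ids = np.array([s.set_id for s in design.sets])

    # per-participant set assignment (random k-subset when k < n_sets,
    # keeping administration approximately balanced across sets)
    if k == n_sets:
        assign = np.tile(np.arange(n_sets), (n_participants, 1))
    else:
        assign = np.empty((n_participants, k), dtype=int)
        for i in range(n_participants):
            assign[i] = rng.choice(n_sets, size=k, replace=False)

    u = rng.normal(0.0, model.sigma_u, size=n_participants)
    p_cond = expit(eta_set[assign] + u[:, None])  # (n_participants, k)

    n_cond = n_participants * k
    n_trials = n_cond * trials
    p_flat = np.repeat(p_cond.ravel(), trials)

    r1 = rng.random(n_trials)
    r2 = rng.random(n_trials)
    is_nodiff = r1 < model.no_diff_rate
    is_lapse = (~is_nodiff) & (r1 < model.no_diff_rate + model.lapse)
    threshold = np.where(is_lapse, 0.5, p_flat)
    is_note = (~is_nodiff) & (r2 < threshold)

    choice = np.where(is_nodiff, "no_difference", np.where(is_note, "note", "contour"))

    participant = np.repeat(np.arange(n_participants), k * trials)
    set_idx = np.repeat(assign.ravel(), trials)
    block = np.repeat(np.tile(np.arange(k), n_participants), trials)
    trial = np.tile(np.arange(k * trials), n_participants)

    comprehension = rng.integers(4, 6, size=n_participants)  # 4 or 5
    years = rng.integers(0, 11, size=n_participants)
    plays = years > 0

    return pd.DataFrame(
        {
            "participant_id": participant,
            "cohort": design.cohort,
            "set_id": set_ids[set_idx],
            "melody_length": design.melody_length,
            "block": block,
            "trial": trial,
            "choice": choice,
            "comprehension_rating": comprehension[participant],
            "years_training": years[participant],
            "plays_instrument": plays[participant],
        }
    )


def simulate_exclusion_features(
    table: pd.DataFrame,
    low_comprehension_fraction: float = 0.0,
    sparse_condition_fraction: float = 0.0,
    sparse_usable: int = 14,
    seed: int | None = None,
) -> pd.DataFrame:
    """Inject exclusion-worthy structure into a response table.

    A fraction of participants gets a comprehension rating of 3 or below;
    a fraction of (participant, set) conditions gets extra no-difference
    responses until only ``sparse_usable`` usable trials remain, which
    puts them under the default 15-response analysis threshold.
    """
    for name, frac in [
        ("low_comprehension_fraction", low_comprehension_fraction),
        ("sparse_condition_fraction", sparse_condition_fraction),
    ]:
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    out = table.copy()

    participants = out["participant_id"].unique()
    n_low = int(round(low_comprehension_fraction * len(participants)))
    if n_low:
        low = rng.choice(participants, size=n_low, replace=False)
        out.loc[out["participant_id"].isin(low), "comprehension_rating"] = (
            rng.integers(1, 4, size=int(out["participant_id"].isin(low).sum()))
        )

    conditions = out[["participant_id", "set_id"]].drop_duplicates()
    n_sparse = int(round(sparse_condition_fraction * len(conditions)))
    if n_sparse:
        pick = conditions.iloc[
            rng.choice(len(conditions), size=n_sparse, replace=False)
        ]
        for pid, sid in pick.itertuples(index=False):
            mask = (out["participant_id"] == pid) & (out["set_id"] == sid)
            usable = out.index[mask & (out["choice"] != "no_difference")]
            if len(usable) > sparse_usable:
                flip = usable[sparse_usable:]
                out.loc[flip, "choice"] = "no_difference"
    return out
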