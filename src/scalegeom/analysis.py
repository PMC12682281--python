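"""Statistical pipeline: exclusions, bias statistic, group tests,
evenness correlation, and interval-class ridge regression with
permutation inference.

The bias statistic for a (participant, set) condition is
``(n_note - n_contour) / (n_note + n_contour)`` after discarding
no-difference reports. Conditions with fewer than 15 usable responses and
participants with comprehension ratings of 3 or below are excluded.

Ridge regression of per-set mean bias on the six interval-class counts is
fitted with an unpenalized intercept and raw count predictors. For sets of
fixed cardinality the counts sum to a constant, so the predictors are
perfectly collinear; the ridge penalty is what makes the fit identified.
Inference is by permutation of the response across sets: the model p-value
is the upper-tail proportion of permuted R values, coefficient p-values are
two-sided tail proportions of |B|, and coefficient CIs are
``B_obs +/- q97.5(|B_perm - mean(B_perm)|)`` (a centered absolute-quantile
construction, recorded in the result metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.linear_model import Ridge

from .settheory import SetClass
from .simulate import set_features

__all__ = [
    "ExclusionResult",
    "apply_exclusions",
    "compute_bias",
    "set_score_table",
    "TestResult",
    "one_sample_t",
    "paired_t",
    "independent_t",
    "mixed_anova",
    "group_tests",
    "evenness_correlation",
    "RegressionResult",
    "ridge_interval_regression",
    "IC_PREDICTORS",
]

IC_PREDICTORS = tuple(f"ic{i}" for i in range(1, 7))

_REQUIRED_COLUMNS = {"participant_id", "set_id", "choice", "comprehension_rating"}


class ExclusionResult(NamedTuple):
    table: pd.DataFrame
    log: pd.DataFrame


def apply_exclusions(
    table: pd.DataFrame,
    min_responses: int = 15,
    comprehension_cutoff: int = 3,
) -> ExclusionResult:
    """Drop low-comprehension participants and under-responded conditions.

    Participants with a comprehension rating at or below the cutoff are
    removed entirely. Then every (participant, set) condition with fewer
    than ``min_responses`` usable (note + contour) responses is removed.
    Every removal is logged.
    """
    missing = _REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"response table lacks columns: {sorted(missing)}")
    log_rows: list[dict] = []

    comp = table.groupby("participant_id")["comprehension_rating"].first()
    bad_participants = comp.index[comp <= comprehension_cutoff]
    for pid in bad_participants:
        log_rows.append(
            {
                "reason": "low_comprehension",
                "participant_id": pid,
                "set_id": None,
                "detail": int(comp[pid]),
            }
        )
    kept = table[~table["participant_id"].isin(bad_participants)]

    usable = kept[kept["choice"] != "no_difference"]
    counts = usable.groupby(["participant_id", "set_id"]).size()
    all_conditions = kept.groupby(["participant_id", "set_id"]).size()
    n_usable = counts.reindex(all_conditions.index, fill_value=0)
    bad_conditions = n_usable.index[n_usable < min_responses]
    for pid, sid in bad_conditions:
        log_rows.append(
            {
                "reason": "too_few_responses",
                "participant_id": pid,
                "set_id": sid,
                "detail": int(n_usable[(pid, sid)]),
            }
        )
    if len(bad_conditions):
        idx = pd.MultiIndex.from_frame(kept[["participant_id", "set_id"]])
        kept = kept[~idx.isin(bad_conditions)]

    log = pd.DataFrame(
        log_rows, columns=["reason", "participant_id", "set_id", "detail"]
    )
    return ExclusionResult(kept.reset_index(drop=True), log)


def compute_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, set) bias toward note deviations.

    No-difference trials are dropped from the denominator. Conditions with
    zero usable responses get ``bias = NaN`` and ``valid = False`` rather
    than a silent zero.
    """
    extra = [
        c for c in ("cohort", "melody_length") if c in table.columns
    ]
    keys = ["participant_id", "set_id"] + extra
    counts = (
        table.groupby(keys, sort=True)["choice"]
        .value_counts()
        .unstack(fill_value=0)
    )
    for col in ("note", "contour", "no_difference"):
        if col not in counts:
            counts[col] = 0
    out = counts.reset_index().rename(
        columns={
            "note": "n_note",
            "contour": "n_contour",
            "no_difference": "n_nodiff",
        }
    )
    usable = out["n_note"] + out["n_contour"]
    with np.errstate(invalid="ignore"):
        out["bias"] = np.where(
            usable > 0, (out["n_note"] - out["n_contour"]) / usable, np.nan
        )
    out["valid"] = usable > 0
    out.columns.name = None
    return out[keys + ["n_note", "n_contour", "n_nodiff", "bias", "valid"]]


def set_score_table(
    bias_table: pd.DataFrame, set_classes: Sequence[SetClass]
) -> pd.DataFrame:
    """Per-set mean bias joined with geometric features.

    One row per set class: set_id, mean_bias, n_participants, evenness,
    ic1..ic6.
    """
    feats = pd.DataFrame(
        [{"set_id": s.set_id, **set_features(s)} for s in set_classes]
    )
    valid = bias_table[bias_table["valid"]] if "valid" in bias_table else bias_table
    agg = (
        valid.groupby("set_id")["bias"]
        .agg(mean_bias="mean", n_participants="count")
        .reset_index()
    )
    out = feats.merge(agg, on="set_id", how="left")
    cols = ["set_id", "mean_bias", "n_participants", "evenness", *IC_PREDICTORS]
    return out[cols]


# ---------------------------------------------------------------------------
# group tests


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float
    p_value: float
    effect_size: float
    effect_size_name: str = "cohen_d"

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
        }


def _check_variance(x: np.ndarray, label: str) -> None:
    if np.std(x, ddof=1) == 0:
        raise ValueError(f"{label} has zero variance; t-test undefined")


def one_sample_t(x: Iterable[float], popmean: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test against ``popmean`` with Cohen's d."""
    x = np.asarray(list(x), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    _check_variance(x, "sample")
    t, p = stats.ttest_1samp(x, popmean)
    d = (x.mean() - popmean) / x.std(ddof=1)
    return TestResult("one_sample_t", float(t), len(x) - 1, float(p), float(d))


def paired_t(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Two-tailed paired t-test; Cohen's d on the difference scores."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    _check_variance(diff, "difference scores")
    t, p = stats.ttest_rel(x, y)
    d = diff.mean() / diff.std(ddof=1)
    return TestResult("paired_t", float(t), len(x) - 1, float(p), float(d))


def independent_t(
    x: Iterable[float], y: Iterable[float], equal_var: bool = False
) -> TestResult:
    """Two-tailed independent-samples t-test (Welch by default).

    Cohen's d uses the pooled standard deviation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    _check_variance(np.concatenate([x, y]), "combined sample")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    d = (x.mean() - y.mean()) / pooled
    if equal_var:
        df = nx + ny - 2
    else:  # Welch-Satterthwaite
        vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
        df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    return TestResult("independent_t", float(t), float(df), float(p), float(d))


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "bias",
    within: str = "set_id",
    between: str = "melody_length",
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Two-way mixed ANOVA (within x between), F / df / p / partial eta sq.

    Participants missing any within-factor level are dropped listwise with
    a warning.
    """
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    incomplete = counts.index[counts < n_levels]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subjects with incomplete "
            f"within-factor data",
            stacklevel=2,
        )
        data = data[~data[subject].isin(incomplete)]
    cell_n = data.groupby([within, between])[dv].count()
    if (cell_n < 2).any():
        raise ValueError("every design cell needs at least 2 observations")
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    out = aov.rename(
        columns={
            "Source": "source",
            "p-unc": "p_value",
            "p_unc": "p_value",
            "np2": "eta_p2",
        }
    )
    return out[["source", "DF1", "DF2", "F", "p_value", "eta_p2"]]


def group_tests(
    bias_table: pd.DataFrame,
    condition_col: str = "set_id",
    between_col: str | None = None,
) -> pd.DataFrame:
    """Tidy report of the standard group tests on a bias table.

    One-sample t vs 0 per condition; paired t for every condition pair
    (within participants); if ``between_col`` is given and has >= 2
    levels, a two-way mixed ANOVA and pairwise independent-samples tests
    across its levels.
    """
    rows: list[dict] = []
    valid = bias_table[bias_table["valid"]] if "valid" in bias_table else bias_table

    for cond, grp in valid.groupby(condition_col):
        res = one_sample_t(grp["bias"])
        rows.append({"comparison": f"{cond} vs 0", **res.as_dict()})

    conds = sorted(valid[condition_col].unique())
    wide = valid.pivot_table(
        index="participant_id", columns=condition_col, values="bias"
    )
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            pair = wide[[a, b]].dropna()
            if len(pair) >= 2:
                res = paired_t(pair[a], pair[b])
                rows.append({"comparison": f"{a} vs {b}", **res.as_dict()})

    if between_col is not None and valid[between_col].nunique() >= 2:
        levels = sorted(valid[between_col].unique())
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                xa = valid.loc[valid[between_col] == a, "bias"]
                xb = valid.loc[valid[between_col] == b, "bias"]
                res = independent_t(xa, xb)
                rows.append(
                    {"comparison": f"{between_col} {a} vs {b}", **res.as_dict()}
                )
        aov = mixed_anova(
            valid, dv="bias", within=condition_col, between=between_col
        )
        for _, r in aov.iterrows():
            rows.append(
                {
                    "comparison": f"mixed_anova {r['source']}",
                    "test": "mixed_anova",
                    "statistic": r["F"],
                    "df": r["DF1"],
                    "p_value": r["p_value"],
                    "effect_size": r["eta_p2"],
                    "effect_size_name": "eta_p2",
                }
            )
    return pd.DataFrame(rows)


def evenness_correlation(set_scores: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of set evenness with mean bias (two-tailed p)."""
    scores = set_scores.dropna(subset=["mean_bias"])
    if len(scores) < 3:
        raise ValueError("need at least 3 sets")
    x = scores["evenness"].to_numpy(dtype=float)
    y = scores["mean_bias"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in evenness or bias")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# ridge + permutation


@dataclass(frozen=True)
class RegressionResult:
    """Ridge fit with permutation-based inference."""

    predictors: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    r: float
    model_p: float
    coef_p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    penalty: float
    n_perm: int
    seed: int | None
    loo_r: float | None = None
    ci_method: str = "B_obs +/- q97.5(|B_perm - mean(B_perm)|)"

    def as_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": self.intercept,
            "r": self.r,
            "model_p": self.model_p,
            "coef_p": [float(p) for p in self.coef_p],
            "ci_low": [float(c) for c in self.ci_low],
            "ci_high": [float(c) for c in self.ci_high],
            "penalty": self.penalty,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "loo_r": self.loo_r,
            "ci_method": self.ci_method,
        }


def _ridge_coef_matrix(Xc: np.ndarray, penalty: float) -> np.ndarray:
    """Linear map from centered responses to ridge coefficients."""
    p = Xc.shape[1]
    return np.linalg.solve(Xc.T @ Xc + penalty * np.eye(p), Xc.T)


def _pearson_columns(f: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of fitted matrix with response matrix."""
    fc = f - f.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (fc * yc).sum(axis=0)
    den = np.sqrt((fc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(np.isfinite(r), r, 0.0)


def ridge_interval_regression(
    set_scores: pd.DataFrame,
    penalty: float = 1.0,
    n_perm: int = 10_000,
    seed: int | None = None,
    predictors: Sequence[str] = IC_PREDICTORS,
    include_loo: bool = False,
) -> RegressionResult:
    """Ridge regression of mean bias on interval-class counts.

    The intercept is unpenalized (predictors and response are centered
    before the penalized solve, as scikit-learn does). The model R is the
    in-sample Pearson correlation of fitted values with observed values;
    ``include_loo`` adds a leave-one-out variant as a labeled extra.
    Permutation inference shuffles the response across sets and refits;
    p-values use the ``(r + 1) / (n_perm + 1)`` floor.
    """
    scores = set_scores.dropna(subset=["mean_bias"])
    X = scores[list(predictors)].to_numpy(dtype=float)
    y = scores["mean_bias"].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more sets ({n}) than predictors ({p})")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is low; permutation p-values will be coarse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    model = Ridge(alpha=penalty)
    model.fit(X, y)
    coef = model.coef_.copy()
    fitted = model.predict(X)
    r_obs = float(_pearson_columns(fitted[:, None], y[:, None])[0])

    # permutations via the closed-form ridge map (linear in the response)
    Xc = X - X.mean(axis=0)
    M = _ridge_coef_matrix(Xc, penalty)  # (p, n)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)  # rows: permutations
    Yp = y[perm_idx].T  # (n, n_perm)
    Ypc = Yp - Yp.mean(axis=0)
    B_perm = M @ Ypc  # (p, n_perm)
    F_perm = Xc @ B_perm + Yp.mean(axis=0)  # fitted values per permutation
    R_perm = _pearson_columns(F_perm, Yp)

    model_p = (np.sum(R_perm >= r_obs) + 1) / (n_perm + 1)
    coef_p = (
        np.sum(np.abs(B_perm) >= np.abs(coef)[:, None], axis=1) + 1
    ) / (n_perm + 1)
    half = np.percentile(
        np.abs(B_perm - B_perm.mean(axis=1, keepdims=True)), 97.5, axis=1
    )

    loo_r = None
    if include_loo:
        preds = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m = Ridge(alpha=penalty).fit(X[mask], y[mask])
            preds[i] = m.predict(X[i : i + 1])[0]
        loo_r = float(_pearson_columns(preds[:, None], y[:, None])[0])

    return RegressionResult(
        predictors=tuple(predictors),
        coefficients=coef,
        intercept=float(model.intercept_),
        r=r_obs,
        model_p=float(model_p),
        coef_p=coef_p,
        ci_low=coef - half,
        ci_high=coef + half,
        penalty=penalty,
        n_perm=n_perm,
        seed=seed,
        loo_r=loo_r,
    )
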