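"""Sensitivity analyses on the pooled prediction-outcome pairs.

1. Race moderation: outcome ~ prediction * race + (1 | person); the joint F
   test over all prediction x race interaction terms asks whether predictive
   performance differs across racial groups.
2. Lagged-outcome control: outcome_t ~ prediction_t + outcome_{t-1} +
   (1 | person); a positive prediction slope that survives the lag control
   shows the model is not merely carrying the last observation forward.

Both are random-intercept mixed models estimated by REML with
Satterthwaite-type (fractional) degrees of freedom.  The race reference
level is the most frequent category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, NotTestableError
from .mixedlm import MixedLMResult, fit_random_intercept
from .panel import PersonProfile


@dataclass
class ModerationResult:
    f_stat: float
    df_num: int
    df_den: float
    p_value: float
    interaction_coefficients: dict[str, float]
    model: MixedLMResult


@dataclass
class LaggedControlResult:
    beta1: float
    se: float
    t_stat: float
    df: float
    p_value: float
    n: int
    collinear: bool
    model: MixedLMResult


def _race_map(profiles: list[PersonProfile]) -> dict[str, str]:
    return {p.person_id: p.race_group for p in profiles}


def race_moderation_test(
    pairs: pd.DataFrame, profiles: list[PersonProfile]
) -> ModerationResult:
    """Joint F test of all prediction x race interactions.

    `pairs` must carry ``person_id``, ``y_observed`` and
    ``yhat_idiographic`` (imputation-averaged).  Requires at least two race
    levels, each contributed by at least two persons.
    """
    df = pairs.copy()
    df["race"] = df["person_id"].map(_race_map(profiles))
    persons_per_level = df.groupby("race")["person_id"].nunique()
    usable = persons_per_level[persons_per_level >= 2].index
    if len(persons_per_level) < 2:
        raise NotTestableError("race moderation needs >= 2 race levels")
    if len(usable) < 2:
        raise NotTestableError(
            "race moderation needs >= 2 race levels with >= 2 persons each"
        )
    df = df[df["race"].isin(usable)]

    counts = df["race"].value_counts()
    reference = counts.index[0]
    others = [lvl for lvl in sorted(counts.index) if lvl != reference]
    pred = df["yhat_idiographic"].to_numpy(dtype=float)
    cols = [np.ones(len(df)), pred]
    names = ["intercept", "prediction"]
    for lvl in others:
        ind = (df["race"] == lvl).to_numpy(dtype=float)
        cols += [ind, ind * pred]
        names += [f"race[{lvl}]", f"prediction:race[{lvl}]"]
    X = np.column_stack(cols)
    res = fit_random_intercept(
        X, df["y_observed"].to_numpy(dtype=float), df["person_id"].to_numpy(), names
    )
    inter_idx = [i for i, nm in enumerate(names) if nm.startswith("prediction:race[")]
    L = np.zeros((len(inter_idx), X.shape[1]))
    for row, i in enumerate(inter_idx):
        L[row, i] = 1.0
    ftest = res.f_test(L)
    coefs = {names[i]: float(res.beta[i]) for i in inter_idx}
    return ModerationResult(
        f_stat=ftest["f"],
        df_num=int(ftest["df_num"]),
        df_den=ftest["df_den"],
        p_value=ftest["p"],
        interaction_coefficients=coefs,
        model=res,
    )


def build_lagged_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach the previous-hour outcome; rows without hour t-1 are dropped.

    The lag index is strictly t-1 — future hours are never consulted.
    """
    df = pairs.sort_values(["person_id", "hour_index"]).copy()
    prev = df[["person_id", "hour_index", "y_observed"]].copy()
    prev["hour_index"] = prev["hour_index"] + 1
    prev = prev.rename(columns={"y_observed": "y_lagged"})
    merged = df.merge(prev, on=["person_id", "hour_index"], how="inner")
    return merged


def lagged_outcome_test(pairs: pd.DataFrame) -> LaggedControlResult:
    """Prediction slope controlling for the previous-hour outcome."""
    df = build_lagged_pairs(pairs)
    if len(df) < 10:
        raise InsufficientDataError(
            f"only {len(df)} consecutive-hour pairs; lagged control needs >= 10"
        )
    pred = df["yhat_idiographic"].to_numpy(dtype=float)
    lag = df["y_lagged"].to_numpy(dtype=float)
    collinear = False
    if np.std(pred) > 0 and np.std(lag) > 0:
        if abs(np.corrcoef(pred, lag)[0, 1]) > 0.999:
            collinear = True
            warnings.warn(
                "prediction and lagged outcome are collinear; "
                "the prediction coefficient is not interpretable"
            )
    X = np.column_stack([np.ones(len(df)), pred, lag])
    res = fit_random_intercept(
        X,
        df["y_observed"].to_numpy(dtype=float),
        df["person_id"].to_numpy(),
        ["intercept", "prediction", "lagged_outcome"],
    )
    tt = res.t_test(np.array([0.0, 1.0, 0.0]))
    return LaggedControlResult(
        beta1=tt["estimate"],
        se=tt["se"],
        t_stat=tt["t"],
        df=tt["df"],
        p_value=tt["p"],
        n=len(df),
        collinear=collinear,
        model=res,
    )


def sensitivity_report_lines(
    moderation: ModerationResult | None, lagged: LaggedControlResult | None
) -> list[str]:
    lines = []
    if moderation is not None:
        lines.append(
            f"race moderation: F({moderation.df_num}, {moderation.df_den:.1f}) = "
            f"{moderation.f_stat:.3f}, p = {moderation.p_value:.3f}"
        )
    if lagged is not None:
        lines.append(
            f"lagged-outcome control: beta1 = {lagged.beta1:.3f}, SE = {lagged.se:.3f}, "
            f"t({lagged.df:.0f}) = {lagged.t_stat:.3f}, p = {lagged.p_value:.2g}"
            + (" [collinear]" if lagged.collinear else "")
        )
    return lines
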