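"""Multiple imputation of the sensor panel.

Chained-equation-style iterative conditional draws over the numeric sensor
fields: each field with missing cells is regressed (Bayesian ridge) on the
other sensors, person indicators and hour-of-day harmonics, and missing
cells are replaced by draws from the posterior predictive.  Categorical
fields are drawn from the person's observed category distribution (cohort
distribution as fallback).  Mood items are the *outcome* and are never
imputed and never used as imputation predictors — a deliberate firewall so
that no future outcome can leak into any model-input feature.

Imputed numeric values are clamped to the person's observed range when that
person has >= 3 observations of the variable, else to the cohort range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge

from .config import child_rng
from .exceptions import ConfigError
from .panel import (
    SENSOR_CATEGORICAL,
    SENSOR_NUMERIC,
    ImputedPanelSet,
    Panel,
)

_S_IMPUTE = 7
N_SWEEPS = 3


def _predictor_matrix(df: pd.DataFrame, values: pd.DataFrame, skip: str) -> np.ndarray:
    """Current completed numeric sensors (minus `skip`) + person dummies +
    hour-of-day harmonics."""
    cols = [c for c in SENSOR_NUMERIC if c != skip]
    blocks = [values[cols].to_numpy(dtype=float)]
    persons = pd.get_dummies(df["person_id"]).to_numpy(dtype=float)
    hod = df["hour_index"].to_numpy() % 24
    harm = np.column_stack(
        [np.sin(2 * np.pi * hod / 24), np.cos(2 * np.pi * hod / 24)]
    )
    blocks += [persons, harm]
    return np.hstack(blocks)


def _clamp_to_ranges(
    df: pd.DataFrame, col: str, observed: pd.Series, imputed: np.ndarray, miss_idx: np.ndarray
) -> np.ndarray:
    """Range contract: person range when >=3 person-observations, else cohort."""
    lo_all, hi_all = observed.min(), observed.max()
    out = imputed.copy()
    pid = df["person_id"].to_numpy()
    obs_mask = observed.notna().to_numpy()
    for person in np.unique(pid[miss_idx]):
        prows = pid == person
        pobs = observed[prows & obs_mask]
        lo, hi = (pobs.min(), pobs.max()) if len(pobs) >= 3 else (lo_all, hi_all)
        sel = prows[miss_idx]
        out[sel] = np.clip(out[sel], lo, hi)
    return out


def _impute_once(panel: Panel, rng: np.random.Generator) -> Panel:
    out = panel.copy()
    df = out.data
    obs = {c: df[c].copy() for c in SENSOR_NUMERIC}
    miss = {c: df[c].isna().to_numpy() for c in SENSOR_NUMERIC}

    # initialize missing numerics with person means (cohort mean fallback)
    values = df[SENSOR_NUMERIC].copy()
    person_means = values.groupby(df["person_id"]).transform("mean")
    cohort_means = values.mean()
    values = values.fillna(person_means).fillna(cohort_means).fillna(0.0)

    targets = [c for c in SENSOR_NUMERIC if miss[c].any() and (~miss[c]).sum() >= 10]
    for _ in range(N_SWEEPS):
        for col in targets:
            X = _predictor_matrix(df, values, skip=col)
            m = miss[col]
            model = BayesianRidge()
            model.fit(X[~m], obs[col][~m].to_numpy(dtype=float))
            mean, std = model.predict(X[m], return_std=True)
            draw = rng.normal(mean, std)
            draw = _clamp_to_ranges(df, col, obs[col], draw, m)
            values.loc[m, col] = draw
    for col in SENSOR_NUMERIC:
        if miss[col].any():
            df[col] = np.where(miss[col], values[col], obs[col])
    df["outgoing_calls"] = np.round(np.clip(df["outgoing_calls"], 0, None))

    # categoricals: draw within the observed category sets
    pid = df["person_id"].to_numpy()
    for col in SENSOR_CATEGORICAL:
        colvals = df[col].to_numpy(dtype=object)
        isna = pd.isna(colvals)
        if not isna.any():
            continue
        cohort_counts = pd.Series(colvals[~isna]).value_counts(normalize=True)
        for person in np.unique(pid[isna]):
            prows = pid == person
            pobs = pd.Series(colvals[prows & ~isna])
            dist = pobs.value_counts(normalize=True) if len(pobs) else cohort_counts
            fill_n = int((prows & isna).sum())
            draws = rng.choice(dist.index.to_numpy(), size=fill_n, p=dist.to_numpy())
            colvals[prows & isna] = draws
        df[col] = colvals
    return out


def impute(panel: Panel, m: int = 5, seed: int = 0) -> ImputedPanelSet:
    """Produce `m` completed copies of the panel's sensor fields.

    Observed cells are untouched in every copy; copies differ only in their
    stochastic draws for the missing cells (identical when nothing is
    missing).  ``m < 2`` is a configuration error: a single imputation
    cannot propagate imputation uncertainty.
    """
    if m < 2:
        raise ConfigError("multiple imputation requires m >= 2 copies")
    panels = []
    for k in range(m):
        rng = child_rng(seed, _S_IMPUTE, k)
        panels.append(_impute_once(panel, rng))
    return ImputedPanelSet(panels=panels, m=m, imputation_seed=seed)
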