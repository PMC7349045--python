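"""Rolling 24-h windows and the two-phase predictive models.

For each target hour t a window collects the trailing 24 h of person-hours
with an observed mood composite; temporal direction is never reversed — no
training row may be at hour >= t.  Phase 1 fits one pooled gradient-boosted
model (XGBoost) of the *within-person-centered* outcome on the sensor
features; its predictions are appended to the design as a single stacked
feature.  Phase 2 fits, per person, a randomized-forest regression in which
the target person's rows carry weight 1.0 and everyone else's 0.2, with a
grid search over the per-split candidate count (three evenly spaced values
in [1, p]) crossed with the split rule (variance vs extremely randomized),
scored by person-blocked cross-validation inside the training window only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold
from xgboost import XGBRegressor

from .config import IdiographicConfig, NomotheticConfig, WeightScheme
from .exceptions import AlignmentError, ConfigError, WindowSkipped
from .panel import FeatureCodec

log = logging.getLogger(__name__)

SPLIT_RULE_VARIANCE = "variance"
SPLIT_RULE_EXTRATREES = "extratrees"


@dataclass
class WindowSpec:
    """A target hour plus its trailing training set (half-open [t-L, t))."""

    target_hour: int
    lookback: int
    training: pd.DataFrame  # rows in [t-L, t) with observed mood
    prediction: pd.DataFrame  # all rows at hour t

    def __post_init__(self) -> None:
        if len(self.training) and int(self.training["hour_index"].max()) >= self.target_hour:
            raise AlignmentError("training rows must strictly precede the target hour")


def build_window(df: pd.DataFrame, t: int, lookback: int = 24) -> WindowSpec:
    """Cut the window for target hour `t` from a panel with a `mood` column.

    Rows lacking the outcome are excluded from training but remain eligible
    prediction rows.  An empty training set raises :class:`WindowSkipped`
    (logged by callers, never fatal).
    """
    if t < lookback:
        raise ConfigError(f"target hour {t} precedes the first full window ({lookback})")
    in_window = (df["hour_index"] >= t - lookback) & (df["hour_index"] < t)
    training = df[in_window & df["mood"].notna()]
    prediction = df[df["hour_index"] == t]
    if not len(training):
        raise WindowSkipped(f"no observed outcomes in [{t - lookback}, {t})")
    return WindowSpec(t, lookback, training.copy(), prediction.copy())


# ---------------------------------------------------------------------------
# Phase 1: pooled (nomothetic) gradient boosting on centered outcome
# ---------------------------------------------------------------------------

@dataclass
class NomotheticModel:
    booster: XGBRegressor
    codec: FeatureCodec
    person_means: dict[str, float] = field(default_factory=dict)
    cohort_mean: float = 0.0
    centered: bool = True

    def center(self, df: pd.DataFrame) -> np.ndarray:
        """Within-person-centered outcome; persons unseen in the training
        window fall back to cohort-mean centering."""
        mu = df["person_id"].map(self.person_means).fillna(self.cohort_mean)
        return df["mood"].to_numpy(dtype=float) - mu.to_numpy(dtype=float)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predictions on the centered scale (raw scale if centering off)."""
        return self.booster.predict(self.codec.transform(df)).astype(float)


def fit_nomothetic(
    window: WindowSpec,
    codec: FeatureCodec,
    config: NomotheticConfig,
    seed: int = 0,
) -> NomotheticModel:
    """Fit the pooled boosted-tree stage on the window's training rows."""
    config.validate()
    df = window.training
    if len(df) < 2:
        raise WindowSkipped("nomothetic stage needs >= 2 training rows")
    if config.center_within_person:
        means = df.groupby("person_id")["mood"].mean().to_dict()
        cohort = float(df["mood"].mean())
        target = df["mood"].to_numpy(dtype=float) - df["person_id"].map(means).to_numpy(dtype=float)
    else:
        means, cohort = {}, 0.0
        target = df["mood"].to_numpy(dtype=float)
    booster = XGBRegressor(
        n_estimators=config.rounds,
        max_depth=config.depth,
        learning_rate=config.learning_rate,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    booster.fit(codec.transform(df), target)
    return NomotheticModel(
        booster=booster,
        codec=codec,
        person_means=means,
        cohort_mean=cohort,
        centered=config.center_within_person,
    )


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def augment_features(X: np.ndarray, nomothetic_predictions: np.ndarray) -> np.ndarray:
    """Append the nomothetic prediction as one stacked column (p -> p+1)."""
    X = np.asarray(X, dtype=float)
    preds = np.asarray(nomothetic_predictions, dtype=float).ravel()
    if X.shape[0] != preds.shape[0]:
        raise AlignmentError(
            f"{X.shape[0]} rows but {preds.shape[0]} nomothetic predictions"
        )
    return np.hstack([X, preds[:, None]])


# ---------------------------------------------------------------------------
# Phase 2: idiographically-weighted randomized forest
# ---------------------------------------------------------------------------

def _make_forest(rule: str, max_features: int, n_trees: int, seed: int):
    cls = {
        SPLIT_RULE_VARIANCE: RandomForestRegressor,
        SPLIT_RULE_EXTRATREES: ExtraTreesRegressor,
    }[rule]
    return cls(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )


def per_split_candidate_grid(p: int) -> list[int]:
    """Three evenly spaced integer per-split candidate counts in [1, p]."""
    return sorted(set(int(v) for v in np.round(np.linspace(1, p, 3))))


@dataclass
class IdiographicModel:
    estimator: object
    split_rule: str
    max_features: int
    grid_searched: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=float)


def _cv_folds(person_ids: np.ndarray, n_folds: int, seed: int):
    """Person-blocked folds inside the training window; plain K-fold when
    there are fewer persons than folds."""
    n = len(person_ids)
    groups = pd.factorize(person_ids)[0]
    n_groups = groups.max() + 1
    if n_groups >= n_folds:
        return list(GroupKFold(n_splits=n_folds).split(np.zeros(n), groups=groups))
    k = min(n_folds, n)
    if k < 2:
        return []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


def fit_idiographic(
    X: np.ndarray,
    y: np.ndarray,
    person_ids: np.ndarray,
    target_person: str,
    weights: WeightScheme,
    config: IdiographicConfig,
    seed: int = 0,
) -> IdiographicModel:
    """Fit the person-weighted forest for one target person.

    Exact degeneracies hold by construction: equal weights fit an
    unweighted pooled forest; zero other-weight drops the other persons'
    rows entirely, reproducing a person-only forest under the same seed.
    Grid search (when enabled) scores weighted MSE on person-blocked folds
    of the training window only — prediction rows are never touched.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    person_ids = np.asarray(person_ids)
    if len(y) < 2:
        raise WindowSkipped("idiographic stage needs >= 2 training rows")
    if target_person not in set(person_ids):
        log.info("person %s absent from training window; fitting on others", target_person)

    w = np.where(person_ids == target_person, weights.target_weight, weights.other_weight)
    if weights.other_weight == 0:
        keep = w > 0
        X, y, person_ids, w = X[keep], y[keep], person_ids[keep], w[keep]
        if len(y) < 2:
            raise WindowSkipped("zero other-weight left < 2 training rows")
    sample_weight = None if np.allclose(w, w[0]) else w

    p = X.shape[1]
    if not config.grid_search:
        mf = max(1, int(round(np.sqrt(p))))
        est = _make_forest(SPLIT_RULE_VARIANCE, mf, config.forest_size, seed)
        est.fit(X, y, sample_weight=sample_weight)
        return IdiographicModel(est, SPLIT_RULE_VARIANCE, mf, grid_searched=False)

    folds = _cv_folds(person_ids, config.cv_folds, seed)
    grid = per_split_candidate_grid(p)
    best = None  # (score, mf, rule); ties keep the earlier (smaller mf, variance)
    for mf in grid:
        for rule in (SPLIT_RULE_VARIANCE, SPLIT_RULE_EXTRATREES):
            scores = []
            for tr, va in folds:
                wv = w[va]
                if wv.sum() == 0 or len(tr) < 2:
                    continue
                est = _make_forest(rule, mf, config.forest_size, seed)
                swt = None if sample_weight is None else w[tr]
                est.fit(X[tr], y[tr], sample_weight=swt)
                err = (est.predict(X[va]) - y[va]) ** 2
                scores.append(float(np.average(err, weights=wv)))
            score = float(np.mean(scores)) if scores else np.inf
            if best is None or score < best[0] - 1e-12:
                best = (score, mf, rule)
    _, mf, rule = best
    est = _make_forest(rule, mf, config.forest_size, seed)
    est.fit(X, y, sample_weight=sample_weight)
    return IdiographicModel(est, rule, mf, grid_searched=True)


# ---------------------------------------------------------------------------
# Hour-t prediction records
# ---------------------------------------------------------------------------

def predict_hour(
    idiographic_models: dict[str, IdiographicModel],
    nomothetic: NomotheticModel,
    window: WindowSpec,
    imputation_id: int = 0,
) -> pd.DataFrame:
    """One record per person with an observed outcome at the target hour.

    Predictions use only hour-t sensor features and models fitted strictly
    on [t-lookback, t).
    """
    rows = window.prediction
    observed = rows[rows["mood"].notna()]
    records = []
    for _, row in observed.iterrows():
        pid = row["person_id"]
        if pid not in idiographic_models:
            continue
        rf = idiographic_models[pid]
        one = observed[observed["person_id"] == pid]
        Xp = nomothetic.codec.transform(one)
        yhat_nomo = nomothetic.predict(one)
        Xs = augment_features(Xp, yhat_nomo)
        records.append(
            {
                "person_id": pid,
                "hour_index": window.target_hour,
                "imputation_id": imputation_id,
                "y_observed": float(row["mood"]),
                "yhat_nomothetic": float(yhat_nomo[0]),
                "yhat_idiographic": float(rf.predict(Xs)[0]),
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "person_id",
            "hour_index",
            "imputation_id",
            "y_observed",
            "yhat_nomothetic",
            "yhat_idiographic",
        ],
    )
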