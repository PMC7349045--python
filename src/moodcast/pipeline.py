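"""End-to-end orchestration: for each imputation copy, each target hour and
each person, fit the two-phase model and record out-of-sample predictions.

Every fit is enumerated in a ledger (imputation, hour, person, status,
chosen hyperparameters), so the fit-count contract — persons x target hours
x imputations, minus enumerated skips — is auditable.  A dry run emits the
planned ledger without training anything.

Child seeds are keyed by (imputation, hour, person slot), never by
execution order, so any single fit is reproducible in isolation and results
are independent of parallelism or iteration order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig, child_seed
from .exceptions import WindowSkipped
from .panel import FeatureCodec, ImputedPanelSet, add_outcome
from .windows import (
    augment_features,
    build_window,
    fit_idiographic,
    fit_nomothetic,
    predict_hour,
)

log = logging.getLogger(__name__)

# seed-stream tags for the two model phases
_S_NOMOTHETIC, _S_IDIOGRAPHIC = 101, 202

LEDGER_COLS = [
    "imputation_id",
    "hour_index",
    "person_id",
    "status",
    "reason",
    "n_train",
    "max_features",
    "split_rule",
]
PREDICTION_COLS = [
    "person_id",
    "hour_index",
    "imputation_id",
    "y_observed",
    "yhat_nomothetic",
    "yhat_idiographic",
]


def default_target_hours(config: RunConfig) -> list[int]:
    n_hours = config.cohort.n_hours
    return list(range(config.lookback, n_hours, config.hour_stride))


def run_pipeline(
    imputed: ImputedPanelSet,
    config: RunConfig,
    target_hours: list[int] | None = None,
    dry_run: bool = False,
    fit_only_observed: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the two-phase pipeline over all imputations and target hours.

    Returns ``(predictions, ledger)``.  With ``fit_only_observed`` (the
    default) idiographic models are fitted only for persons whose outcome is
    observed at the target hour — the others could never be evaluated and
    are logged as skips.  A dry run plans one fit per (person, hour,
    imputation) regardless, and trains nothing.
    """
    config.validate()
    if target_hours is None:
        target_hours = default_target_hours(config)
    profiles = imputed.panels[0].profiles
    person_index = {p.person_id: j for j, p in enumerate(profiles)}

    codec = FeatureCodec().fit(imputed.panels[0].data)
    ledger_rows: list[dict] = []
    predictions: list[pd.DataFrame] = []

    for k, panel in enumerate(imputed.panels):
        df = add_outcome(panel.data)
        for t in target_hours:
            if dry_run:
                for prof in profiles:
                    ledger_rows.append(
                        dict(
                            imputation_id=k,
                            hour_index=t,
                            person_id=prof.person_id,
                            status="planned",
                            reason="",
                            n_train=np.nan,
                            max_features=np.nan,
                            split_rule="",
                        )
                    )
                continue
            try:
                window = build_window(df, t, config.lookback)
            except WindowSkipped as exc:
                log.info("hour %d skipped: %s", t, exc)
                for prof in profiles:
                    ledger_rows.append(
                        dict(
                            imputation_id=k,
                            hour_index=t,
                            person_id=prof.person_id,
                            status="skipped",
                            reason=str(exc),
                            n_train=0,
                            max_features=np.nan,
                            split_rule="",
                        )
                    )
                continue

            nomo_seed = child_seed(config.seed, _S_NOMOTHETIC, k, t)
            nomothetic = fit_nomothetic(window, codec, config.nomothetic, nomo_seed)
            Xtr = codec.transform(window.training)
            yhat_tr = nomothetic.predict(window.training)
            Xstack = augment_features(Xtr, yhat_tr)
            ytr = window.training["mood"].to_numpy(dtype=float)
            train_pids = window.training["person_id"].to_numpy()

            observed_at_t = set(
                window.prediction.loc[window.prediction["mood"].notna(), "person_id"]
            )
            models = {}
            for prof in profiles:
                pid = prof.person_id
                if fit_only_observed and pid not in observed_at_t:
                    ledger_rows.append(
                        dict(
                            imputation_id=k,
                            hour_index=t,
                            person_id=pid,
                            status="skipped",
                            reason="no_observed_outcome_at_t",
                            n_train=len(ytr),
                            max_features=np.nan,
                            split_rule="",
                        )
                    )
                    continue
                seed = child_seed(config.seed, _S_IDIOGRAPHIC, k, t, person_index[pid])
                try:
                    model = fit_idiographic(
                        Xstack,
                        ytr,
                        train_pids,
                        pid,
                        config.weights,
                        config.idiographic,
                        seed,
                    )
                except WindowSkipped as exc:
                    ledger_rows.append(
                        dict(
                            imputation_id=k,
                            hour_index=t,
                            person_id=pid,
                            status="skipped",
                            reason=str(exc),
                            n_train=len(ytr),
                            max_features=np.nan,
                            split_rule="",
                        )
                    )
                    continue
                models[pid] = model
                log.debug("fit imp=%d hour=%d person=%s", k, t, pid)
                ledger_rows.append(
                    dict(
                        imputation_id=k,
                        hour_index=t,
                        person_id=pid,
                        status="fit",
                        reason="",
                        n_train=len(ytr),
                        max_features=model.max_features,
                        split_rule=model.split_rule,
                    )
                )
            if models:
                predictions.append(predict_hour(models, nomothetic, window, k))

    ledger = pd.DataFrame(ledger_rows, columns=LEDGER_COLS)
    preds = (
        pd.concat(predictions, ignore_index=True)
        if predictions
        else pd.DataFrame(columns=PREDICTION_COLS)
    )
    return preds, ledger
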