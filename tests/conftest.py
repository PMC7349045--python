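import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import moodcast as mc

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def tiny_config() -> mc.CohortConfig:
    """4 persons x 3 days — enough structure for unit tests, cheap to build."""
    return mc.CohortConfig(n_persons=4, n_days=3, seed=101)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    panel, truth = mc.generate_cohort(tiny_config)
    return panel, truth


@pytest.fixture(scope="session")
def tiny_imputed(tiny_cohort):
    panel, _ = tiny_cohort
    return mc.impute(panel, m=2, seed=101)


@pytest.fixture(scope="session")
def signal_run():
    """One shared clean-signal end-to-end run: strong couplings, low noise.

    Several tests interrogate different aspects of the same run (recovery,
    sensitivity, reporting), so it is computed once per session.
    """
    cfg = mc.RunConfig()
    cfg.cohort = mc.CohortConfig(
        n_persons=15,
        n_days=8,
        seed=11,
        coupling_scale=2.0,
        noise_sd=2.0,
        item_noise_sd=3.0,
    )
    cfg.seed = 11
    cfg.m_imputations = 2
    cfg.idiographic.grid_search = False
    cfg.idiographic.forest_size = 100
    panel, truth = mc.generate_cohort(cfg.cohort)
    imputed = mc.impute(panel, m=cfg.m_imputations, seed=cfg.seed)
    target_hours = list(range(24, cfg.cohort.n_hours, 4))
    preds, ledger = mc.run_pipeline(imputed, cfg, target_hours=target_hours)
    pooled = mc.pool_imputations(preds)
    return dict(
        config=cfg,
        panel=panel,
        truth=truth,
        predictions=preds,
        ledger=ledger,
        pooled=pooled,
    )


def make_linear_window_df(n_per_person=30, persons=("pA", "pB"), slope=3.0, seed=0):
    """A constructed panel slice whose mood is an exact linear function of one
    sensor — an oracle fixture for the model stages."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in persons:
        for h in range(n_per_person):
            hr = rng.uniform(60, 100)
            rows.append(
                dict(
                    person_id=pid,
                    hour_index=h,
                    awake=1,
                    sad=np.nan,
                    lonely=np.nan,
                    latitude=40.0,
                    longitude=-77.0,
                    location_accuracy=10.0,
                    location_speed=0.5,
                    temperature=15.0,
                    humidity=50.0,
                    precipitation=0.0,
                    light_level=100.0,
                    hr_mean=hr,
                    hrv_rmssd=40.0,
                    outgoing_calls=0.0,
                    location_source="gps",
                    location_type="home",
                    mood=slope * hr,
                )
            )
    return pd.DataFrame(rows)
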