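"""Synthetic EMA + passive-sensing cohort generator.

Emulates a one-site smartphone study: ~31 undergraduates enrolled for ~8
days, prompted to rate momentary sadness and loneliness (0-100) once per
wake hour, while the phone indexes sensors hourly on the hour (location,
weather, light, photoplethysmographic heart metrics, outgoing calls).

The generative model, chosen for face validity and full configurability:

* latent depressed mood per person-hour = person intercept (anchored to the
  baseline DASS depression score) + AR(1) innovation chain + a 24-h
  sinusoid;
* sad and lonely are two noisy readouts of the same latent state (item
  noise sized so their correlation is ≈ 0.66 at default settings);
* each coupled sensor moves with the person's standardized latent state
  through a person-specific coupling coefficient (worse mood: higher mean
  HR, lower RMSSD, fewer outgoing calls, less light, lower speed);
* weather is cohort-shared (single site); location is a small set of
  per-person anchor points (home, university, gym, ...) with GPS jitter;
* mood prompts exist only during wake hours of the prompting days and are
  answered with probability ``compliance_rate``; sensors get independent
  small missingness to exercise imputation.

Ground truth (latent trajectories, coupling vectors) is retained so
downstream stages can be tested for signal recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, child_rng
from .exceptions import ConfigError
from .panel import (
    MOOD_COLS,
    PANEL_COLS,
    SENSOR_CATEGORICAL,
    SENSOR_NUMERIC,
    Panel,
    PersonProfile,
)

#: sensor-units of shift per 1 SD of (worsening) latent mood, before the
#: global coupling_scale and per-person heterogeneity are applied
BASE_COUPLINGS = {
    "hr_mean": 4.0,  # beats/min
    "hrv_rmssd": -6.0,  # ms
    "outgoing_calls": -0.5,  # log-rate units (Poisson)
    "light_level": -120.0,  # lux
    "location_speed": -0.15,  # m/s
}

DASS_N_ITEMS = 14
DASS_ITEM_MAX = 3

#: fixed cohort reference scale for the latent state when applying sensor
#: couplings: z = (latent - 32) / 12.  Normalizing by a cohort constant (not
#: within person) keeps habitual mood level visible in the sensors, so both
#: intra- and inter-individual variability are recoverable downstream.
LATENT_REF_MEAN = 32.0
LATENT_REF_SD = 12.0

LOCATION_ANCHORS = ["home", "university", "gym", "restaurant", "other"]
#: where an awake person is in a given hour (rough campus-life mix)
ANCHOR_PROBS = [0.30, 0.45, 0.08, 0.10, 0.07]
CAMPUS_LAT, CAMPUS_LON = 40.80, -77.86

# internal RNG stream tags (keep distinct across modules)
_S_PROFILES, _S_WEATHER, _S_LATENT, _S_SENSORS, _S_MISSING = 1, 2, 3, 4, 5


@dataclass
class GroundTruth:
    """What the generator knows and the models must recover."""

    latent: dict[str, np.ndarray]  # person_id -> hourly latent mood
    couplings: dict[str, dict[str, float]]  # person_id -> coupling vector


# ---------------------------------------------------------------------------
# Baseline questionnaire
# ---------------------------------------------------------------------------

def generate_dass_items(rng: np.random.Generator) -> np.ndarray:
    """Draw 14 depression-subscale item responses, each rated 0-3.

    Item severity is driven by a person-level propensity so that total
    scores span the full attainable range [0, 42]; the default propensity
    is skewed toward the severe end, matching a clinically elevated sample.
    """
    propensity = rng.beta(3.0, 1.8)
    return rng.binomial(DASS_ITEM_MAX, propensity, size=DASS_N_ITEMS)


def dass_depression_score(items: np.ndarray) -> int:
    """Sum of the 14 item responses; attainable range is exactly [0, 42]."""
    items = np.asarray(items)
    if items.shape != (DASS_N_ITEMS,):
        raise ConfigError(f"expected {DASS_N_ITEMS} item responses")
    if items.min() < 0 or items.max() > DASS_ITEM_MAX:
        raise ConfigError(f"item responses must lie in [0, {DASS_ITEM_MAX}]")
    return int(items.sum())


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def generate_profiles(config: CohortConfig) -> list[PersonProfile]:
    """Draw the cohort roster: ids, race, baseline severity, wake schedule,
    and ground-truth sensor-mood coupling vectors."""
    config.validate()
    rng = child_rng(config.seed, _S_PROFILES)
    races = list(config.race_distribution.keys())
    probs = np.array(list(config.race_distribution.values()), dtype=float)
    probs = probs / probs.sum()
    n_flip = int(round(config.flip_fraction * config.n_persons))
    flipped = set(range(n_flip))  # first persons get flipped couplings

    profiles = []
    for i in range(config.n_persons):
        race = races[int(rng.choice(len(races), p=probs))]
        score = dass_depression_score(generate_dass_items(rng))
        wake = int(rng.integers(7, 10))
        sign = -1.0 if i in flipped else 1.0
        coupling = {
            k: sign
            * config.coupling_scale
            * base
            * (1.0 + config.coupling_heterogeneity * rng.standard_normal())
            for k, base in BASE_COUPLINGS.items()
        }
        profiles.append(
            PersonProfile(
                person_id=f"p{i:03d}",
                race_group=race,
                baseline_dass_d=score,
                wake_hour=wake,
                bed_hour=(wake + config.wake_hours_per_day) % 24,
                coupling_vector=coupling,
            )
        )
    return profiles


def _awake_mask(profile: PersonProfile, config: CohortConfig, hours: np.ndarray) -> np.ndarray:
    hod = hours % 24
    return ((hod - profile.wake_hour) % 24) < config.wake_hours_per_day


# ---------------------------------------------------------------------------
# Latent mood
# ---------------------------------------------------------------------------

def person_intercept(
    profile: PersonProfile, config: CohortConfig, rng: np.random.Generator
) -> float:
    """Habitual mood level in 0-100 units, anchored to baseline severity."""
    return (
        config.intercept_mean
        + config.intercept_dass_slope * (profile.baseline_dass_d - 20.0)
        + config.intercept_sd * rng.standard_normal()
    )


def simulate_latent_mood(
    profile: PersonProfile,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hourly latent depressed mood over the enrollment.

    process: intercept + AR(1) chain (stationary start) + diurnal sinusoid
    of period 24 h and the configured amplitude (worst in the small hours).
    """
    config.validate()
    if rng is None:
        idx = int(profile.person_id.lstrip("p"))
        rng = child_rng(config.seed, _S_LATENT, idx)
    n = config.n_hours
    phi, sd = config.ar_coefficient, config.noise_sd
    icpt = person_intercept(profile, config, rng)
    x = np.zeros(n)
    if sd > 0:
        x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
        innov = rng.normal(0.0, sd, size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t]
    hours = np.arange(n)
    diurnal = config.diurnal_amplitude * np.sin(2 * np.pi * hours / 24.0)
    return icpt + x + diurnal


def default_item_noise_sd(config: CohortConfig) -> float:
    """Item-noise SD targeting a sad-lonely correlation ≈ 0.66.

    With sad = L + e1, lonely = L + e2, corr = var(L)/(var(L)+var(e)); the
    pooled latent variance combines the between-person intercept spread,
    the AR(1) marginal variance and the diurnal term.
    """
    if config.item_noise_sd is not None:
        return config.item_noise_sd
    # DASS-driven spread (score SD ~ 9 under the default item model) plus
    # the idiosyncratic intercept component
    var_between = (config.intercept_dass_slope * 9.0) ** 2 + config.intercept_sd**2
    var_ar = config.noise_sd**2 / (1.0 - config.ar_coefficient**2)
    var_diurnal = config.diurnal_amplitude**2 / 2.0
    var_latent = var_between + var_ar + var_diurnal
    return float(np.sqrt(var_latent * (1.0 / 0.66 - 1.0)))


def observed_mood(
    latent: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sad and lonely readouts: latent + independent item noise, optional
    zero-inflation, clipped to the 0-100 response scale."""
    sd = default_item_noise_sd(config)
    sad = np.clip(latent + rng.normal(0.0, sd, size=latent.size), 0.0, 100.0)
    lonely = np.clip(latent + rng.normal(0.0, sd, size=latent.size), 0.0, 100.0)
    if config.zero_inflation > 0:
        zmask = rng.random(latent.size) < config.zero_inflation
        sad[zmask] = 0.0
        lonely[zmask] = 0.0
    return sad, lonely


# ---------------------------------------------------------------------------
# Sensors
# ---------------------------------------------------------------------------

def simulate_weather(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Cohort-shared hourly weather (single site): diurnal temperature cycle
    with AR noise, anti-correlated humidity, bursty precipitation."""
    if rng is None:
        rng = child_rng(config.seed, _S_WEATHER)
    n = config.n_hours
    hod = np.arange(n) % 24
    temp = 16.0 + 5.0 * np.sin(2 * np.pi * (hod - 9) / 24.0)
    ar = np.zeros(n)
    for t in range(1, n):
        ar[t] = 0.9 * ar[t - 1] + rng.normal(0.0, 0.8)
    temp = temp + ar
    humidity = np.clip(65.0 - 1.5 * (temp - 16.0) + rng.normal(0, 5, n), 5.0, 100.0)
    raining = np.zeros(n, dtype=bool)
    for t in range(1, n):
        p = 0.3 if raining[t - 1] else 0.04
        raining[t] = rng.random() < p
    precip = np.where(raining, rng.exponential(1.2, n), 0.0)
    return pd.DataFrame(
        {"temperature": temp, "humidity": humidity, "precipitation": precip}
    )


def simulate_sensors(
    latent: np.ndarray,
    profile: PersonProfile,
    config: CohortConfig,
    weather: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One person's hourly sensor stream, coupled to the latent state.

    Couplings act on the latent state standardized by a fixed cohort
    reference scale, so both a person's habitual level and their hour-to-
    hour fluctuation move the sensors (chronically worse mood shows up as,
    e.g., chronically higher HR).  Physically implausible values are
    clamped (HR 35-190 bpm, RMSSD 3-250 ms, non-negative
    light/speed/calls, humidity 0-100).
    """
    if rng is None:
        idx = int(profile.person_id.lstrip("p"))
        rng = child_rng(config.seed, _S_SENSORS, idx)
    n = latent.size
    z = (latent - LATENT_REF_MEAN) / LATENT_REF_SD
    cv = profile.coupling_vector
    hod = np.arange(n) % 24
    awake = _awake_mask(profile, config, np.arange(n))

    # location: per-person anchor coordinates around one campus
    anchor_coords = {
        a: (
            CAMPUS_LAT + rng.normal(0, 0.01),
            CAMPUS_LON + rng.normal(0, 0.01),
        )
        for a in LOCATION_ANCHORS
    }
    anchors = np.where(
        awake,
        rng.choice(LOCATION_ANCHORS, size=n, p=ANCHOR_PROBS),
        "home",
    )
    lat = np.array([anchor_coords[a][0] for a in anchors]) + rng.normal(0, 1e-4, n)
    lon = np.array([anchor_coords[a][1] for a in anchors]) + rng.normal(0, 1e-4, n)
    source = np.where(rng.random(n) < 0.75, "gps", "wifi")
    accuracy = np.where(
        source == "gps", rng.lognormal(np.log(12.0), 0.4, n), rng.lognormal(np.log(35.0), 0.4, n)
    )
    speed = np.clip(
        np.where(awake, 0.6, 0.05)
        + cv.get("location_speed", 0.0) * z
        + rng.normal(0, 0.25, n),
        0.0,
        None,
    )

    daylight = np.clip(np.sin(2 * np.pi * (hod - 6) / 24.0), 0.0, None)
    light = np.clip(
        60.0 + 500.0 * daylight * awake
        + cv.get("light_level", 0.0) * z
        + rng.normal(0, 60.0, n),
        0.0,
        None,
    )

    hr = np.clip(
        72.0 + 2.5 * np.sin(2 * np.pi * (hod - 16) / 24.0)
        + cv.get("hr_mean", 0.0) * z
        + rng.normal(0, 3.0, n),
        35.0,
        190.0,
    )
    hrv = np.clip(
        45.0 + cv.get("hrv_rmssd", 0.0) * z + rng.normal(0, 6.0, n), 3.0, 250.0
    )
    log_rate = np.log(0.35) + cv.get("outgoing_calls", 0.0) * z
    calls = rng.poisson(np.exp(np.clip(log_rate, -10.0, 3.0)) * np.where(awake, 1.0, 0.1))

    return pd.DataFrame(
        {
            "latitude": lat,
            "longitude": lon,
            "location_accuracy": accuracy,
            "location_speed": speed,
            "location_source": source,
            "location_type": anchors,
            "temperature": weather["temperature"].to_numpy(),
            "humidity": weather["humidity"].to_numpy(),
            "precipitation": weather["precipitation"].to_numpy(),
            "light_level": light,
            "hr_mean": hr,
            "hrv_rmssd": hrv,
            "outgoing_calls": calls.astype(float),
        }
    )


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def apply_missingness(
    panel: Panel, config: CohortConfig, profiles: list[PersonProfile] | None = None
) -> Panel:
    """Impose the study's observation process on a complete panel.

    Mood prompts exist only during wake hours of the first
    ``effective_prompt_days`` days and are answered with probability
    ``compliance_rate`` (the whole prompt is answered or skipped as a
    unit).  Every sensor field additionally gets independent MCAR
    missingness at ``sensor_missing_rate``.  Expected completed prompts per
    person = wake_hours_per_day x prompt_days x compliance_rate.
    """
    if profiles is None:
        profiles = panel.profiles
    out = panel.copy()
    df = out.data
    prompt_hours = config.effective_prompt_days * 24
    for i, prof in enumerate(profiles):
        rng = child_rng(config.seed, _S_MISSING, i)
        mask_rows = df["person_id"] == prof.person_id
        hours = df.loc[mask_rows, "hour_index"].to_numpy()
        awake = _awake_mask(prof, config, hours)
        answered = rng.random(hours.size) < config.compliance_rate
        prompt_ok = awake & (hours < prompt_hours) & answered
        for c in MOOD_COLS:
            vals = df.loc[mask_rows, c].to_numpy(dtype=float)
            vals[~prompt_ok] = np.nan
            df.loc[mask_rows, c] = vals
        if config.sensor_missing_rate > 0:
            for c in SENSOR_NUMERIC:
                drop = rng.random(hours.size) < config.sensor_missing_rate
                vals = df.loc[mask_rows, c].to_numpy(dtype=float)
                vals[drop] = np.nan
                df.loc[mask_rows, c] = vals
            drop = rng.random(hours.size) < config.sensor_missing_rate
            for c in SENSOR_CATEGORICAL:
                vals = df.loc[mask_rows, c].to_numpy(dtype=object)
                vals[drop] = np.nan
                df.loc[mask_rows, c] = vals
        df.loc[mask_rows, "awake"] = awake.astype(int)
    return out


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def generate_complete_panel(
    config: CohortConfig, profiles: list[PersonProfile] | None = None
) -> tuple[Panel, GroundTruth]:
    """Fully observed panel (before the observation process is applied)."""
    config.validate()
    if profiles is None:
        profiles = generate_profiles(config)
    weather = simulate_weather(config)
    frames, latents, couplings = [], {}, {}
    for i, prof in enumerate(profiles):
        rng_lat = child_rng(config.seed, _S_LATENT, i)
        rng_sen = child_rng(config.seed, _S_SENSORS, i)
        latent = simulate_latent_mood(prof, config, rng_lat)
        sad, lonely = observed_mood(latent, config, rng_lat)
        sensors = simulate_sensors(latent, prof, config, weather, rng_sen)
        hours = np.arange(config.n_hours)
        frame = pd.DataFrame(
            {
                "person_id": prof.person_id,
                "hour_index": hours,
                "awake": _awake_mask(prof, config, hours).astype(int),
                "sad": sad,
                "lonely": lonely,
            }
        )
        frame = pd.concat([frame, sensors], axis=1)
        frames.append(frame)
        latents[prof.person_id] = latent
        couplings[prof.person_id] = dict(prof.coupling_vector)
    data = pd.concat(frames, ignore_index=True)[PANEL_COLS]
    panel = Panel(data, profiles)
    panel.validate()
    return panel, GroundTruth(latent=latents, couplings=couplings)


def generate_cohort(config: CohortConfig) -> tuple[Panel, GroundTruth]:
    """Observable panel (wake-hour prompts, imperfect compliance, sensor
    dropout) plus the retained ground truth."""
    complete, truth = generate_complete_panel(config)
    panel = apply_missingness(complete, config)
    return panel, truth
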