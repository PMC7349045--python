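"""Person-hour panel data model, hourly alignment, outcome construction and I/O.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
with one row per (person, hour) — the :class:`Panel` wraps it together with
the person profiles.  Hours are 0-based integers since cohort start; all
records are stamped on the hour.

Column dictionary (``write_panel`` emits exactly these):

==================  =======================================================
person_id           opaque person identifier (string)
hour_index          integer hours since cohort start, 0-based
awake               1 if the hour falls in the person's self-reported wake
                    window, else 0
sad, lonely         momentary mood items, 0-100 (missing when unprompted or
                    prompt not answered)
latitude/longitude  degrees
location_accuracy   meters
location_speed      m/s
location_source     ``gps`` or ``wifi``
location_type       anchor category (home, university, gym, ...)
temperature         degrees C (cohort-shared weather)
humidity            percent, [0, 100]
precipitation       mm
light_level         lux
hr_mean             beats/min
hrv_rmssd           ms
outgoing_calls      calls in the hour (non-negative integer)
==================  =======================================================
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, InsufficientDataError

KEY_COLS = ["person_id", "hour_index"]
MOOD_COLS = ["sad", "lonely"]
SENSOR_NUMERIC = [
    "latitude",
    "longitude",
    "location_accuracy",
    "location_speed",
    "temperature",
    "humidity",
    "precipitation",
    "light_level",
    "hr_mean",
    "hrv_rmssd",
    "outgoing_calls",
]
SENSOR_CATEGORICAL = ["location_source", "location_type"]
SENSOR_COLS = SENSOR_NUMERIC + SENSOR_CATEGORICAL
PANEL_COLS = KEY_COLS + ["awake"] + MOOD_COLS + SENSOR_COLS

LOCATION_SOURCES = ["gps", "wifi"]


@dataclass
class PersonProfile:
    """Static person attributes plus retained simulation ground truth."""

    person_id: str
    race_group: str
    baseline_dass_d: int
    wake_hour: int
    bed_hour: int
    #: per-sensor effect of the latent mood state on that sensor
    #: (ground truth, retained for recovery tests; empty for real data)
    coupling_vector: dict[str, float] = field(default_factory=dict)


@dataclass
class Panel:
    """A cohort's aligned hourly grid plus its person profiles."""

    data: pd.DataFrame
    profiles: list[PersonProfile]

    @property
    def person_ids(self) -> list[str]:
        return [p.person_id for p in self.profiles]

    @property
    def n_hours(self) -> int:
        return int(self.data["hour_index"].max()) + 1 if len(self.data) else 0

    def validate(self) -> None:
        dup = self.data.duplicated(subset=KEY_COLS)
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise DataError(
                f"duplicate record for person {row['person_id']!r} "
                f"hour {int(row['hour_index'])}"
            )
        known = set(self.person_ids)
        unknown = set(self.data["person_id"]) - known
        if unknown:
            raise DataError(f"records reference unknown persons: {sorted(unknown)}")
        if (self.data["hour_index"] < 0).any():
            raise DataError("hour_index must be >= 0")

    def copy(self) -> "Panel":
        return Panel(self.data.copy(), list(self.profiles))


@dataclass
class ImputedPanelSet:
    """m completed copies of one panel; observed cells identical across copies."""

    panels: list[Panel]
    m: int
    imputation_seed: int


# ---------------------------------------------------------------------------
# Outcome construction
# ---------------------------------------------------------------------------

def compute_outcome(sad, lonely):
    """Depressed-mood composite: arithmetic mean of the available items.

    Sad and lonely are treated as exchangeable readouts of depressed affect;
    with both present the composite is their mean, with one present it is
    that item, with neither it is missing.  Works elementwise on arrays.
    """
    sad = np.asarray(sad, dtype=float)
    lonely = np.asarray(lonely, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(np.stack([sad, lonely]), axis=0)
    return float(out) if out.ndim == 0 else out


def add_outcome(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of `df` with a `mood` column (the composite outcome)."""
    out = df.copy()
    out["mood"] = compute_outcome(df["sad"].to_numpy(), df["lonely"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Heart-rate utilities
# ---------------------------------------------------------------------------

def rmssd(ibis: Sequence[float]) -> float:
    """Root mean square of successive differences of inter-beat intervals (ms).

    Translation-invariant (a constant shift of all intervals cancels in the
    differences) and linear under rescaling of the intervals.
    """
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size < 2:
        raise InsufficientDataError("rmssd needs at least 2 inter-beat intervals")
    d = np.diff(ibis)
    return float(np.sqrt(np.mean(d**2)))


def mean_heart_rate(ibis: Sequence[float]) -> float:
    """Average heart rate (beats/min) from inter-beat intervals in ms."""
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size < 1 or np.any(ibis <= 0):
        raise InsufficientDataError("mean_heart_rate needs positive intervals")
    return float(60000.0 / np.mean(ibis))


# ---------------------------------------------------------------------------
# Hourly alignment of raw event streams
# ---------------------------------------------------------------------------

def align_hourly(events: pd.DataFrame, n_hours: int | None = None) -> pd.DataFrame:
    """Collapse a raw timestamped event stream onto the hourly grid.

    `events` columns: ``person_id``, ``time_hours`` (fractional hours since
    cohort start), ``stream`` (``call``, ``sad``, ``lonely``, or a sensor
    name), ``value`` (ignored for calls).

    Per person-hour: call events are summed; sensor samples are reduced to
    the on-the-hour reading (the latest sample at-or-before the hour mark,
    looking back at most one hour); mood ratings attach to the hour of their
    prompt.  Hours with no call events get ``outgoing_calls = 0``; sensors
    with no sample stay missing.
    """
    req = {"person_id", "time_hours", "stream"}
    if not req.issubset(events.columns):
        raise DataError(f"event stream must have columns {sorted(req)}")
    events = events.copy()
    if n_hours is None:
        n_hours = int(np.floor(events["time_hours"].max())) + 1

    persons = sorted(events["person_id"].unique())
    grid = pd.DataFrame(
        [(p, h) for p in persons for h in range(n_hours)], columns=KEY_COLS
    )
    for c in MOOD_COLS + SENSOR_NUMERIC:
        grid[c] = np.nan
    for c in SENSOR_CATEGORICAL:
        grid[c] = pd.Series([np.nan] * len(grid), dtype=object)
    grid["outgoing_calls"] = 0.0
    grid = grid.set_index(KEY_COLS)

    calls = events[events["stream"] == "call"]
    if len(calls):
        counts = (
            calls.assign(hour_index=np.floor(calls["time_hours"]).astype(int))
            .groupby(["person_id", "hour_index"])
            .size()
        )
        for (p, h), n in counts.items():
            if h < n_hours:
                grid.loc[(p, h), "outgoing_calls"] = float(n)

    mood = events[events["stream"].isin(MOOD_COLS)]
    for _, row in mood.iterrows():
        h = int(np.floor(row["time_hours"]))
        if h < n_hours:
            grid.loc[(row["person_id"], h), row["stream"]] = row["value"]

    sensor_names = [c for c in SENSOR_COLS if c != "outgoing_calls"]
    sensors = events[events["stream"].isin(sensor_names)]
    for (p, s), grp in sensors.groupby(["person_id", "stream"]):
        grp = grp.sort_values("time_hours", kind="stable")
        for h in range(n_hours):
            win = grp[(grp["time_hours"] > h - 1) & (grp["time_hours"] <= h)]
            if not len(win):
                continue
            tmax = win["time_hours"].max()
            at_mark = win[win["time_hours"] == tmax]
            vals = at_mark["value"].unique()
            if len(vals) > 1:
                raise DataError(
                    f"conflicting on-the-hour samples for sensor {s!r}, "
                    f"person {p!r}, hour {h}"
                )
            grid.loc[(p, h), s] = vals[0]

    out = grid.reset_index()
    out["awake"] = 1
    return out[PANEL_COLS]


# ---------------------------------------------------------------------------
# I/O — long-format delimited text, one person-hour per row
# ---------------------------------------------------------------------------

def write_panel(panel: Panel, path: str | Path, profiles_path: str | Path | None = None) -> None:
    """Write the panel records as CSV and the profiles as a sibling CSV.

    Missing cells are written as empty fields; the round trip through
    :func:`read_panel` is lossless, including missingness.
    """
    path = Path(path)
    df = panel.data.loc[:, PANEL_COLS].copy()
    df.to_csv(path, index=False)
    if profiles_path is None:
        profiles_path = path.with_name(path.stem + "_profiles.csv")
    prof = pd.DataFrame(
        {
            "person_id": [p.person_id for p in panel.profiles],
            "race_group": [p.race_group for p in panel.profiles],
            "baseline_dass_d": [p.baseline_dass_d for p in panel.profiles],
            "wake_hour": [p.wake_hour for p in panel.profiles],
            "bed_hour": [p.bed_hour for p in panel.profiles],
            "coupling_vector": [json.dumps(p.coupling_vector) for p in panel.profiles],
        }
    )
    prof.to_csv(profiles_path, index=False)


def read_panel(path: str | Path, profiles_path: str | Path | None = None) -> Panel:
    """Read a panel written by :func:`write_panel` (or any conforming CSV).

    Unknown columns raise a warning and are dropped; a file lacking
    ``person_id``/``hour_index`` is a format error.  If no profiles file is
    found, minimal profiles are synthesized from the person ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"person_id": str})
    missing = [c for c in KEY_COLS if c not in df.columns]
    if missing:
        raise DataError(f"panel file {path} lacks mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in PANEL_COLS]
    if unknown:
        warnings.warn(f"ignoring unknown panel columns {unknown}")
        df = df.drop(columns=unknown)
    for c in PANEL_COLS:
        if c not in df.columns:
            df[c] = np.nan
    if df["awake"].isna().all():
        df["awake"] = 1
    df["hour_index"] = df["hour_index"].astype(int)
    for c in MOOD_COLS + SENSOR_NUMERIC:
        df[c] = pd.to_numeric(df[c])
    df = df[PANEL_COLS]

    if profiles_path is None:
        cand = path.with_name(path.stem + "_profiles.csv")
        profiles_path = cand if cand.exists() else None
    if profiles_path is not None:
        prof = pd.read_csv(profiles_path, dtype={"person_id": str})
        profiles = [
            PersonProfile(
                person_id=r["person_id"],
                race_group=r["race_group"],
                baseline_dass_d=int(r["baseline_dass_d"]),
                wake_hour=int(r["wake_hour"]),
                bed_hour=int(r["bed_hour"]),
                coupling_vector=json.loads(r["coupling_vector"])
                if isinstance(r.get("coupling_vector"), str)
                else {},
            )
            for _, r in prof.iterrows()
        ]
    else:
        profiles = [
            PersonProfile(pid, race_group="unknown", baseline_dass_d=0, wake_hour=8, bed_hour=24)
            for pid in sorted(df["person_id"].unique())
        ]
    panel = Panel(df.reset_index(drop=True), profiles)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# Fixed-dictionary categorical encoding for modeling
# ---------------------------------------------------------------------------

class FeatureCodec:
    """Freezes the categorical dictionaries at pipeline start so the model
    design matrix has constant dimensionality p across every window."""

    def __init__(self) -> None:
        self.categories: dict[str, list[str]] = {}
        self.feature_names: list[str] = []

    def fit(self, df: pd.DataFrame) -> "FeatureCodec":
        for c in SENSOR_CATEGORICAL:
            cats = sorted(x for x in df[c].dropna().unique())
            self.categories[c] = cats
        self.feature_names = list(SENSOR_NUMERIC) + [
            f"{c}={lvl}" for c in SENSOR_CATEGORICAL for lvl in self.categories[c]
        ]
        return self

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Encode sensor columns into the fixed p-column design matrix."""
        if not self.feature_names:
            raise DataError("FeatureCodec used before fit()")
        blocks = [df[SENSOR_NUMERIC].to_numpy(dtype=float)]
        for c in SENSOR_CATEGORICAL:
            cats = self.categories[c]
            col = df[c].to_numpy(dtype=object)
            onehot = np.zeros((len(df), len(cats)))
            for j, lvl in enumerate(cats):
                onehot[:, j] = col == lvl
            blocks.append(onehot)
        return np.hstack(blocks)
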