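"""Assemble the 24-dimensional feature vector x = (x_ant, x_chr, x_met, x_resp).

Feature groups
--------------
x_ant   age, gender (female=0, male=1), bmi = weight_kg / height_m**2.
x_chr   quartiles of the cadence-to-heart-rate ratio c_i/hr_i over activity
        minutes (cadence above 60 steps/min); steps per beat.
x_met   quartiles over observed days of the daily MET-minutes ratio, where a
        minute's MET is estimated from heart rate as 6*hr/hr_rest - 5 and a
        day's MET-minutes are divided by 1440 (a fully resting day).
x_resp  the 15 piecewise-linear quantile-regression coefficients
        (w0, w1, w2) at q in {0.1, 0.2, 0.5, 0.8, 0.9} of heart rate on
        cadence over active minutes (hr above 75 bpm, cadence over 60).

Quartiles use linear interpolation between closest ranks (numpy's default,
"type 7") everywhere.  Components that cannot be computed (e.g. a user with
no activity minutes) are encoded as NaN sentinels and handled natively by
the downstream tree model rather than dropping the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocessing, pwlqr

MINUTES_PER_DAY = 1440
MET_FLOOR = 1.0
CHR_CADENCE_THRESHOLD = 60.0
#: fitted response coefficients are unreliable below this many active minutes
LOW_DATA_MINUTES = 30

RESPONSE_NAMES = [
    f"w{i}_{int(q * 100)}" for q in pwlqr.RESPONSE_LEVELS for i in (0, 1, 2)
]
FEATURE_NAMES = (
    ["age", "gender", "bmi"]
    + ["chr25", "chr50", "chr75"]
    + ["met25", "met50", "met75"]
    + RESPONSE_NAMES
)
GROUPS = {
    "ant": ["age", "gender", "bmi"],
    "chr": ["chr25", "chr50", "chr75"],
    "met": ["met25", "met50", "met75"],
    "resp": RESPONSE_NAMES,
}


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m^2."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m**2


@dataclass(frozen=True)
class AnthroFeature:
    age: float
    gender: float  # female = 0, male = 1
    bmi: float

    def values(self) -> np.ndarray:
        return np.array([self.age, self.gender, self.bmi], dtype=float)


def _quartiles(values: np.ndarray) -> np.ndarray:
    return np.percentile(values, [25.0, 50.0, 75.0])


def chr_feature(hr, cadence) -> np.ndarray:
    """Quartiles of cadence/heart-rate over activity minutes (c > 60).

    Returns a length-3 NaN vector (missing-feature sentinel) when the user
    has no activity minutes.
    """
    hr = np.asarray(hr, dtype=float)
    cadence = np.asarray(cadence, dtype=float)
    active = cadence > CHR_CADENCE_THRESHOLD
    if not active.any():
        return np.full(3, np.nan)
    return _quartiles(cadence[active] / hr[active])


def met_minute(hr, hr_rest):
    """Heart-rate-based MET estimate ``6*hr/hr_rest - 5``, floored at 1.

    Values below one (heart rate below resting) are clipped to the resting
    MET of one.
    """
    hr_rest = np.asarray(hr_rest, dtype=float)
    if (hr_rest <= 0).any() if hr_rest.ndim else hr_rest <= 0:
        raise ValueError("resting heart rate must be positive")
    raw = 6.0 * np.asarray(hr, dtype=float) / hr_rest - 5.0
    out = np.maximum(raw, MET_FLOOR)
    return float(out) if np.ndim(out) == 0 else out


def daily_met(hr, hr_rest: float) -> float:
    """Daily MET-minutes divided by 1440 (the MET-minutes of a resting day).

    ``hr`` holds the covered minutes of one day; uncovered minutes are
    assumed to have a MET of one.
    """
    hr = np.asarray(hr, dtype=float)
    if len(hr) == 0:
        raise preprocessing.EmptySeriesError("day has no covered minutes")
    if len(hr) > MINUTES_PER_DAY:
        raise ValueError("more covered minutes than minutes in a day")
    covered = met_minute(hr, hr_rest).sum()
    return (covered + MET_FLOOR * (MINUTES_PER_DAY - len(hr))) / MINUTES_PER_DAY


def met_feature(daily_values) -> np.ndarray:
    """Quartiles of the per-day ``met`` values; NaN sentinel if no days."""
    daily_values = np.asarray(daily_values, dtype=float)
    if len(daily_values) == 0:
        return np.full(3, np.nan)
    return _quartiles(daily_values)


def response_feature(hr, cadence) -> tuple[np.ndarray, bool]:
    """The 15 response coefficients and a low-data flag.

    Active minutes (hr > 75, cadence > 60) feed five independent quantile
    fits.  With no active minutes the 15 components are NaN sentinels; with
    fewer than ``LOW_DATA_MINUTES`` the fit proceeds but is flagged.
    """
    hr = np.asarray(hr, dtype=float)
    cadence = np.asarray(cadence, dtype=float)
    mask = pwlqr.activity_mask(hr, cadence)
    n = int(mask.sum())
    if n == 0:
        return np.full(15, np.nan), True
    models = pwlqr.fit_response(cadence[mask], hr[mask])
    coefs = np.concatenate([m.coefficients for m in models])
    return coefs, n < LOW_DATA_MINUTES


def assemble(ant: AnthroFeature, chr_vec, met_vec, resp_vec) -> np.ndarray:
    """Concatenate (x_ant, x_chr, x_met, x_resp) into the 24-vector."""
    x = np.concatenate(
        [
            ant.values(),
            np.asarray(chr_vec, dtype=float),
            np.asarray(met_vec, dtype=float),
            np.asarray(resp_vec, dtype=float),
        ]
    )
    if len(x) != len(FEATURE_NAMES):
        raise ValueError(f"feature vector has length {len(x)}, expected 24")
    return x


def daily_met_series(minute, hr) -> np.ndarray:
    """Per-day ``met`` values from a user's minute timestamps and heart rates.

    Vectorised equivalent of computing each day's resting heart rate
    (10th percentile, noon-9pm window with whole-day fallback) and then
    ``daily_met`` per observed day.
    """
    m = np.asarray(minute).astype("datetime64[s]")
    hr = np.asarray(hr, dtype=float)
    order = np.argsort(m, kind="stable")
    m, hr = m[order], hr[order]
    day = m.astype("datetime64[D]")
    tod = ((m - day) / np.timedelta64(60, "s")).astype(np.int64)
    in_window = (tod >= preprocessing.REST_WINDOW[0]) & (tod < preprocessing.REST_WINDOW[1])

    days, day_codes = np.unique(day, return_inverse=True)
    bounds = np.searchsorted(day_codes, np.arange(len(days) + 1))
    daily = np.empty(len(days))
    for k in range(len(days)):
        sl = slice(bounds[k], bounds[k + 1])
        pool = hr[sl][in_window[sl]]
        if len(pool) == 0:
            pool = hr[sl]
        rest = np.percentile(pool, preprocessing.REST_PERCENTILE)
        daily[k] = daily_met(hr[sl], rest)
    return daily


def user_features(minutes: pd.DataFrame, ant: AnthroFeature) -> np.ndarray:
    """Feature vector for one user from their per-minute series.

    ``minutes`` has columns minute, hr, cadence (one user).  An empty series
    yields anthropometrics plus 21 NaN sentinels.
    """
    if len(minutes) == 0:
        return assemble(ant, np.full(3, np.nan), np.full(3, np.nan), np.full(15, np.nan))
    hr = minutes["hr"].to_numpy(dtype=float)
    cadence = minutes["cadence"].to_numpy(dtype=float)
    x_chr = chr_feature(hr, cadence)
    x_met = met_feature(daily_met_series(minutes["minute"].to_numpy(), hr))
    x_resp, _low = response_feature(hr, cadence)
    return assemble(ant, x_chr, x_met, x_resp)


def active_minutes(minutes: pd.DataFrame) -> int:
    """Number of activity minutes (cadence above 60) in a user's history."""
    return int((minutes["cadence"].to_numpy(dtype=float) > CHR_CADENCE_THRESHOLD).sum())


def extract_features(
    minutes_df: pd.DataFrame,
    users_df: pd.DataFrame,
    lookback_days: int | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort.

    Parameters
    ----------
    minutes_df
        Preprocessed per-minute rows: user_id, minute, hr, cadence.
    users_df
        Anthropometrics: user_id, age, gender, height_cm, weight_kg.
        ``gender`` may be 'f'/'m' strings or 0/1 codes.
    lookback_days
        If given, only minutes within this many days of each user's last
        observed minute are used (history-window experiments).

    Returns
    -------
    DataFrame indexed like users_df with user_id, the 24 named feature
    columns, and an ``active_minutes`` bookkeeping column.
    """
    by_user = (
        dict(iter(minutes_df.groupby("user_id", observed=True)))
        if len(minutes_df)
        else {}
    )
    rows = []
    for rec in users_df.itertuples(index=False):
        gender = rec.gender
        if isinstance(gender, str):
            gender = {"f": 0.0, "female": 0.0, "m": 1.0, "male": 1.0}[gender.lower()]
        ant = AnthroFeature(
            age=float(rec.age),
            gender=float(gender),
            bmi=bmi(float(rec.weight_kg), float(rec.height_cm) / 100.0),
        )
        minutes = by_user.get(rec.user_id)
        if minutes is None:
            minutes = pd.DataFrame(columns=["minute", "hr", "cadence"])
        elif lookback_days is not None and len(minutes):
            t = pd.to_datetime(minutes["minute"])
            minutes = minutes[t > t.max() - pd.Timedelta(days=lookback_days)]
        x = user_features(minutes, ant)
        rows.append(
            {"user_id": rec.user_id, "active_minutes": active_minutes(minutes)}
            | dict(zip(FEATURE_NAMES, x))
        )
    out = pd.DataFrame(rows)
    return out[["user_id", *FEATURE_NAMES, "active_minutes"]]
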