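"""Raw wearable streams -> per-minute (t_i, hr_i, c_i) series.

Heart rate arrives as irregular (timestamp, bpm) samples and is averaged over
the minute starting at each minute mark; only minutes containing at least one
sample appear.  Step counts arrive as intervals (start, end, stepcount) and
are converted to a cadence c_i: the number of steps made during the one-minute
window ending at t_i.  An interval spanning several minute windows distributes
its steps proportionally to overlap duration (constant stepping rate).

All timestamps are interpreted as the wearer's local wall-clock time; day
boundaries and the noon-9pm resting window are local-clock concepts.  If
input timestamps carry a UTC offset, the offset is used to recover the local
wall-clock reading and then dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("vo2quant")

BPM_MIN, BPM_MAX = 20.0, 250.0
MINUTE = pd.Timedelta(minutes=1)
#: local-clock resting window: noon (inclusive) to 9 pm (exclusive)
REST_WINDOW = (12 * 60, 21 * 60)
REST_PERCENTILE = 10.0

HR_COLUMNS = ["user_id", "timestamp", "bpm"]
STEP_COLUMNS = ["user_id", "start", "end", "steps"]
MINUTE_COLUMNS = ["user_id", "minute", "hr", "cadence"]


class EmptySeriesError(ValueError):
    """Raised when an operation receives no usable samples."""


def _to_local_naive(ts: pd.Series) -> pd.Series:
    """Parse timestamps, keeping wall-clock time and dropping any UTC offset."""
    parsed = pd.to_datetime(ts, format="ISO8601")
    if getattr(parsed.dt, "tz", None) is not None:
        parsed = parsed.dt.tz_localize(None)
    return parsed


def resample_hr(samples: pd.DataFrame) -> pd.DataFrame:
    """Average heart-rate samples over consecutive one-minute intervals.

    Parameters
    ----------
    samples
        Columns ``timestamp`` (datetime-like) and ``bpm``.

    Returns
    -------
    DataFrame with columns ``minute`` (minute-aligned, sorted) and ``hr``;
    one row per minute containing at least one sample.
    """
    if len(samples) == 0:
        raise EmptySeriesError("no heart-rate samples")
    bpm = np.asarray(samples["bpm"], dtype=float)
    if not np.isfinite(bpm).all():
        raise ValueError("non-finite bpm values in heart-rate stream")
    if ((bpm <= BPM_MIN) | (bpm >= BPM_MAX)).any():
        raise ValueError(f"bpm values outside ({BPM_MIN}, {BPM_MAX})")
    ts = pd.to_datetime(samples["timestamp"])
    minute = ts.dt.floor("min")
    out = (
        pd.DataFrame({"minute": minute.to_numpy(), "hr": bpm})
        .groupby("minute", as_index=False)["hr"]
        .mean()
        .sort_values("minute", ignore_index=True)
    )
    return out


def validate_intervals(intervals: pd.DataFrame) -> None:
    """Reject malformed or overlapping step intervals (per one user)."""
    if len(intervals) == 0:
        return
    start = pd.to_datetime(intervals["start"]).to_numpy()
    end = pd.to_datetime(intervals["end"]).to_numpy()
    steps = np.asarray(intervals["steps"], dtype=float)
    if (end <= start).any():
        raise ValueError("step interval with end <= start")
    if (steps < 0).any() or not np.isfinite(steps).all():
        raise ValueError("negative or non-finite step counts")
    order = np.argsort(start, kind="stable")
    if (start[order][1:] < end[order][:-1]).any():
        raise ValueError("overlapping step intervals for one user")


def prorate_steps(intervals: pd.DataFrame) -> pd.Series:
    """Distribute interval step counts over one-minute windows.

    A minute labelled ``t`` owns the half-open window ``(t - 1min, t]``.  Each
    interval's steps are spread uniformly over its duration, so a window
    receives ``steps * overlap / duration``.  The returned Series is indexed
    by minute label and conserves the total step count.
    """
    validate_intervals(intervals)
    if len(intervals) == 0:
        return pd.Series(dtype=float)
    start = pd.to_datetime(intervals["start"]).to_numpy().astype("datetime64[s]")
    end = pd.to_datetime(intervals["end"]).to_numpy().astype("datetime64[s]")
    steps = np.asarray(intervals["steps"], dtype=float)

    labels: list[np.datetime64] = []
    values: list[float] = []
    one_min = np.timedelta64(60, "s")
    for s, e, n in zip(start, end, steps):
        dur = (e - s) / np.timedelta64(1, "s")
        # windows (t-1min, t] with positive overlap have labels t in (s, e+1min)
        first = s + np.timedelta64(1, "s")
        first_label = (
            first + (one_min - np.timedelta64(1, "s"))
        ).astype("datetime64[m]").astype("datetime64[s]")
        t = first_label
        while t < e + one_min:
            lo = max(s, t - one_min)
            hi = min(e, t)
            overlap = (hi - lo) / np.timedelta64(1, "s")
            if overlap > 0:
                labels.append(t)
                values.append(n * overlap / dur)
            t = t + one_min
    out = pd.Series(values, index=pd.DatetimeIndex(labels))
    return out.groupby(level=0).sum()


def compute_cadence(intervals: pd.DataFrame, minutes) -> np.ndarray:
    """Cadence (steps/min) at each requested minute label.

    ``minutes`` are the minute labels of the heart-rate series; a minute with
    no overlapping step interval gets cadence 0.
    """
    minutes = pd.DatetimeIndex(minutes)
    prorated = prorate_steps(intervals)
    return prorated.reindex(minutes, fill_value=0.0).to_numpy()


def merge_streams(hr: pd.DataFrame, cadence) -> pd.DataFrame:
    """Zip the resampled heart-rate series with per-minute cadence."""
    cadence = np.asarray(cadence, dtype=float)
    if len(cadence) != len(hr):
        raise ValueError(
            f"cadence length {len(cadence)} does not match {len(hr)} hr minutes"
        )
    out = hr.copy()
    out["cadence"] = cadence
    return out


def resting_hr(day: pd.DataFrame) -> float:
    """Daily resting heart rate: 10th percentile of hr between noon and 9 pm.

    Falls back to the whole day's 10th percentile when the noon-9pm window
    holds no minutes.  ``day`` must contain minutes of a single calendar day.
    """
    if len(day) == 0:
        raise EmptySeriesError("no minutes in day")
    minute = pd.to_datetime(day["minute"])
    tod = minute.dt.hour * 60 + minute.dt.minute
    in_window = (tod >= REST_WINDOW[0]) & (tod < REST_WINDOW[1])
    hr = np.asarray(day["hr"], dtype=float)
    pool = hr[np.asarray(in_window)]
    if len(pool) == 0:
        pool = hr
    return float(np.percentile(pool, REST_PERCENTILE))


def daily_resting_hr(minutes: pd.DataFrame) -> pd.Series:
    """Resting heart rate per observed calendar day, indexed by date."""
    minute = pd.to_datetime(minutes["minute"])
    return (
        minutes.assign(_date=minute.dt.date)
        .groupby("_date")[["minute", "hr"]]
        .apply(resting_hr)
        .rename("hr_rest")
    )


def preprocess_user(hr_samples: pd.DataFrame, step_intervals: pd.DataFrame) -> pd.DataFrame:
    """Full per-user preprocessing: resample, prorate, merge."""
    hr = resample_hr(hr_samples)
    cadence = compute_cadence(step_intervals, hr["minute"])
    return merge_streams(hr, cadence)


def _read_validated(path, columns: list[str], parse: dict) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise ValueError(f"{path}: expected columns {columns}, got {list(df.columns)}")
    n = len(df)
    for col, fn in parse.items():
        df[col] = fn(df[col])
    bad = df.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: rejected %d unparseable rows", path, int(bad.sum()))
        df = df[~bad]
    logger.info("%s: read %d rows (%d rejected)", path, len(df), n - len(df))
    return df.reset_index(drop=True)


def read_hr_csv(path) -> pd.DataFrame:
    """Read hr.csv (user_id, timestamp, bpm) with strict header validation."""
    return _read_validated(
        path,
        HR_COLUMNS,
        {"timestamp": _to_local_naive, "bpm": lambda s: pd.to_numeric(s, errors="coerce")},
    )


def read_steps_csv(path) -> pd.DataFrame:
    """Read steps.csv (user_id, start, end, steps) with strict header validation."""
    return _read_validated(
        path,
        STEP_COLUMNS,
        {
            "start": _to_local_naive,
            "end": _to_local_naive,
            "steps": lambda s: pd.to_numeric(s, errors="coerce"),
        },
    )


def preprocess(hr_df: pd.DataFrame, steps_df: pd.DataFrame) -> pd.DataFrame:
    """Preprocess all users; returns user_id, minute, hr, cadence rows."""
    frames = []
    step_groups = (
        dict(iter(steps_df.groupby("user_id", observed=True))) if len(steps_df) else {}
    )
    for user_id, hr_user in hr_df.groupby("user_id", observed=True):
        steps_user = step_groups.get(
            user_id, pd.DataFrame(columns=STEP_COLUMNS)
        )
        merged = preprocess_user(hr_user, steps_user)
        merged.insert(0, "user_id", user_id)
        frames.append(merged)
    if not frames:
        return pd.DataFrame(columns=MINUTE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
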