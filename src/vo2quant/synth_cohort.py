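"""Synthetic wearable cohort: the feature model run forward.

Each simulated user carries a latent VO2 max built from anthropometrics
(older age, higher BMI and female gender lower it), an independent habitual-
activity component, and residual variation; the marginal distribution matches
a free-living smartwatch cohort (mean 36.16, SD 6.66 ml/kg/min).  Fitness is
expressed in the streams exactly through the structures the features assume:

* a per-user continuous two-segment piecewise-linear heart-rate response to
  cadence (knot at 100 steps/min) whose intercept and slopes decrease with
  the fitness core — fitter users run lower heart rates at the same cadence;
* a resting heart rate that decreases with fitness, driving the daily
  MET-minute structure;
* walking/running bouts whose daily volume follows a heavy-tailed per-user
  propensity, so the cohort spans users with almost no activity up to
  thousands of active minutes;
* a day-level systemic heart-rate shift (sleep, stress, heat) on top of
  minute noise, so response estimates from short histories are genuinely
  uncertain and prediction sharpness improves with more observed data;
* heart-rate samples at irregular within-minute times and step counts
  emitted as multi-minute intervals (one per bout), exercising resampling
  and proration;
* labels equal to latent VO2 max plus Gaussian device-style noise
  (SD 3.5 ml/kg/min, the accuracy reported for wrist-worn estimates).

Every user and every (user, day) has its own RNG stream derived from the
cohort seed, so generation is fully deterministic and order-independent.
The generator makes no physiological claims beyond these identifiable
structures (no circadian rhythm, HRV, GPS, or disease states).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MINUTE = np.timedelta64(60, "s")


@dataclass
class CohortConfig:
    """Generator settings; defaults are the desk-scale study conditions."""

    n_users: int = 2000
    days_per_user: int = 10
    start_date: str = "2021-03-01"
    seed: int = 0

    # label distribution and noise
    vo2_mean: float = 36.16
    vo2_sd: float = 6.66
    label_noise_sd: float = 3.5

    # anthropometrics
    male_fraction: float = 2.0 / 3.0
    age_mean: float = 42.0
    age_sd: float = 10.6
    bmi_mean: float = 26.5
    bmi_sd: float = 4.0

    # couplings of latent VO2 max (per unit of the named quantity)
    gender_gap: float = 6.0       # male minus cohort-centred gender effect
    age_slope: float = -0.35      # per year
    bmi_slope: float = -0.60      # per kg/m^2
    activity_effect: float = 2.5  # per SD of log habitual activity

    # habitual activity: daily active minutes ~ Poisson(lam),
    # lam = activity_median * exp(activity_sigma * z), z ~ N(0, 1)
    activity_median: float = 20.0
    activity_sigma: float = 1.4
    mean_bout_minutes: float = 8.0
    run_fraction: float = 0.3
    walk_cadence_mean: float = 95.0
    walk_cadence_sd: float = 8.0
    run_cadence_mean: float = 160.0
    run_cadence_sd: float = 8.0

    # heart-rate response coupling (per ml/kg/min of the fitness core)
    w0_base: float = 95.0
    w0_slope: float = -0.8
    w1_base: float = 0.25
    w1_slope: float = -0.004
    w2_base: float = 0.45
    w2_slope: float = -0.003

    # resting heart rate
    rest_hr_base: float = 72.0
    rest_hr_slope: float = -0.5
    rest_hr_sd: float = 3.0

    # stream noise / sampling
    hr_noise_sd: float = 5.0
    day_hr_shift_sd: float = 5.0  # day-level systemic HR shift (sleep, stress, heat)
    rest_sample_period: float = 5.0  # minutes between background HR samples

    def core_sd(self) -> float:
        """Residual SD of the fitness core so the marginal SD hits vo2_sd."""
        p = self.male_fraction
        explained = (
            self.gender_gap**2 * p * (1 - p)
            + self.age_slope**2 * self.age_sd**2
            + self.bmi_slope**2 * self.bmi_sd**2
            + self.activity_effect**2
        )
        return float(np.sqrt(max(self.vo2_sd**2 - explained, 0.25)))


@dataclass
class SimUser:
    """One simulated user: profile, latent truth, generating coefficients."""

    index: int
    user_id: str
    gender: int  # female = 0, male = 1
    age: float
    bmi: float
    height_cm: float
    weight_kg: float
    hr_rest: float
    lam: float          # mean daily active minutes
    vo2_core: float     # fitness expressed in heart-rate response
    vo2max: float       # latent label target
    label: float
    w_true: tuple[float, float, float]


def _user_rng(config: CohortConfig, index: int, day: int | None = None):
    key = [config.seed, 1, index] if day is None else [config.seed, 2, index, day]
    return np.random.default_rng(key)


def sample_user(config: CohortConfig, index: int) -> SimUser:
    """Draw one user's profile and latent structure (deterministic in seed/index)."""
    if index >= config.n_users:
        raise IndexError(f"user index {index} out of range for n_users={config.n_users}")
    rng = _user_rng(config, index)
    male = int(rng.random() < config.male_fraction)
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 80.0))
    bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 16.0, 45.0))
    height = float(
        np.clip(rng.normal(178.0 if male else 165.0, 7.0), 145.0, 205.0)
    )
    weight = bmi * (height / 100.0) ** 2

    z_act = float(rng.normal())
    lam = config.activity_median * float(np.exp(config.activity_sigma * z_act))

    vo2_core = (
        config.vo2_mean
        + config.gender_gap * (male - config.male_fraction)
        + config.age_slope * (age - config.age_mean)
        + config.bmi_slope * (bmi - config.bmi_mean)
        + config.core_sd() * float(rng.normal())
    )
    vo2 = float(np.clip(vo2_core + config.activity_effect * z_act, 15.0, 70.0))

    dv = vo2_core - config.vo2_mean
    w0 = config.w0_base + config.w0_slope * dv
    w1 = float(np.clip(config.w1_base + config.w1_slope * dv, 0.05, 0.6))
    w2 = float(np.clip(config.w2_base + config.w2_slope * dv, 0.05, 0.8))
    hr_rest = float(
        np.clip(
            config.rest_hr_base
            + config.rest_hr_slope * dv
            + rng.normal(0.0, config.rest_hr_sd),
            45.0,
            95.0,
        )
    )
    # device-style label: latent value plus estimate noise, within the range
    # wrist devices actually report
    label = float(
        np.clip(vo2 + rng.normal(0.0, config.label_noise_sd), 12.0, 80.0)
    )
    return SimUser(
        index=index,
        user_id=f"u{index:05d}",
        gender=male,
        age=age,
        bmi=bmi,
        height_cm=height,
        weight_kg=weight,
        hr_rest=hr_rest,
        lam=lam,
        vo2_core=vo2_core,
        vo2max=vo2,
        label=label,
        w_true=(w0, w1, w2),
    )


def _response(w: tuple[float, float, float], cadence, knot: float = 100.0):
    c = np.asarray(cadence, dtype=float)
    return w[0] + w[1] * np.minimum(c, knot) + w[2] * np.maximum(c - knot, 0.0)


#: active bouts are placed at minute-of-day labels inside this window
ACTIVE_WINDOW = (8 * 60, 20 * 60)
#: background heart-rate samples span this window
WAKING_WINDOW = (7 * 60, 23 * 60)


def _simulate_day_arrays(user: SimUser, config: CohortConfig, day_index: int, emit_streams: bool):
    rng = _user_rng(config, user.index, day_index)
    day0 = np.datetime64(config.start_date, "s") + np.timedelta64(day_index, "D")

    # --- place activity bouts on minute-of-day labels
    n_act = int(min(rng.poisson(user.lam), 600))
    occupied = np.zeros(1440, dtype=bool)
    bouts = []  # (start_mod, length, cadence)
    remaining = n_act
    while remaining > 0:
        length = int(min(remaining, 1 + rng.geometric(1.0 / config.mean_bout_minutes)))
        for _ in range(20):
            s = int(rng.integers(ACTIVE_WINDOW[0], ACTIVE_WINDOW[1] - length))
            if not occupied[s - 1 : s + length + 1].any():
                occupied[s : s + length] = True
                running = rng.random() < config.run_fraction
                mean = config.run_cadence_mean if running else config.walk_cadence_mean
                sd = config.run_cadence_sd if running else config.walk_cadence_sd
                cadence = int(np.clip(np.round(rng.normal(mean, sd)), 65, 220))
                bouts.append((s, length, cadence))
                break
        # unplaced bouts (day already saturated) simply drop their minutes
        remaining -= length

    # --- background (resting) coverage
    period = max(1, int(config.rest_sample_period))
    base = np.arange(WAKING_WINDOW[0], WAKING_WINDOW[1], period)
    rest_mod = np.unique(base + rng.integers(0, period, size=len(base)))
    rest_mod = rest_mod[~occupied[rest_mod]]
    # systemic day-level shift: the whole day's heart rate runs high or low
    day_shift = rng.normal(0.0, config.day_hr_shift_sd)
    hr_rest_day = user.hr_rest + day_shift
    rest_hr = hr_rest_day + rng.normal(0.0, 2.0, size=len(rest_mod))

    # --- active minutes: heart rate follows the piecewise-linear response
    act_mod = np.concatenate(
        [np.arange(s, s + L) for s, L, _ in bouts]
    ) if bouts else np.empty(0, dtype=int)
    act_cad = np.concatenate(
        [np.full(L, c, dtype=float) for _, L, c in bouts]
    ) if bouts else np.empty(0)
    scale = 0.5 + act_cad / 200.0  # heteroscedastic: noisier at high cadence
    act_hr = (
        _response(user.w_true, act_cad)
        + day_shift
        + rng.normal(size=len(act_mod)) * (config.hr_noise_sd * scale)
    )

    mod = np.concatenate([rest_mod, act_mod])
    hr = np.clip(np.concatenate([rest_hr, act_hr]), 25.0, 245.0)
    cad = np.concatenate([np.zeros(len(rest_mod)), act_cad])
    order = np.argsort(mod, kind="stable")
    mod, hr, cad = mod[order], hr[order], cad[order]
    labels = day0 + mod.astype("timedelta64[m]").astype("timedelta64[s]")

    ts = bpm = starts = ends = steps = None
    if emit_streams:
        # irregular HR samples: 1-3 per covered minute, same value
        counts = rng.integers(1, 4, size=len(mod))
        offsets = rng.integers(0, 60, size=int(counts.sum()))
        ts = np.repeat(labels, counts) + offsets.astype("timedelta64[s]")
        bpm = np.repeat(hr, counts)
        sample_order = np.argsort(ts, kind="stable")
        ts, bpm = ts[sample_order], bpm[sample_order]
        # one multi-minute step interval per bout
        bouts.sort()
        firsts = day0 + np.array([s for s, _, _ in bouts], dtype="timedelta64[m]")
        starts = firsts - MINUTE
        ends = firsts + np.array([L - 1 for _, L, _ in bouts], dtype="timedelta64[m]")
        steps = np.array([c * L for _, L, c in bouts], dtype=np.int64)
    return labels, hr, cad, ts, bpm, starts, ends, steps


def simulate_day(user: SimUser, config: CohortConfig, day_index: int):
    """One day of streams for one user.

    Returns ``(minutes, hr_samples, step_intervals)``:

    * minutes — DataFrame (minute, hr, cadence), the ground-truth per-minute
      series the preprocessing stage should reconstruct; a minute label ``t``
      pairs heart rate sampled during [t, t+1min) with the steps made during
      (t-1min, t] (heart rate trails the cadence window by construction);
    * hr_samples — DataFrame (timestamp, bpm), 1-3 samples per covered
      minute at irregular second offsets, all reporting the minute's value;
    * step_intervals — DataFrame (start, end, steps), one interval per bout
      spanning its whole duration at constant cadence.
    """
    labels, hr, cad, ts, bpm, starts, ends, steps = _simulate_day_arrays(
        user, config, day_index, emit_streams=True
    )
    minutes = pd.DataFrame({"minute": labels, "hr": hr, "cadence": cad})
    hr_samples = pd.DataFrame({"timestamp": ts, "bpm": bpm})
    step_intervals = pd.DataFrame(
        {"start": starts, "end": ends, "steps": steps},
    )
    return minutes, hr_samples, step_intervals


@dataclass
class SimCohort:
    """Generated cohort: truth table, labels, minute series and raw streams."""

    config: CohortConfig
    users: pd.DataFrame    # profile + latent truth columns
    labels: pd.DataFrame   # user_id, vo2max (noisy device-style label)
    minutes: pd.DataFrame  # user_id, minute, hr, cadence (ground truth)
    hr: pd.DataFrame | None = None      # user_id, timestamp, bpm
    steps: pd.DataFrame | None = None   # user_id, start, end, steps

    def write_csv(self, out_dir) -> None:
        """Write the CSV dialects the pipeline readers expect."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        users = self.users.copy()
        users["gender"] = np.where(users["gender"] == 1, "m", "f")
        users[["user_id", "age", "gender", "height_cm", "weight_kg"]].to_csv(
            out / "users.csv", index=False
        )
        self.labels.to_csv(out / "labels.csv", index=False)
        if self.hr is None or self.steps is None:
            raise ValueError("cohort was generated without streams")
        self.hr.to_csv(out / "hr.csv", index=False)
        self.steps.to_csv(out / "steps.csv", index=False)


def simulate_user_streams(user: SimUser, config: CohortConfig, emit_streams: bool = True):
    """All days of one user; concatenated (minutes, hr_samples, step_intervals)."""
    parts = [
        _simulate_day_arrays(user, config, d, emit_streams)
        for d in range(config.days_per_user)
    ]
    minutes = pd.DataFrame(
        {
            "minute": np.concatenate([p[0] for p in parts]),
            "hr": np.concatenate([p[1] for p in parts]),
            "cadence": np.concatenate([p[2] for p in parts]),
        }
    )
    if not emit_streams:
        return minutes, None, None
    hr_samples = pd.DataFrame(
        {
            "timestamp": np.concatenate([p[3] for p in parts]),
            "bpm": np.concatenate([p[4] for p in parts]),
        }
    )
    step_intervals = pd.DataFrame(
        {
            "start": np.concatenate([p[5] for p in parts]),
            "end": np.concatenate([p[6] for p in parts]),
            "steps": np.concatenate([p[7] for p in parts]),
        }
    )
    return minutes, hr_samples, step_intervals


def generate_cohort(
    config: CohortConfig, emit_streams: bool = True, out_dir=None
) -> SimCohort:
    """Generate the full cohort; optionally write the CSV fixture set.

    With ``emit_streams=False`` only the ground-truth minute series is built
    (the raw sample/interval expansion is skipped); the minute series is
    identical to what preprocessing the emitted streams would produce, which
    is what large pipeline experiments consume.
    """
    users = [sample_user(config, i) for i in range(config.n_users)]
    user_rows = []
    min_parts: list[tuple] = []
    hr_parts: list[tuple] = []
    step_parts: list[tuple] = []
    for u in users:
        for d in range(config.days_per_user):
            labels, hr, cad, ts, bpm, starts, ends, steps = _simulate_day_arrays(
                u, config, d, emit_streams
            )
            min_parts.append((u.user_id, labels, hr, cad))
            if emit_streams:
                hr_parts.append((u.user_id, ts, bpm))
                step_parts.append((u.user_id, starts, ends, steps))
        row = asdict(u)
        w = row.pop("w_true")
        row.update({"w0_true": w[0], "w1_true": w[1], "w2_true": w[2]})
        user_rows.append(row)

    def _concat(parts, names):
        ids = [u.user_id for u in users]
        id_codes = {uid: k for k, uid in enumerate(ids)}
        codes = np.repeat(
            np.array([id_codes[p[0]] for p in parts]),
            [len(p[1]) for p in parts],
        )
        data = {"user_id": pd.Categorical.from_codes(codes, categories=ids)}
        for i, name in enumerate(names, start=1):
            data[name] = np.concatenate([p[i] for p in parts])
        return pd.DataFrame(data)

    users_df = pd.DataFrame(user_rows)
    labels_df = users_df[["user_id", "label"]].rename(columns={"label": "vo2max"})
    cohort = SimCohort(
        config=config,
        users=users_df,
        labels=labels_df,
        minutes=_concat(min_parts, ["minute", "hr", "cadence"]),
        hr=_concat(hr_parts, ["timestamp", "bpm"]) if emit_streams else None,
        steps=_concat(step_parts, ["start", "end", "steps"]) if emit_streams else None,
    )
    if out_dir is not None:
        cohort.write_csv(out_dir)
    return cohort


def config_from_yaml(path) -> CohortConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return CohortConfig(**raw)
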