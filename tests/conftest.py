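"""Shared fixtures: small synthetic cohorts and a trained stack."""

import numpy as np
import pandas as pd
import pytest

import vo2quant as vq


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 users, 3 days, with raw streams — used for round-trip tests."""
    cfg = vq.CohortConfig(n_users=12, days_per_user=3, seed=7)
    return vq.generate_cohort(cfg, emit_streams=True)


@pytest.fixture(scope="session")
def small_cohort():
    """250 users without stream expansion — enough to train a stack."""
    cfg = vq.CohortConfig(n_users=250, days_per_user=6, seed=42)
    return vq.generate_cohort(cfg, emit_streams=False)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return vq.extract_features(small_cohort.minutes, small_cohort.users)


@pytest.fixture(scope="session")
def small_xy(small_cohort, small_features):
    X = small_features[vq.FEATURE_NAMES].to_numpy(dtype=float)
    y = small_cohort.labels["vo2max"].to_numpy(dtype=float)
    return X, y


@pytest.fixture(scope="session")
def trained_stack(small_xy):
    X, y = small_xy
    return vq.QuantileStack(vq.StackConfig(seed=3)).fit(X, y)


def minutes_frame(start, hrs, cadences=None):
    """Helper: a MinuteSeries frame from a start time and per-minute values."""
    n = len(hrs)
    minutes = pd.date_range(start, periods=n, freq="min")
    return pd.DataFrame(
        {
            "minute": minutes,
            "hr": np.asarray(hrs, dtype=float),
            "cadence": np.zeros(n) if cadences is None else np.asarray(cadences, float),
        }
    )
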