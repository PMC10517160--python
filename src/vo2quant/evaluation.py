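"""Scoring of probabilistic VO2 max predictions.

CRPS
    The continuous ranked probability score of a predicted CDF F against an
    observation y, integral of (F(z) - 1{z >= y})^2 dz.  With the CDF given
    implicitly as the inverse of the rearranged quantile function, the score
    is computed in quantile space through the identity
    CRPS = 2 * integral over q in [0, 1] of the pinball loss L_q(y, Q(q)),
    evaluated by trapezoid on the rearrangement grid.  Reported positively
    oriented: lower is better (the score is sometimes written with a leading
    minus and maximized; we drop the sign).
ECE
    The expected calibration error: average absolute gap between the nominal
    level q and the observed coverage p_obs(q) = fraction of labels at or
    below the predicted q-quantile.  The integrand is observable only at the
    fitted levels [0.05, 0.95]; we integrate by trapezoid over that range and
    leave the unobservable tails out (they would require extrapolating the
    quantile function).
Sharpness
    Average predicted interquartile range; smaller is more informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from .features import FEATURE_NAMES, GROUPS
from .quantile_model import (
    MarginalQuantileStack,
    QuantileStack,
    RearrangedPrediction,
    StackConfig,
)

#: active-minute bins for the sharpness-vs-data experiment
ACTIVITY_BINS = (0, 10, 30, 60, 100, 200, 500, 1000, np.inf)


@dataclass(frozen=True)
class EvalReport:
    ece: float
    iqr: float
    crps_mean: float
    median_error_mean: float
    median_error_sd: float
    n: int

    def to_dict(self) -> dict:
        return {
            "ece": self.ece,
            "iqr": self.iqr,
            "crps_mean": self.crps_mean,
            "median_error_mean": self.median_error_mean,
            "median_error_sd": self.median_error_sd,
            "n": self.n,
        }


def crps(prediction: RearrangedPrediction, y: float) -> float:
    """CRPS via the quantile-space pinball identity on the rearrangement grid."""
    q = prediction.grid
    vals = prediction.sorted_grid
    if (np.diff(vals) < 0).any():
        raise ValueError("prediction quantiles are not monotone")
    losses = q * np.maximum(y - vals, 0.0) + (1.0 - q) * np.maximum(vals - y, 0.0)
    return float(2.0 * np.trapezoid(losses, q))


def crps_cdf_space(prediction: RearrangedPrediction, y: float, n_grid: int = 20001) -> float:
    """CRPS by direct numeric quadrature of (F(z) - 1{z >= y})^2 dz.

    Independent of the quantile-space route: reconstructs the CDF as the
    inverse of the quantile function and integrates in observation space.
    """
    vals = prediction.sorted_grid
    levels = prediction.grid
    # invert the (possibly flat) quantile function: keep the highest level
    # attained at each distinct value
    uniq, idx = np.unique(vals[::-1], return_index=True)
    top_level = levels[::-1][idx]
    lo = min(vals[0], y)
    hi = max(vals[-1], y)
    pad = max(1e-9, 1e-6 * (hi - lo))
    z = np.linspace(lo - pad, hi + pad, n_grid)
    F = np.interp(z, uniq, top_level, left=0.0, right=1.0)
    integrand = (F - (z >= y)) ** 2
    return float(np.trapezoid(integrand, z))


def observed_coverage(predictions, labels) -> tuple[np.ndarray, np.ndarray]:
    """(p_obs, levels): observed coverage per fitted level."""
    labels = np.asarray(labels, dtype=float)
    if len(predictions) != len(labels) or len(labels) == 0:
        raise ValueError("predictions and labels must be aligned and non-empty")
    levels = predictions[0].levels
    Q = np.vstack([p.values for p in predictions])
    return (labels[:, None] <= Q).mean(axis=0), levels


def ece(predictions, labels) -> float:
    """Expected calibration error, trapezoid over the fitted levels."""
    p_obs, levels = observed_coverage(predictions, labels)
    return float(np.trapezoid(np.abs(p_obs - levels), levels))


def sharpness(predictions) -> float:
    """Average predicted interquartile range (ml/kg/min)."""
    return float(np.mean([p.iqr for p in predictions]))


def median_error(predictions, labels) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of y - Q-hat(x, 0.5)."""
    labels = np.asarray(labels, dtype=float)
    err = labels - np.array([p.median for p in predictions])
    sd = float(err.std(ddof=1)) if len(err) > 1 else 0.0
    return float(err.mean()), sd


def evaluate(predictions, labels) -> EvalReport:
    """All headline metrics for a prediction/label set."""
    labels = np.asarray(labels, dtype=float)
    me, sd = median_error(predictions, labels)
    return EvalReport(
        ece=ece(predictions, labels),
        iqr=sharpness(predictions),
        crps_mean=float(np.mean([crps(p, y) for p, y in zip(predictions, labels)])),
        median_error_mean=me,
        median_error_sd=sd,
        n=len(labels),
    )


def cv_crps(X, y, config: StackConfig | None = None, k: int = 5, seed: int = 0) -> float:
    """Mean held-out CRPS over a seeded shuffled k-fold split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < k:
        raise ValueError(f"need at least {k} rows for {k}-fold CV")
    scores = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        stack = QuantileStack(config).fit(X[train_idx], y[train_idx])
        preds = stack.predict_quantiles(X[test_idx])
        scores.append(np.mean([crps(p, yy) for p, yy in zip(preds, y[test_idx])]))
    return float(np.mean(scores))


def search_hyperparams(
    X,
    y,
    candidates: list[dict],
    base_config: StackConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[StackConfig, pd.DataFrame]:
    """Grid/random search over StackConfig overrides minimizing CV CRPS.

    ``candidates`` is a list of field-override dicts (a grid, or random draws
    prepared by the caller); the best config and the full score table are
    returned.
    """
    base = base_config or StackConfig()
    rows = []
    for overrides in candidates:
        cfg = StackConfig(**({f: getattr(base, f) for f in base.__dataclass_fields__} | overrides))
        rows.append(overrides | {"cv_crps": cv_crps(X, y, cfg, k=k, seed=seed)})
    table = pd.DataFrame(rows).sort_values("cv_crps", ignore_index=True)
    best = candidates[int(np.argmin([r["cv_crps"] for r in rows]))]
    best_cfg = StackConfig(
        **({f: getattr(base, f) for f in base.__dataclass_fields__} | best)
    )
    return best_cfg, table


GROUP_SEQUENCE = (
    (),
    ("ant",),
    ("ant", "chr"),
    ("ant", "chr", "resp"),
    ("ant", "chr", "resp", "met"),
)


def _group_columns(groups) -> list[int]:
    cols = []
    for g in groups:
        cols.extend(FEATURE_NAMES.index(name) for name in GROUPS[g])
    return sorted(cols)


def _fit_subset(X_train, y_train, groups, config: StackConfig | None):
    """Fit a stack on a feature-group subset; empty set -> marginal model."""
    cfg = config or StackConfig()
    if len(groups) == 0:
        return MarginalQuantileStack(cfg.levels).fit(X_train, y_train), slice(0, 0)
    cols = _group_columns(groups)
    return QuantileStack(cfg).fit(X_train[:, cols], y_train), cols


def ablation(
    X,
    y,
    group_sequence=GROUP_SEQUENCE,
    config: StackConfig | None = None,
    test_size: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-fit and score the model on nested feature-group subsets.

    A seeded train/test split is shared across subsets; the empty subset is
    the marginal-quantile baseline.  Returns one EvalReport row per subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=test_size, random_state=seed)
    rows = []
    for groups in group_sequence:
        model, cols = _fit_subset(X_tr, y_tr, groups, config)
        X_te_sub = X_te[:, cols] if len(groups) else X_te
        report = evaluate(model.predict_quantiles(X_te_sub), y_te)
        train_report = evaluate(
            model.predict_quantiles(X_tr[:, cols] if len(groups) else X_tr), y_tr
        )
        rows.append(
            {"features": "+".join(groups) if groups else "none"}
            | report.to_dict()
            | {
                "train_median_error_mean": train_report.median_error_mean,
                "train_median_error_sd": train_report.median_error_sd,
            }
        )
    return pd.DataFrame(rows)


def sharpness_vs_history(
    stack,
    minutes_df,
    users_df,
    window_days=(1, 3, 10),
    bins=ACTIVITY_BINS,
    full_features=None,
) -> pd.DataFrame:
    """Predicted sharpness versus amount of available input data.

    Mirrors the history-window design: for each user, features are computed
    from progressively shorter lookback windows of their stream history, the
    model predicts from each window, and the predicted interquartile range is
    binned by the window's active-minute count.  ``full_features`` may pass a
    precomputed full-history feature table to avoid recomputing the longest
    window.

    Returns the per-bin mean IQR table (pooled over users and windows).
    """
    from .features import FEATURE_NAMES, extract_features

    iqrs, actives = [], []
    max_window = max(window_days)
    for w in window_days:
        if w == max_window and full_features is not None:
            feats = full_features
        else:
            feats = extract_features(minutes_df, users_df, lookback_days=w)
        X = feats[FEATURE_NAMES].to_numpy(dtype=float)
        preds = stack.predict_quantiles(X)
        iqrs.extend(p.iqr for p in preds)
        actives.extend(feats["active_minutes"].to_numpy())
    return sharpness_by_activity(
        [_FixedIqr(v) for v in iqrs], np.asarray(actives), bins=bins
    )


class _FixedIqr:
    """Adapter letting precomputed IQRs flow through sharpness_by_activity."""

    def __init__(self, iqr: float):
        self.iqr = iqr


def sharpness_by_activity(
    predictions, active_minutes, bins=ACTIVITY_BINS
) -> pd.DataFrame:
    """Mean predicted IQR binned by the user's active-minute count."""
    active_minutes = np.asarray(active_minutes, dtype=float)
    iqrs = np.array([p.iqr for p in predictions])
    edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (active_minutes >= lo) & (active_minutes < hi)
        rows.append(
            {
                "bin": f"[{lo:g}, {hi:g})",
                "lo": lo,
                "hi": hi,
                "n": int(mask.sum()),
                "iqr": float(iqrs[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
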