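"""Gradient-boosting quantile stack with monotone rearrangement.

One LightGBM learner f_q is trained per level q = 0.05, 0.10, ..., 0.95 with
the pinball objective at that level, all sharing the same hyperparameters and
training rows.  Because the learners are fitted independently, the raw curve
q -> f_q(x) need not be monotone; at prediction time it is monotonized by
rearrangement: interpolate the (q, f_q(x)) pairs to a function f_x on [0, 1]
(constant-clamped outside the fitted levels), and take the quantile function
of f_x(U) with U ~ Uniform(0, 1).  The rearranged curve Q-hat(x, q) is
non-decreasing in q by construction and is never further from the true
conditional quantiles than the raw one.

The rearrangement is computed deterministically by evaluating f_x on a fixed
fine grid (1001 equispaced points on [0, 1]), sorting, and reading quantiles
off the sorted grid by linear interpolation — the standard plug-in estimator
of the quantile function of f_x(U).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import lightgbm as lgb
import yaml

DEFAULT_LEVELS = tuple(np.round(np.arange(1, 20) * 0.05, 2))
REARRANGE_GRID = 1001
MIN_TRAIN_ROWS = 50
LABEL_RANGE = (10.0, 90.0)  # plausible VO2 max, ml/kg/min


@dataclass
class StackConfig:
    """Hyperparameters shared by all per-level learners.

    Defaults are the tuned gradient-boosting parameters: tree depth 4,
    313 estimators, bagging fraction 0.75 every 13 iterations, learning
    rate 0.1, at least 22 samples per leaf, L1 regularization 0.142.
    """

    levels: tuple = DEFAULT_LEVELS
    max_depth: int = 4
    n_estimators: int = 313
    bagging_fraction: float = 0.75
    bagging_frequency: int = 13
    learning_rate: float = 0.1
    min_samples_leaf: int = 22
    l1_reg: float = 0.142
    seed: int = 0

    def __post_init__(self):
        levels = tuple(float(q) for q in self.levels)
        if not all(0.0 < q < 1.0 for q in levels):
            raise ValueError("levels must lie in (0, 1)")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly increasing")
        self.levels = levels

    def lgbm_params(self, q: float) -> dict:
        return dict(
            objective="quantile",
            alpha=q,
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            subsample=self.bagging_fraction,
            subsample_freq=self.bagging_frequency,
            learning_rate=self.learning_rate,
            min_child_samples=self.min_samples_leaf,
            reg_alpha=self.l1_reg,
            random_state=self.seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )


@dataclass(frozen=True)
class RearrangedPrediction:
    """Raw per-level values f_q(x) and their monotone rearrangement.

    ``sorted_grid`` holds the rearranged values at ``grid`` (equispaced on
    [0, 1]); ``quantile(q)`` linearly interpolates the sorted grid, which is
    exactly the conditional quantile estimate Q-hat(x, q).
    """

    levels: np.ndarray
    raw: np.ndarray
    grid: np.ndarray
    sorted_grid: np.ndarray

    def quantile(self, q):
        return np.interp(q, self.grid, self.sorted_grid)

    @property
    def values(self) -> np.ndarray:
        """Rearranged values at the stack's own levels."""
        return self.quantile(self.levels)

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    @property
    def iqr(self) -> float:
        return float(self.quantile(0.75) - self.quantile(0.25))


def rearrange(levels, values, grid_size: int = REARRANGE_GRID) -> RearrangedPrediction:
    """Monotonize raw quantile values by rearrangement.

    ``values`` are f_q(x) at strictly increasing ``levels``; the interpolant
    is piecewise linear between levels and constant-clamped outside them.
    """
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(values, dtype=float)
    if levels.shape != values.shape or levels.ndim != 1 or len(levels) < 2:
        raise ValueError("need >= 2 aligned (level, value) pairs")
    if not np.isfinite(values).all():
        raise ValueError("non-finite raw quantile values")
    grid = np.linspace(0.0, 1.0, grid_size)
    f_x = np.interp(grid, levels, values)  # np.interp clamps outside levels
    return RearrangedPrediction(
        levels=levels, raw=values, grid=grid, sorted_grid=np.sort(f_x)
    )


class QuantileStack:
    """The family of per-level learners plus rearranged prediction."""

    def __init__(self, config: StackConfig | None = None):
        self.config = config or StackConfig()
        self.learners_: dict[float, lgb.LGBMRegressor] = {}

    @property
    def levels(self) -> np.ndarray:
        return np.asarray(self.config.levels)

    def fit(self, X, y) -> "QuantileStack":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < MIN_TRAIN_ROWS:
            raise ValueError(f"need >= {MIN_TRAIN_ROWS} training rows, got {len(X)}")
        if ((y < LABEL_RANGE[0]) | (y > LABEL_RANGE[1])).any():
            raise ValueError(f"labels outside plausible VO2 max range {LABEL_RANGE}")
        self.learners_ = {}
        self.train_hash_ = data_hash(X, y)
        for q in self.config.levels:
            m = lgb.LGBMRegressor(**self.config.lgbm_params(q))
            m.fit(X, y)
            self.learners_[q] = m
        return self

    def _check_fitted(self):
        if not self.learners_:
            raise RuntimeError("stack is not trained")

    def predict_raw(self, X) -> np.ndarray:
        """Raw (pre-rearrangement) f_q values, shape (n_rows, n_levels)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [self.learners_[q].booster_.predict(X) for q in self.config.levels]
        )

    def predict_quantiles(self, X) -> list[RearrangedPrediction]:
        """Rearranged conditional-quantile predictions, one per row."""
        raw = self.predict_raw(X)
        return [rearrange(self.levels, row) for row in raw]

    def predict_one(self, x) -> RearrangedPrediction:
        return self.predict_quantiles(np.atleast_2d(x))[0]

    def median_fn(self):
        """The raw 0.5-level learner as a plain function (for attribution)."""
        self._check_fitted()
        if 0.5 not in self.learners_:
            raise ValueError("stack has no 0.5 level")
        booster = self.learners_[0.5].booster_
        return lambda X: booster.predict(np.atleast_2d(np.asarray(X, dtype=float)))

    # ------------------------------------------------------------------ io
    def save(self, path) -> None:
        """Model artifact: config.yaml, one learner per level, manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self._check_fitted()
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config) | {"levels": list(self.config.levels)}, fh)
        for q, m in self.learners_.items():
            (path / f"learner_q{int(round(q * 100)):02d}.txt").write_text(
                m.booster_.model_to_string()
            )
        manifest = {
            "seed": self.config.seed,
            "levels": list(self.config.levels),
            "train_data_sha256": getattr(self, "train_hash_", None),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "QuantileStack":
        path = Path(path)
        with open(path / "config.yaml") as fh:
            raw = yaml.safe_load(fh)
        config = StackConfig(**{k: v for k, v in raw.items()})
        stack = cls(config)
        for q in config.levels:
            booster = lgb.Booster(
                model_str=(path / f"learner_q{int(round(q * 100)):02d}.txt").read_text()
            )
            stack.learners_[q] = _BoosterAdapter(booster)
        return stack


class _BoosterAdapter:
    """Minimal predict-only wrapper so loaded boosters match the fit path."""

    def __init__(self, booster: lgb.Booster):
        self.booster_ = booster

    def predict(self, X):
        return self.booster_.predict(np.asarray(X, dtype=float))


class MarginalQuantileStack:
    """The no-feature baseline: empirical label quantiles regardless of x."""

    def __init__(self, levels=DEFAULT_LEVELS):
        self.levels = np.asarray(levels, dtype=float)
        self.quantiles_: np.ndarray | None = None

    def fit(self, X, y) -> "MarginalQuantileStack":
        y = np.asarray(y, dtype=float)
        self.quantiles_ = np.quantile(y, self.levels)
        return self

    def predict_raw(self, X) -> np.ndarray:
        if self.quantiles_ is None:
            raise RuntimeError("stack is not trained")
        n = len(np.atleast_2d(np.asarray(X, dtype=float)))
        return np.tile(self.quantiles_, (n, 1))

    def predict_quantiles(self, X) -> list[RearrangedPrediction]:
        return [rearrange(self.levels, row) for row in self.predict_raw(X)]


def data_hash(X, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.asarray(X, dtype=float)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, dtype=float)).tobytes())
    return h.hexdigest()
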