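"""Shapley-value attribution for the median prediction model.

The attributed function is the raw 0.5-level learner f = f_0.5.  Coalition
values use the interventional definition: f_S(x) is the average of f over
background rows where the features in S are replaced by x's values, so
f_fullset(x) = f(x) and f_empty(x) = the background mean.  Group-level values
treat the four feature groups (ant, chr, met, resp) as players and enumerate
all 2^4 coalitions exactly; per-feature values over all 24 features are
estimated by seeded permutation sampling.  Both satisfy efficiency: the
values sum to f(x) minus the background mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .features import FEATURE_NAMES, GROUPS

GROUP_ORDER = ("ant", "chr", "met", "resp")
#: background rows are sub-sampled to this many for speed (seeded)
DEFAULT_BACKGROUND = 500


def group_indices() -> dict[str, list[int]]:
    return {g: [FEATURE_NAMES.index(n) for n in GROUPS[g]] for g in GROUP_ORDER}


def sample_background(X, size: int = DEFAULT_BACKGROUND, seed: int = 0) -> np.ndarray:
    """Seeded background sub-sample (the whole set if small enough)."""
    X = np.asarray(X, dtype=float)
    if len(X) <= size:
        return X
    rng = np.random.default_rng(seed)
    return X[rng.choice(len(X), size=size, replace=False)]


def coalition_value(f, x, feature_subset, background) -> float:
    """f_S(x): mean of f over background rows with features in S set to x."""
    background = np.asarray(background, dtype=float)
    if len(background) == 0:
        raise ValueError("background set is empty")
    Z = background.copy()
    idx = list(feature_subset)
    if idx:
        Z[:, idx] = np.asarray(x, dtype=float)[idx]
    return float(np.mean(f(Z)))


@dataclass(frozen=True)
class Attribution:
    """Per-group Shapley values (ml/kg/min) and the efficiency reference."""

    phi: dict[str, float]
    fx: float
    background_mean: float

    @property
    def total(self) -> float:
        return sum(self.phi.values())


def shapley_groups(f, x, background, groups: dict | None = None) -> Attribution:
    """Exact Shapley values with the feature groups as players.

    Enumerates all coalitions of the (by default four) groups and applies the
    factorial weights |S|! (m - |S| - 1)! / m! to the marginal contributions.
    Deterministic; efficiency holds up to float round-off.
    """
    groups = groups or group_indices()
    names = list(groups)
    m = len(names)
    x = np.asarray(x, dtype=float)

    values = {}
    for mask in range(2**m):
        idx = [j for g in range(m) if mask >> g & 1 for j in groups[names[g]]]
        values[mask] = coalition_value(f, x, idx, background)

    phi = {}
    for g in range(m):
        total = 0.0
        for mask in range(2**m):
            if mask >> g & 1:
                continue
            s = bin(mask).count("1")
            weight = factorial(s) * factorial(m - s - 1) / factorial(m)
            total += weight * (values[mask | 1 << g] - values[mask])
        phi[names[g]] = total
    return Attribution(
        phi=phi, fx=values[2**m - 1], background_mean=values[0]
    )


def shapley_features_mc(
    f, x, background, n_permutations: int = 200, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo per-feature Shapley values over all 24 features.

    Averages marginal contributions over seeded random feature orderings; one
    background-set sweep per permutation.  Returns (values, standard errors).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations for a stable estimate")
    background = np.asarray(background, dtype=float)
    x = np.asarray(x, dtype=float)
    m = len(x)
    rng = np.random.default_rng(seed)
    contribs = np.zeros((n_permutations, m))
    for p in range(n_permutations):
        order = rng.permutation(m)
        Z = background.copy()
        v_prev = float(np.mean(f(Z)))
        for i in order:
            Z[:, i] = x[i]
            v = float(np.mean(f(Z)))
            contribs[p, i] = v - v_prev
            v_prev = v
    values = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return values, se


def group_importance(f, X, background) -> dict[str, float]:
    """Mean absolute group Shapley value across dataset rows, sorted.

    The batched equivalent of calling ``shapley_groups`` per row: coalition
    values for all rows are computed with one model call per coalition.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(X) == 0:
        raise ValueError("dataset is empty")
    groups = group_indices()
    names = list(groups)
    m = len(names)
    n_x, n_bg = len(X), len(background)

    values = {}  # mask -> (n_x,) coalition values
    for mask in range(2**m):
        idx = [j for g in range(m) if mask >> g & 1 for j in groups[names[g]]]
        Z = np.repeat(background[None, :, :], n_x, axis=0)  # (n_x, n_bg, d)
        if idx:
            Z[:, :, idx] = X[:, None, idx]
        preds = f(Z.reshape(n_x * n_bg, -1)).reshape(n_x, n_bg)
        values[mask] = preds.mean(axis=1)

    importance = {}
    for g in range(m):
        phi = np.zeros(n_x)
        for mask in range(2**m):
            if mask >> g & 1:
                continue
            s = bin(mask).count("1")
            weight = factorial(s) * factorial(m - s - 1) / factorial(m)
            phi += weight * (values[mask | 1 << g] - values[mask])
        importance[names[g]] = float(np.abs(phi).mean())
    return dict(sorted(importance.items(), key=lambda kv: -kv[1]))
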