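"""Piecewise-linear quantile regression of heart rate on cadence.

A person's heart-rate response to walking/running cadence is summarised by a
continuous two-segment piecewise-linear curve with the knot fixed at 100
steps/min (the cadence that roughly corresponds to 3 MET).  For each quantile
level ``q`` the three coefficients — intercept ``w0``, first-segment slope
``w1`` and second-segment slope ``w2`` — are chosen to minimise the total
pinball loss over the observed (cadence, heart rate) points.

The minimisation is an exact linear program.  We solve its dual

    max  y' lam    s.t.  X' lam = 0,   lam_i in [q - 1, q]

whose equality-constraint shadow prices are (up to sign) the primal
coefficients; this keeps the constraint matrix at three rows regardless of
the sample size and is solved deterministically by HiGHS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

DEFAULT_KNOT = 100.0
#: quantile levels used for the heart-rate response feature
RESPONSE_LEVELS = (0.1, 0.2, 0.5, 0.8, 0.9)
#: activity filter for response fitting: strict thresholds
HR_THRESHOLD = 75.0
CADENCE_THRESHOLD = 60.0
#: coefficients are reported on a 1e-6 grid for reproducibility
COEF_DECIMALS = 6


def pinball_loss(y, yhat, q: float):
    """Pinball (quantile) loss ``q*max(y-yhat,0) + (1-q)*max(yhat-y,0)``.

    Vectorised over ``y``/``yhat``; ``q`` must lie strictly inside (0, 1).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    diff = y - yhat
    return q * np.maximum(diff, 0.0) + (1.0 - q) * np.maximum(-diff, 0.0)


@dataclass(frozen=True)
class PiecewiseLinearModel:
    """Continuous two-segment piecewise-linear curve hr = f(cadence).

    ``predict`` evaluates ``w0 + w1*min(c, knot) + w2*max(c - knot, 0)``,
    which is continuous at the knot by construction.
    """

    w0: float
    w1: float
    w2: float
    q: float
    knot: float = DEFAULT_KNOT
    degenerate: bool = False

    def predict(self, cadence):
        c = np.asarray(cadence, dtype=float)
        out = self.w0 + self.w1 * np.minimum(c, self.knot) + self.w2 * np.maximum(
            c - self.knot, 0.0
        )
        return float(out) if np.isscalar(cadence) else out

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.w0, self.w1, self.w2)


def _basis(cadence: np.ndarray, knot: float) -> np.ndarray:
    return np.column_stack(
        [
            np.ones_like(cadence),
            np.minimum(cadence, knot),
            np.maximum(cadence - knot, 0.0),
        ]
    )


def fit_quantile(
    cadence,
    hr,
    q: float,
    knot: float = DEFAULT_KNOT,
) -> PiecewiseLinearModel:
    """Fit (w0, w1, w2) at quantile level ``q`` by exact pinball-loss LP.

    Degenerate designs (fewer than two distinct cadence values on a side of
    the knot) drop the unidentifiable slope column; the returned model is
    flagged ``degenerate`` and the dropped slope is zero.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    c = np.asarray(cadence, dtype=float)
    y = np.asarray(hr, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("cadence and hr must be 1-d arrays of equal length")
    if len(c) < 1:
        raise ValueError("cannot fit on an empty sample")
    if not (np.isfinite(c).all() and np.isfinite(y).all()):
        raise ValueError("non-finite cadence or heart-rate values")

    X = _basis(c, knot)
    # identifiability: each slope needs >= 2 distinct values in its column
    keep = [0]
    degenerate = False
    for j in (1, 2):
        if len(np.unique(X[:, j])) >= 2:
            keep.append(j)
        else:
            degenerate = True
    Xk = X[:, keep]

    # dual simplex first; on rare degenerate instances it stalls, in which
    # case the interior-point method with crossover solves the same LP
    res = None
    for method in ("highs", "highs-ipm"):
        res = linprog(
            -y,
            A_eq=Xk.T,
            b_eq=np.zeros(len(keep)),
            bounds=[(q - 1.0, q)] * len(y),
            method=method,
        )
        if res.status == 0:
            break
    if res.status != 0:  # pragma: no cover - at least one solver succeeds
        raise RuntimeError(f"quantile LP failed: {res.message}")
    coefs = np.zeros(3)
    coefs[keep] = -np.asarray(res.eqlin.marginals, dtype=float)
    coefs = np.round(coefs, COEF_DECIMALS)
    return PiecewiseLinearModel(
        w0=float(coefs[0]),
        w1=float(coefs[1]),
        w2=float(coefs[2]),
        q=q,
        knot=knot,
        degenerate=degenerate,
    )


def fit_response(
    cadence,
    hr,
    levels=RESPONSE_LEVELS,
    knot: float = DEFAULT_KNOT,
) -> list[PiecewiseLinearModel]:
    """Independent piecewise-linear quantile fits at each level.

    Levels must be strictly increasing inside (0, 1); the default five levels
    yield the 15 response coefficients.
    """
    levels = tuple(levels)
    if not all(0.0 < q < 1.0 for q in levels):
        raise ValueError("levels must lie in (0, 1)")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")
    return [fit_quantile(cadence, hr, q, knot=knot) for q in levels]


def activity_mask(hr, cadence) -> np.ndarray:
    """Minutes qualifying for the response fit: hr above 75 and cadence over 60."""
    hr = np.asarray(hr, dtype=float)
    cadence = np.asarray(cadence, dtype=float)
    return (hr > HR_THRESHOLD) & (cadence > CADENCE_THRESHOLD)
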