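"""Log-scale, fixed-variability Weber-fraction model.

Numerosity n is represented on a logarithmic mental number line with
constant representational noise.  For a comparison of n_L > n_S the
difference of the two representations is Gaussian with mean
log(n_L) - log(n_S) and standard deviation sqrt(2)*w, so the error rate is
the mass of that Gaussian below zero:

    P(error) = 1/2 * erfc( (log n_L - log n_S) / (2 w) )

w (the Weber fraction) is estimated per participant by maximum likelihood
over the four ratio conditions' binomial error counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfc

from .io import RATIOS, ConditionData

__all__ = ["WeberFit", "weber_error_rate", "fit_weber"]

#: Search bounds for w; generously brackets the empirically plausible range.
W_BOUNDS = (0.01, 2.0)


def weber_error_rate(w: float, n_L: int, n_S: int):
    """Predicted error rate for comparing n_L > n_S dots at Weber fraction w.

    Vectorized over ``w``.  Natural logarithms throughout.
    """
    if np.any(np.asarray(w) <= 0):
        raise ValueError("w must be > 0")
    if not n_L > n_S >= 1:
        raise ValueError(f"need n_L > n_S >= 1, got {n_L}, {n_S}")
    delta = math.log(n_L) - math.log(n_S)
    out = 0.5 * erfc(delta / (2.0 * np.asarray(w, dtype=float)))
    return float(out) if np.isscalar(w) else out


@dataclass
class WeberFit:
    """Maximum-likelihood Weber fraction for one participant.

    ``objective_value`` is the negative log-likelihood at the optimum.
    ``at_bound`` flags estimates pinned at the search bounds ("lower" for
    ceiling performers with no errors, "upper" for chance performers).
    """

    w: float
    predicted_error_rates: dict[tuple[int, int], float]
    objective_value: float
    at_bound: str | None = None

    @property
    def log_w(self) -> float:
        return math.log(self.w)


def _nll(w: float, counts: list[tuple[float, int, int]]) -> float:
    # counts: (log-ratio delta, n_error, n_correct) per condition
    total = 0.0
    for delta, n_err, n_cor in counts:
        p = 0.5 * erfc(delta / (2.0 * w))
        p = min(max(p, 1e-12), 1 - 1e-12)
        total -= n_err * math.log(p) + n_cor * math.log(1.0 - p)
    return total


def fit_weber(
    conditions: dict[tuple[int, int], ConditionData],
    bounds: tuple[float, float] = W_BOUNDS,
) -> WeberFit:
    """Estimate w from the four ratio conditions' error counts.

    Maximizes the product of binomial likelihoods of the observed error
    counts under :func:`weber_error_rate`, by bounded scalar minimization
    of the negative log-likelihood over ``bounds``.
    """
    counts = []
    for ratio, cond in conditions.items():
        if cond.n_total == 0:
            continue
        delta = math.log(ratio[0]) - math.log(ratio[1])
        counts.append((delta, cond.n_error, cond.n_correct))
    if not counts:
        raise ValueError("no trials in any condition")

    res = minimize_scalar(
        _nll, args=(counts,), bounds=bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    w = float(res.x)
    at_bound = None
    span = bounds[1] - bounds[0]
    if w - bounds[0] < 1e-3 * span:
        w, at_bound = bounds[0], "lower"
        warnings.warn("w pinned at lower bound (ceiling performance)", stacklevel=2)
    elif bounds[1] - w < 1e-3 * span:
        w, at_bound = bounds[1], "upper"
        warnings.warn("w pinned at upper bound (chance performance)", stacklevel=2)
    predicted = {r: weber_error_rate(w, *r) for r in RATIOS}
    return WeberFit(
        w=w,
        predicted_error_rates=predicted,
        objective_value=_nll(w, counts),
        at_bound=at_bound,
    )
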