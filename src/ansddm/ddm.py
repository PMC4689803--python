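"""Wiener diffusion predictions under the log-ratio drift constraint.

The decision process is a Wiener diffusion between absorbing boundaries 0
and ``a`` starting at ``z`` (fixed at a/2), with within-trial diffusion
coefficient ``s`` (gauge convention 0.1).  The mean drift toward the
correct boundary in a ratio condition is

    v = v_S * (log n_L - log n_S)        (natural log),

with a single drift scale ``v_S`` shared across ratios.  Across trials the
drift is Normal(v, eta), the starting point Uniform(z +/- s_Z/2) and the
non-decision time Uniform(T_ER +/- s_T/2); a proportion ``p_O`` of trials
is delayed by a contaminant process with uniform RTs over a window (the
contaminant leaves choice probabilities untouched).

First-passage quantities use the classical series solutions: a
reflection-image ("small-time") sum of Gaussian-CDF terms and an
eigenfunction ("large-time") sum, switching to whichever converges faster
at the requested time.  Across-trial mixtures are integrated by
tensor-product Gauss-Legendre quadrature (the Gaussian drift dimension via
probit-transformed nodes) so predictions are smooth and deterministic for
the optimizer that sits on top of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import roots_hermitenorm, roots_legendre

__all__ = [
    "DiffusionParams",
    "ConditionPrediction",
    "drift_rate",
    "absorption_prob",
    "fpt_cdf",
    "predict_condition",
]

#: Within-trial diffusion coefficient (gauge convention).
S_CONVENTION = 0.1

#: Default contaminant RT window in seconds (fast-guess floor to response window).
DEFAULT_CONTAMINANT_WINDOW = (0.25, 3.0)

_SERIES_TOL = 1e-7
_KMAX = 100_000


class SeriesConvergenceError(RuntimeError):
    """The first-passage series did not reach tolerance within the term cap."""


@dataclass
class DiffusionParams:
    """The seven free diffusion parameters plus fixed conventions.

    a : boundary separation (evidence units)
    s_Z : across-trial range of the starting point
    v_S : drift scale (evidence units per unit log-ratio)
    eta : SD of the across-trial drift distribution
    T_ER : mean non-decision time (s)
    s_T : across-trial range of non-decision time (s)
    p_O : proportion of contaminant-delayed trials

    The mean starting point ``z`` is always a/2 and the within-trial
    diffusion coefficient ``s`` is the 0.1 gauge unless overridden.
    """

    a: float
    s_Z: float
    v_S: float
    eta: float
    T_ER: float
    s_T: float
    p_O: float
    s: float = S_CONVENTION

    @property
    def z(self) -> float:
        return self.a / 2.0

    def validate(self) -> "DiffusionParams":
        if not self.a > 0:
            raise ValueError("a must be > 0")
        if not 0 <= self.s_Z < self.a:
            raise ValueError("need 0 <= s_Z < a")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if not self.T_ER > self.s_T / 2 >= 0:
            raise ValueError("need T_ER > s_T/2 >= 0")
        if not 0 <= self.p_O <= 1:
            raise ValueError("p_O must be in [0, 1]")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        return self

    def astuple(self) -> tuple[float, ...]:
        return (self.a, self.s_Z, self.v_S, self.eta, self.T_ER, self.s_T, self.p_O)


def drift_rate(v_S: float, n_L: int, n_S: int) -> float:
    """Mean drift toward the correct boundary for an n_L : n_S comparison."""
    if not n_L > n_S:
        raise ValueError(f"need n_L > n_S, got {n_L}, {n_S}")
    return v_S * (math.log(n_L) - math.log(n_S))


# ----------------------------------------------------------------------
# scalar first-passage kernels (numba)
# ----------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _p_upper(v, a, z, s):
    """Probability of absorption at the upper boundary."""
    x = 2.0 * v / (s * s)
    if abs(x * a) < 1e-9:
        return z / a
    # (1 - exp(-x z)) / (1 - exp(-x a)), stable for both drift signs
    if x * z < -690.0 or x * a < -690.0:
        # strong negative drift: ratio of huge exponentials
        return math.exp(x * (a - z)) if x * (a - z) > -745.0 else 0.0
    num = -math.expm1(-x * z)
    den = -math.expm1(-x * a)
    return num / den


@njit(cache=True)
def _exp_ndtr(b, x):
    """exp(b) * Phi(x), stable when Phi(x) underflows but the product is finite."""
    if x < -8.0:
        # log Phi(x) via the asymptotic expansion of the Mills ratio
        x2 = x * x
        lp = -0.5 * x2 - math.log(-x) - _LOG_SQRT_2PI
        lp += math.log1p(-1.0 / x2 + 3.0 / (x2 * x2))
        e = b + lp
        return math.exp(e) if e > -745.0 else 0.0
    phi = 0.5 * math.erfc(-x / _SQRT2)
    if b > 700.0:
        # product may still be representable; go through logs
        e = b + math.log(phi)
        return math.exp(e) if e < 709.0 else math.inf
    return math.exp(b) * phi


@njit(cache=True)
def _cdf_lower_small(t, v, a, z, s, tol, kmax):
    """Small-time (reflection-image) series for the lower-boundary FPT CDF."""
    s2 = s * s
    st = s * math.sqrt(t)
    total = 0.0
    k = 0
    small_runs = 0
    while k <= kmax:
        # image pair for this k: c = z + 2ka and its mirror z - 2(k+1)a
        mag = 0.0
        c1 = z + 2.0 * k * a
        c2 = z - 2.0 * (k + 1.0) * a
        for c in (c1, c2):
            b1 = (c - z) * v / s2
            b2 = -(c + z) * v / s2
            if c > 0.0:
                term = _exp_ndtr(b1, (-v * t - c) / st) + _exp_ndtr(b2, (v * t - c) / st)
            else:
                term = -_exp_ndtr(b1, (v * t + c) / st) - _exp_ndtr(b2, (-v * t + c) / st)
            total += term
            mag += abs(term)
        if mag < tol:
            small_runs += 1
            if small_runs >= 2:
                if total < 0.0:
                    total = 0.0
                return total if total < 1.0 else 1.0
        else:
            small_runs = 0
        k += 1
    return -1.0  # signal non-convergence


@njit(cache=True)
def _cdf_lower_large(t, v, a, z, s, tol, kmax):
    """Large-time (eigenfunction) series for the lower-boundary FPT CDF."""
    s2 = s * s
    p0 = 1.0 - _p_upper(v, a, z, s)
    e = -v * z / s2
    if e > 700.0:
        # prefactor overflow: fall back on the image series
        return _cdf_lower_small(t, v, a, z, s, tol, kmax)
    pref = math.pi * s2 / (a * a) * math.exp(e)
    pi_a = math.pi / a
    acc = 0.0
    k = 1
    small_runs = 0
    while k <= kmax:
        lam = 0.5 * (v * v / s2 + k * k * pi_a * pi_a * s2)
        term = k * math.sin(k * pi_a * z) / lam * math.exp(-lam * t)
        acc += term
        if pref * (abs(term) + k * math.exp(-lam * t) / lam) < tol:
            # bound includes the magnitude of the next comparable term
            small_runs += 1
            if small_runs >= 2:
                out = p0 - pref * acc
                if out < 0.0:
                    out = 0.0
                return out if out < p0 else p0
        else:
            small_runs = 0
        k += 1
    return -1.0


@njit(cache=True)
def _cdf_lower(t, v, a, z, s, tol):
    """Defective CDF of first passage through the lower boundary at time t."""
    if t <= 0.0:
        return 0.0
    # estimated term counts favour the image sum for pi*s^2*t/(2 a^2) < 1
    if math.pi * s * s * t < 2.0 * a * a:
        return _cdf_lower_small(t, v, a, z, s, tol, _KMAX)
    return _cdf_lower_large(t, v, a, z, s, tol, _KMAX)


@njit(cache=True)
def _avg_cdfs(ts, vnodes, vweights, znodes, zweights, a, s, tol):
    """Quadrature averages over drift and starting point.

    Returns (p_upper_mean, upper_cdf_at_ts, lower_cdf_at_ts) where the CDFs
    are defective decision-time CDFs averaged over the drift/start mixture.

    Uses the eigenfunction series with the drift-independent factors
    exp(-k^2 pi^2 s^2 t / (2 a^2)) precomputed once per (t, k) and shared
    across all quadrature nodes; per-node exponent overflow falls back to
    the adaptive scalar series.
    """
    n = ts.size
    up = np.zeros(n)
    lo = np.zeros(n)
    p_up_mean = 0.0
    s2 = s * s
    c0 = 0.5 * math.pi * math.pi * s2 / (a * a)  # lambda_k = c0 k^2 + v^2/(2 s^2)
    tmin = 1.0e300
    for m in range(n):
        if 0.0 < ts[m] < tmin:
            tmin = ts[m]
    if n == 0 or tmin == 1.0e300:
        for i in range(vnodes.size):
            for j in range(znodes.size):
                p_up_mean += vweights[i] * zweights[j] * _p_upper(vnodes[i], a, znodes[j], s)
        return p_up_mean, up, lo

    L = -math.log(tol) + 4.0
    K = int(math.sqrt(L / (c0 * tmin))) + 2
    if K < 4:
        K = 4
    Q = np.empty((n, K))
    for m in range(n):
        t = ts[m]
        if t > 0.0:
            for k in range(K):
                kk = k + 1.0
                q = -c0 * kk * kk * t
                Q[m, k] = math.exp(q) if q > -745.0 else 0.0

    pref0 = math.pi * s2 / (a * a)
    b_lo = np.empty(K)
    b_up = np.empty(K)
    evts = np.empty(n)
    for i in range(vnodes.size):
        v = vnodes[i]
        vv = 0.5 * v * v / s2
        for m in range(n):
            evts[m] = math.exp(-vv * ts[m]) if ts[m] > 0.0 else 0.0
        for j in range(znodes.size):
            z = znodes[j]
            w = vweights[i] * zweights[j]
            p_up = _p_upper(v, a, z, s)
            p_up_mean += w * p_up
            e_lo = -v * z / s2
            e_up = v * (a - z) / s2
            if e_lo > 690.0 or e_up > 690.0:
                # exponent overflow in the shared factorization: scalar path
                for m in range(n):
                    t = ts[m]
                    if t > 0.0:
                        cl = _cdf_lower(t, v, a, z, s, tol)
                        cu = _cdf_lower(t, -v, a, a - z, s, tol)
                        if cl < 0.0 or cu < 0.0:
                            return -1.0, up, lo
                        lo[m] += w * cl
                        up[m] += w * cu
                continue
            pref_lo = pref0 * math.exp(e_lo)
            pref_up = pref0 * math.exp(e_up)
            for k in range(K):
                kk = k + 1.0
                sk = math.sin(kk * math.pi * z / a)
                lam = c0 * kk * kk + vv
                b_lo[k] = kk * sk / lam
                # upper boundary = lower passage of the mirrored process;
                # sin(k pi (a-z)/a) = (-1)^(k+1) sin(k pi z / a)
                b_up[k] = kk * sk / lam if k % 2 == 0 else -kk * sk / lam
            for m in range(n):
                t = ts[m]
                if t <= 0.0:
                    continue
                acc_lo = 0.0
                acc_up = 0.0
                for k in range(K):
                    q = Q[m, k]
                    if q < 1e-16:
                        break
                    acc_lo += b_lo[k] * q
                    acc_up += b_up[k] * q
                evt = evts[m]
                cl = (1.0 - p_up) - pref_lo * evt * acc_lo
                cu = p_up - pref_up * evt * acc_up
                if cl < 0.0:
                    cl = 0.0
                elif cl > 1.0 - p_up:
                    cl = 1.0 - p_up
                if cu < 0.0:
                    cu = 0.0
                elif cu > p_up:
                    cu = p_up
                lo[m] += w * cl
                up[m] += w * cu
    return p_up_mean, up, lo


# ----------------------------------------------------------------------
# public scalar API
# ----------------------------------------------------------------------


def absorption_prob(v: float, a: float, z: float, s: float = S_CONVENTION) -> float:
    """Probability that the process is absorbed at the correct (upper) boundary.

    Closed form for a Wiener process with drift ``v`` and diffusion
    coefficient ``s`` between absorbing boundaries 0 and ``a``, starting at
    ``z``; continuous in ``v`` at v = 0.
    """
    if not 0 < z < a:
        raise ValueError(f"need 0 < z < a, got z={z}, a={a}")
    return float(_p_upper(float(v), float(a), float(z), float(s)))


def fpt_cdf(
    t,
    response: str,
    v: float,
    a: float,
    z: float,
    s: float = S_CONVENTION,
    tol: float = _SERIES_TOL,
):
    """Defective first-passage-time CDF for the given response boundary.

    ``response`` is "correct" (upper boundary) or "error" (lower).  As
    t -> inf the value approaches the corresponding absorption probability.
    Vectorized over ``t``.
    """
    if not 0 < z < a:
        raise ValueError(f"need 0 < z < a, got z={z}, a={a}")
    if response not in ("correct", "error"):
        raise ValueError("response must be 'correct' or 'error'")
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tarr < 0):
        raise ValueError("t must be >= 0")
    out = np.empty_like(tarr)
    for i, ti in enumerate(tarr):
        if response == "error":
            val = _cdf_lower(ti, v, a, z, s, tol)
        else:
            val = _cdf_lower(ti, -v, a, a - z, s, tol)
        if val < 0:
            raise SeriesConvergenceError(
                f"first-passage series did not converge at t={ti}"
            )
        out[i] = val
    return float(out[0]) if np.isscalar(t) else out


# ----------------------------------------------------------------------
# across-trial mixture predictions
# ----------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=64)
def _gl_nodes(n: int):
    return roots_legendre(n)


@lru_cache(maxsize=64)
def _gh_nodes(n: int):
    x, w = roots_hermitenorm(n)
    return x, w / w.sum()


def normal_quadrature(mu: float, sigma: float, n: int):
    """Gauss-Hermite (probabilists') nodes/weights for a Normal(mu, sigma) expectation.

    Hermite quadrature is exact against the Gaussian weight and converges
    spectrally for the smooth first-passage integrands; a Legendre rule on
    the same dimension converges only algebraically and cannot reach the
    refinement tolerance at practical node counts.
    """
    if sigma <= 0 or n == 1:
        return np.array([mu]), np.array([1.0])
    x, w = _gh_nodes(n)
    return mu + sigma * x, w


def uniform_quadrature(center: float, width: float, n: int):
    """Gauss-Legendre nodes/weights for a Uniform(center +/- width/2) expectation."""
    if width <= 0 or n == 1:
        return np.array([center]), np.array([1.0])
    x, w = _gl_nodes(n)
    return center + 0.5 * width * x, 0.5 * w


def _mixture_nodes(params: DiffusionParams, drift: float, n_nodes: int):
    vnodes, vw = normal_quadrature(drift, params.eta, n_nodes)
    znodes, zw = uniform_quadrature(params.z, params.s_Z, n_nodes)
    return vnodes, vw, znodes, zw


def _ter_shifted_nodes(t: float, ter_lo: float, ter_hi: float, n_nodes: int):
    """Decision-time nodes/weights for E_ter[F(t - ter)], ter ~ U(ter_lo, ter_hi).

    The integration interval is clipped at ter = t, where the decision-time
    CDF hits its (non-analytic) zero; integrating only over the support of
    the integrand restores spectral convergence of the Legendre rule.
    """
    if ter_hi <= ter_lo:  # degenerate: point mass at ter_lo
        if t <= ter_lo:
            return np.empty(0), np.empty(0)
        return np.array([t - ter_lo]), np.array([1.0])
    hi = min(t, ter_hi)
    if hi <= ter_lo:
        return np.empty(0), np.empty(0)
    x, w = _gl_nodes(n_nodes)
    nodes = 0.5 * (hi + ter_lo) + 0.5 * (hi - ter_lo) * x
    weights = 0.5 * (hi - ter_lo) / (ter_hi - ter_lo) * w
    return t - nodes, weights


def _window_overlap(t: float, lo: float, hi: float) -> float:
    """CDF at t of the uniform contaminant on (lo, hi)."""
    if t <= lo:
        return 0.0
    if t >= hi:
        return 1.0
    return (t - lo) / (hi - lo)


@dataclass
class ConditionPrediction:
    """Model predictions for one ratio condition.

    Exposes the mixture choice probability, defective RT CDFs for each
    response, RT-bin probabilities for arbitrary cut points, and RT
    quantiles; all quantities include the across-trial parameter mixture
    and the contaminant component.
    """

    ratio: tuple[int, int]
    drift: float
    params: DiffusionParams
    n_nodes: int = 11
    tol: float = _SERIES_TOL
    contaminant_window: tuple[float, float] = DEFAULT_CONTAMINANT_WINDOW
    p_correct: float = field(init=False)

    def __post_init__(self) -> None:
        self.params.validate()
        self._vn, self._vw, self._zn, self._zw = _mixture_nodes(
            self.params, self.drift, self.n_nodes
        )
        self._ter_lo = self.params.T_ER - self.params.s_T / 2.0
        self._ter_hi = self.params.T_ER + self.params.s_T / 2.0
        p_up, _, _ = _avg_cdfs(
            np.empty(0), self._vn, self._vw, self._zn, self._zw,
            self.params.a, self.params.s, self.tol,
        )
        if p_up < 0:
            raise SeriesConvergenceError("quadrature mixture did not converge")
        self.p_correct = float(p_up)

    def _ddm_cdf_both(self, tarr: np.ndarray):
        """Decision+non-decision defective CDFs (no contaminant) at each t."""
        shifted = []
        weights = []
        slices = []
        pos = 0
        for ti in tarr:
            ts, ws = _ter_shifted_nodes(ti, self._ter_lo, self._ter_hi, self.n_nodes)
            shifted.append(ts)
            weights.append(ws)
            slices.append((pos, pos + ts.size))
            pos += ts.size
        flat = np.concatenate(shifted) if shifted else np.empty(0)
        p_up, up, lo = _avg_cdfs(
            flat, self._vn, self._vw, self._zn, self._zw,
            self.params.a, self.params.s, self.tol,
        )
        if p_up < 0:
            raise SeriesConvergenceError("first-passage series did not converge")
        cdf_up = np.zeros(tarr.size)
        cdf_lo = np.zeros(tarr.size)
        for i, (b, e) in enumerate(slices):
            if e > b:
                cdf_up[i] = up[b:e] @ weights[i]
                cdf_lo[i] = lo[b:e] @ weights[i]
        return p_up, cdf_up, cdf_lo

    # -- defective CDFs ------------------------------------------------
    def cdf(self, t, response: str = "correct"):
        """Defective RT CDF (mass of response r with RT <= t), contaminants included."""
        if response not in ("correct", "error"):
            raise ValueError("response must be 'correct' or 'error'")
        tarr = np.atleast_1d(np.asarray(t, dtype=float))
        p_up, cdf_up, cdf_lo = self._ddm_cdf_both(tarr)
        ddm_cdf = cdf_up if response == "correct" else cdf_lo
        p_resp = p_up if response == "correct" else 1.0 - p_up
        lo_w, hi_w = self.contaminant_window
        contam = np.array([_window_overlap(ti, lo_w, hi_w) for ti in tarr])
        out = (1.0 - self.params.p_O) * ddm_cdf + self.params.p_O * p_resp * contam
        return float(out[0]) if np.isscalar(t) else out

    # -- bin probabilities --------------------------------------------
    def bin_probabilities(self, cuts_correct, cuts_error):
        """Joint (response, RT-bin) probabilities for given interior cut points.

        Returns (probs_correct, probs_error); ``len(cuts) + 1`` bins per
        response, summing (jointly) to 1.  Empty cut arrays give the bare
        choice probabilities.
        """
        cuts_c = np.atleast_1d(np.asarray(cuts_correct, dtype=float))
        cuts_e = np.atleast_1d(np.asarray(cuts_error, dtype=float))
        p_err = 1.0 - self.p_correct
        allcuts = np.concatenate([cuts_c, cuts_e])
        if allcuts.size:
            p_up, cdf_up, cdf_lo = self._ddm_cdf_both(allcuts)
            po = self.params.p_O
            lo_w, hi_w = self.contaminant_window
            contam = np.array([_window_overlap(ti, lo_w, hi_w) for ti in allcuts])
            mix_up = (1.0 - po) * cdf_up + po * p_up * contam
            mix_lo = (1.0 - po) * cdf_lo + po * (1.0 - p_up) * contam
            cc = mix_up[: cuts_c.size]
            ce = mix_lo[cuts_c.size:]
        else:
            cc = ce = np.empty(0)
        probs_c = np.diff(np.concatenate(([0.0], cc, [self.p_correct])))
        probs_e = np.diff(np.concatenate(([0.0], ce, [p_err])))
        return probs_c, probs_e

    # -- quantiles -----------------------------------------------------
    def quantile(self, q: float, response: str = "correct") -> float:
        """RT quantile of the conditional (response-given) RT distribution."""
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        p_resp = self.p_correct if response == "correct" else 1.0 - self.p_correct
        target = q * p_resp

        def f(t):
            return self.cdf(t, response) - target

        lo = max(1e-6, self.params.T_ER - self.params.s_T / 2.0 - 0.5)
        hi = self.params.T_ER + self.params.s_T / 2.0 + 10.0
        if self.params.p_O > 0:
            lo = min(lo, self.contaminant_window[0])
            hi = max(hi, self.contaminant_window[1] + 1.0)
        return float(brentq(f, lo, hi, xtol=1e-8))


def predict_condition(
    params: DiffusionParams,
    ratio: tuple[int, int],
    n_nodes: int = 11,
    tol: float = _SERIES_TOL,
    contaminant_window: tuple[float, float] = DEFAULT_CONTAMINANT_WINDOW,
) -> ConditionPrediction:
    """Predicted choice probability and RT distributions for one ratio.

    ``ratio`` is an (n_L, n_S) pair; the drift is the log-ratio times the
    drift scale, and eta/s_Z/s_T/p_O enter through the across-trial
    mixture (eta is shared across all ratios by construction).
    """
    drift = drift_rate(params.v_S, ratio[0], ratio[1])
    return ConditionPrediction(
        ratio=tuple(ratio), drift=drift, params=params,
        n_nodes=n_nodes, tol=tol, contaminant_window=contaminant_window,
    )
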