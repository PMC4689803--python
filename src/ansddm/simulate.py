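"""Trial-level generative model of the dot-comparison study design.

Simulates the diffusion decision process (Euler-Maruyama with a
Brownian-bridge boundary-crossing check inside each step, so absorption
probabilities are exact up to the time-grid resolution), embeds it in the
full study design (12 blocks x 64 trials, four ratios, side
counterbalancing, 2x2 stimulus-control crossing), samples participant
heterogeneity around the cohort reference values, attaches math scores
correlated with the drift scale, and provides the alternative
linear-scale/scalar-variability generator used for the RT-signature
model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .ddm import DEFAULT_CONTAMINANT_WINDOW, DiffusionParams, drift_rate
from .io import RATIOS, RESPONSE_WINDOW, TRIAL_COLUMNS

__all__ = [
    "TABLE_MEANS",
    "TABLE_SDS",
    "CohortSpec",
    "SimResult",
    "simulate_trial",
    "simulate_batch",
    "simulate_condition",
    "sample_participant_params",
    "generate_cohort",
    "generate_linear_scalar_cohort",
]

#: Cohort reference values: mean and SD of each diffusion parameter across
#: participants (young-adult dot-comparison cohort).
TABLE_MEANS = {
    "a": 0.093, "s_Z": 0.023, "v_S": 1.163, "eta": 0.167,
    "T_ER": 0.414, "s_T": 0.219, "p_O": 0.004,
}
TABLE_SDS = {
    "a": 0.023, "s_Z": 0.018, "v_S": 0.471, "eta": 0.110,
    "T_ER": 0.081, "s_T": 0.109, "p_O": 0.010,
}

_PARAM_FIELDS = ("a", "s_Z", "v_S", "eta", "T_ER", "s_T", "p_O")

#: Admissible numerosity pairs (larger, smaller) per design ratio, both
#: members within 9-21 dots.
RATIO_PAIRS = {
    (4, 3): ((12, 9), (16, 12), (20, 15)),
    (7, 6): ((14, 12), (21, 18)),
    (9, 8): ((18, 16),),
    (10, 9): ((10, 9), (20, 18)),
}

#: Floor on the sampled drift scale, matching the lower edge of plausible
#: above-chance performance.
_V_S_FLOOR = 0.1


_NBUF = 1 << 16


@njit(cache=True, fastmath=True)
def _sim_kernel(n, v_mean, eta, a, z_mean, sz, ter, st, po, s, dt,
                horizon, win_lo, win_hi, rt_cap, seed):
    """Simulate n trials; returns (responses, rts, n_resampled, n_truncated).

    Each step draws the exact Gaussian increment and then checks for a
    within-step boundary crossing with the Brownian-bridge probability
    exp(-2*d1*d2/(s^2 dt)), which removes the O(sqrt(dt)) boundary-miss
    bias of plain Euler-Maruyama.  Gaussian variates are drawn in blocks.
    """
    np.random.seed(seed)
    resp = np.empty(n, np.uint8)
    rts = np.empty(n)
    n_resampled = 0
    n_truncated = 0
    sqdt = math.sqrt(dt)
    s2dt = s * s * dt
    near = 18.0 * s2dt  # d1*d2 beyond this gives crossing prob < 2e-16
    buf = np.random.standard_normal(_NBUF)
    bi = 0
    for i in range(n):
        hit = -1
        t = 0.0
        while hit < 0:
            if bi >= _NBUF - 1:
                buf = np.random.standard_normal(_NBUF)
                bi = 0
            v = v_mean + eta * buf[bi] if eta > 0.0 else v_mean
            bi += 1
            x = z_mean + (np.random.random() - 0.5) * sz
            t = 0.0
            while t < horizon:
                if bi >= _NBUF:
                    buf = np.random.standard_normal(_NBUF)
                    bi = 0
                xn = x + v * dt + s * sqdt * buf[bi]
                bi += 1
                t += dt
                if xn >= a:
                    hit = 1
                    break
                if xn <= 0.0:
                    hit = 0
                    break
                du = (a - x) * (a - xn)
                dl = x * xn
                if du < near or dl < near:
                    pu = math.exp(-2.0 * du / s2dt) if du < near else 0.0
                    pl = math.exp(-2.0 * dl / s2dt) if dl < near else 0.0
                    u = np.random.random()
                    if u < pu:
                        hit = 1
                        break
                    if u < pu + pl:
                        hit = 0
                        break
                x = xn
            if hit < 0:
                n_resampled += 1
        rt = t + ter + (np.random.random() - 0.5) * st
        if po > 0.0 and np.random.random() < po:
            rt = win_lo + np.random.random() * (win_hi - win_lo)
        if rt > rt_cap:
            rt = rt_cap
            n_truncated += 1
        resp[i] = hit
        rts[i] = rt
    return resp, rts, n_resampled, n_truncated


@dataclass
class SimResult:
    """Simulated responses (True = correct) and RTs for one condition."""

    correct: np.ndarray
    rt: np.ndarray
    n_resampled: int = 0
    n_truncated: int = 0

    @property
    def accuracy(self) -> float:
        return float(self.correct.mean())


def _as_seed(seed_or_rng) -> int:
    if isinstance(seed_or_rng, np.random.Generator):
        return int(seed_or_rng.integers(0, 2**31 - 1))
    return int(seed_or_rng) % (2**31 - 1)


def simulate_batch(
    params: DiffusionParams,
    drift: float,
    n_trials: int,
    seed,
    dt: float = 1e-4,
    eta: float | None = None,
    horizon: float = 10.0,
    rt_cap: float = RESPONSE_WINDOW,
    contaminant_window: tuple[float, float] = DEFAULT_CONTAMINANT_WINDOW,
) -> SimResult:
    """Simulate ``n_trials`` at a given mean drift.

    ``eta`` overrides ``params.eta`` (used by the scalar-variability
    generator, whose drift variability depends on the stimulus pair).
    Trials that fail to reach a boundary within ``horizon`` seconds are
    resampled and counted; RTs beyond the response window are truncated at
    it and counted.
    """
    params.validate()
    resp, rts, n_res, n_trunc = _sim_kernel(
        int(n_trials), float(drift),
        float(params.eta if eta is None else eta),
        params.a, params.z, params.s_Z, params.T_ER, params.s_T, params.p_O,
        params.s, dt, horizon, contaminant_window[0], contaminant_window[1],
        rt_cap, _as_seed(seed),
    )
    return SimResult(correct=resp.astype(bool), rt=rts,
                     n_resampled=int(n_res), n_truncated=int(n_trunc))


def simulate_trial(params: DiffusionParams, drift: float, rng) -> tuple[str, float]:
    """One trial; returns ('correct'|'error', rt in seconds)."""
    out = simulate_batch(params, drift, 1, rng)
    return ("correct" if out.correct[0] else "error", float(out.rt[0]))


def simulate_condition(
    params: DiffusionParams, n_L: int, n_S: int, n_trials: int, seed, **kwargs
) -> SimResult:
    """Simulate one ratio condition under the log-scale drift constraint."""
    return simulate_batch(params, drift_rate(params.v_S, n_L, n_S), n_trials, seed, **kwargs)


@dataclass
class CohortSpec:
    """Study-design and heterogeneity specification for a synthetic cohort.

    Participant-level parameters are independent Gaussians with the given
    means/SDs, resampled until the parameter-set invariants hold (an
    optional covariance matrix over the 7 fields replaces independence for
    sensitivity studies).  Math scores are linear in the standardized true
    drift scale with target correlation ``math_rho`` plus Gaussian noise,
    rounded to a nonnegative integer problem count.
    """

    n_participants: int = 20
    param_means: dict = field(default_factory=lambda: dict(TABLE_MEANS))
    param_sds: dict = field(default_factory=lambda: dict(TABLE_SDS))
    param_cov: np.ndarray | None = None
    math_rho: float = 0.3
    math_mean: float = 40.0
    math_sd: float = 10.0
    blocks: int = 12
    trials_per_block: int = 64
    dt: float = 1e-4
    contaminant_window: tuple[float, float] = DEFAULT_CONTAMINANT_WINDOW

    def validate(self) -> "CohortSpec":
        if not abs(self.math_rho) < 1:
            raise ValueError(f"math_rho must satisfy |rho| < 1, got {self.math_rho}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_block % 64:
            raise ValueError("trials_per_block must be a multiple of 64 (4 ratios x 2 sides x 2x2 controls x reps)")
        return self


def sample_participant_params(spec: CohortSpec, rng: np.random.Generator) -> DiffusionParams:
    """Draw one participant's parameter set, resampling until valid."""
    means = np.array([spec.param_means[f] for f in _PARAM_FIELDS])
    if spec.param_cov is not None:
        draw = lambda: rng.multivariate_normal(means, spec.param_cov)
    else:
        sds = np.array([spec.param_sds[f] for f in _PARAM_FIELDS])
        draw = lambda: rng.normal(means, sds)
    for _ in range(10_000):
        vals = dict(zip(_PARAM_FIELDS, draw()))
        p = DiffusionParams(**vals)
        try:
            p.validate()
        except ValueError:
            continue
        if p.v_S < _V_S_FLOOR:
            continue
        return p
    raise RuntimeError("could not draw a valid parameter set in 10,000 attempts")


def _block_design(ratio_order_rng: np.random.Generator, blocks: int, trials_per_block: int):
    """Balanced per-block trial list: (ratio, larger_side, area, field)."""
    reps = trials_per_block // 64
    cells = [
        (ratio, side, ac, fc)
        for ratio in RATIOS
        for side in ("left", "right")
        for ac in (0, 1)
        for fc in (0, 1)
        for _ in range(2 * reps)
    ]
    design = []
    for b in range(1, blocks + 1):
        order = ratio_order_rng.permutation(len(cells))
        design.extend((b, i + 1) + cells[j] for i, j in enumerate(order))
    return design  # rows: (block, trial, ratio, side, area, field)


def _math_scores(v_s: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    sd = v_s.std()
    zv = (v_s - v_s.mean()) / sd if sd > 0 else np.zeros_like(v_s)
    latent = spec.math_rho * zv + math.sqrt(1 - spec.math_rho**2) * rng.standard_normal(v_s.size)
    return np.maximum(0, np.round(spec.math_mean + spec.math_sd * latent)).astype(int)


def _assemble_trials(pid, design, pair_choice, correct, rts):
    rows = []
    for (block, trial, ratio, side, ac, fc), pair, ok, rt in zip(
        design, pair_choice, correct, rts
    ):
        n_larger, n_smaller = pair
        if side == "left":
            n_left, n_right = n_larger, n_smaller
        else:
            n_left, n_right = n_smaller, n_larger
        response = side if ok else ("right" if side == "left" else "left")
        rows.append((pid, block, trial, n_left, n_right, response, rt, ac, fc))
    return rows


def generate_cohort(spec: CohortSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort's trial table and ground-truth table.

    Returns ``(trials, truth)``: ``trials`` in the canonical trial-CSV
    layout; ``truth`` holds each participant's generating parameters, math
    score, and realized accuracy/mean RT for recovery studies.
    Reproducible: identical seeds give identical frames.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    truth_rows = []
    all_rows = []
    params_list = [sample_participant_params(spec, rng) for _ in range(spec.n_participants)]
    v_s = np.array([p.v_S for p in params_list])
    math_scores = _math_scores(v_s, spec, rng)

    for idx, params in enumerate(params_list):
        pid = f"P{idx + 1:03d}"
        design = _block_design(rng, spec.blocks, spec.trials_per_block)
        pairs = [RATIO_PAIRS[d[2]][rng.integers(len(RATIO_PAIRS[d[2]]))] for d in design]
        n = len(design)
        correct = np.empty(n, dtype=bool)
        rts = np.empty(n)
        for ratio in RATIOS:
            sel = [i for i, d in enumerate(design) if d[2] == ratio]
            out = simulate_condition(
                params, ratio[0], ratio[1], len(sel), rng,
                dt=spec.dt, contaminant_window=spec.contaminant_window,
            )
            correct[sel] = out.correct
            rts[sel] = out.rt
        all_rows.extend(_assemble_trials(pid, design, pairs, correct, rts))
        truth_rows.append({
            "participant_id": pid,
            **{f: getattr(params, f) for f in _PARAM_FIELDS},
            "math": int(math_scores[idx]),
            "accuracy": float(correct.mean()),
            "mean_rt": float(rts.mean()),
        })
    trials = pd.DataFrame(all_rows, columns=list(TRIAL_COLUMNS))
    return trials, pd.DataFrame(truth_rows)


def generate_linear_scalar_cohort(
    spec: CohortSpec,
    v0: float = 0.2,
    variability_slope: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Contrast generator: linear-scale representation with scalar variability.

    The mean drift is held constant at ``v0`` for every numerosity pair
    while the across-trial drift SD grows with the total number of items,
    eta = variability_slope * (n_L + n_S).  Accuracy then falls with
    display size, but — unlike the log-scale generator — mean RT gets
    *faster*, which is the diagnostic signature separating the two models.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    all_rows = []
    for idx in range(spec.n_participants):
        base = sample_participant_params(spec, rng)
        pid = f"L{idx + 1:03d}"
        design = _block_design(rng, spec.blocks, spec.trials_per_block)
        pairs = [RATIO_PAIRS[d[2]][rng.integers(len(RATIO_PAIRS[d[2]]))] for d in design]
        n = len(design)
        correct = np.empty(n, dtype=bool)
        rts = np.empty(n)
        for pair in {tuple(p) for p in pairs}:
            sel = [i for i, p in enumerate(pairs) if tuple(p) == pair]
            eta_pair = variability_slope * (pair[0] + pair[1])
            out = simulate_batch(
                base, v0, len(sel), rng, dt=spec.dt, eta=eta_pair,
                contaminant_window=spec.contaminant_window,
            )
            correct[sel] = out.correct
            rts[sel] = out.rt
        all_rows.extend(_assemble_trials(pid, design, pairs, correct, rts))
    return pd.DataFrame(all_rows, columns=list(TRIAL_COLUMNS))
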