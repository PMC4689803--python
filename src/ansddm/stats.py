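"""Cohort-level statistics for acuity estimates.

Reliability (split-half with Spearman-Brown correction), dependent
correlations (Steiger's z), regression of math scores on acuity measures,
inverse efficiency, reliability/validity curves over trial subsets, and
the half-cohort resampling analysis that asks whether the drift scale
out-predicts the Weber fraction even in subsamples where accuracy and RT
are uncorrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .chi2fit import FitConfig, fit_participant
from .io import TrialRecord, collapse_conditions
from .weber import fit_weber

__all__ = [
    "pearson",
    "split_half_reliability",
    "steiger_test",
    "regression_math",
    "inverse_efficiency",
    "subset_reliability_curve",
    "half_cohort_resampling",
    "ResamplingResult",
]

SUBSET_SIZES = (128, 256, 384, 512, 640, 768)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need paired vectors of length >= 3")
    r = float(np.corrcoef(x, y)[0, 1])
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * math.sqrt((n - 2) / (1 - r_ * r_))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, float(p)


def split_half_reliability(estimates_even, estimates_odd) -> float:
    """Spearman-Brown-corrected split-half reliability, 2r/(1+r).

    ``estimates_even``/``estimates_odd`` are one estimate per participant
    from even and odd blocks respectively.
    """
    x = np.asarray(estimates_even, dtype=float)
    y = np.asarray(estimates_odd, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one half; reliability undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return 2 * r / (1 + r)


def steiger_test(r_xy: float, r_xz: float, r_yz: float, n: int) -> tuple[float, float]:
    """Test for the difference between two dependent correlations.

    Compares r_xy with r_xz (sharing variable x), accounting for r_yz,
    using the Fisher-transformed z statistic of Steiger (1980).  Returns
    (z, two-sided p).
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1 < r < 1:
            raise ValueError("correlations must be in (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    cmat = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1]])
    if np.linalg.eigvalsh(cmat)[0] < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    z_xy = math.atanh(r_xy)
    z_xz = math.atanh(r_xz)
    rbar = 0.5 * (r_xy + r_xz)
    rb2 = rbar * rbar
    psi = r_yz * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_yz * r_yz)
    sbar = psi / (1 - rb2) ** 2
    z = (z_xy - z_xz) * math.sqrt((n - 3) / (2 - 2 * sbar))
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def regression_math(table: pd.DataFrame, predictors: list[str],
                    outcome: str = "math") -> pd.DataFrame:
    """OLS of the math score on the named predictors.

    Returns a frame with one row per term (including the intercept) with
    coefficient, t and p, plus the model R^2 in ``.attrs["r_squared"]``.
    Raises on rank-deficient (collinear) design matrices.
    """
    data = table[[outcome] + list(predictors)].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError("too few complete cases")
    X = sm.add_constant(data[list(predictors)].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear predictors)")
    fit = sm.OLS(data[outcome].to_numpy(dtype=float), X).fit()
    out = pd.DataFrame({
        "term": ["const"] + list(predictors),
        "coef": fit.params,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    out.attrs["r_squared"] = float(fit.rsquared)
    return out


def inverse_efficiency(mean_rt: float, accuracy: float) -> float:
    """Mean RT divided by proportion correct (seconds)."""
    if not accuracy > 0:
        raise ValueError("accuracy must be > 0")
    return mean_rt / accuracy


# ----------------------------------------------------------------------
# trial-subset curves
# ----------------------------------------------------------------------


def _fit_estimate(trials: list[TrialRecord], estimator: str,
                  ddm_config: FitConfig | None):
    conds = collapse_conditions(trials)
    if estimator == "weber":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return math.log(fit_weber(conds).w)
    if estimator == "ddm":
        return fit_participant(conds, ddm_config).params.v_S
    raise ValueError(f"unknown estimator {estimator!r}")


def subset_reliability_curve(
    cohort: dict[str, list[TrialRecord]],
    math_scores: dict[str, float] | None = None,
    sizes: tuple[int, ...] = SUBSET_SIZES,
    estimators: tuple[str, ...] = ("weber", "ddm"),
    ddm_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Reliability and math-correlation of each estimator vs trials used.

    For each subset size k, each participant's first k trials (presentation
    order) are fitted in full and separately for even and odd blocks; the
    rows report the Spearman-Brown-corrected even/odd reliability and, when
    math scores are given, the correlation of the full-subset estimate with
    math (log w for the Weber model, v_S for the diffusion model).
    Subsets too small to fit are skipped with a warning.
    """
    import warnings

    rows = []
    pids = sorted(cohort)
    for size in sizes:
        for est in estimators:
            full, even, odd = [], [], []
            ok = True
            for pid in pids:
                trials = sorted(cohort[pid], key=lambda t: (t.block, t.trial))[:size]
                ev = [t for t in trials if t.block % 2 == 0]
                od = [t for t in trials if t.block % 2 == 1]
                try:
                    full.append(_fit_estimate(trials, est, ddm_config))
                    even.append(_fit_estimate(ev, est, ddm_config))
                    odd.append(_fit_estimate(od, est, ddm_config))
                except ValueError as exc:
                    warnings.warn(f"size {size}, {est}, {pid}: skipped ({exc})")
                    ok = False
                    break
            if not ok:
                continue
            rel = split_half_reliability(even, odd)
            row = {"size": size, "estimator": est, "reliability": rel}
            if math_scores is not None:
                scores = [math_scores[p] for p in pids]
                row["r_math"], row["p_math"] = pearson(full, scores)
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# half-cohort resampling
# ----------------------------------------------------------------------


@dataclass
class ResamplingResult:
    """Outcome of the half-cohort resampling analysis.

    Among ``n_nonsignificant`` subsamples whose accuracy-RT correlation is
    not significant, ``fraction_vs_wins`` is the share where the drift
    scale's math correlation exceeds (in magnitude) the Weber fraction's
    (the w-math correlation is computed on the raw w scale).
    """

    reps: int
    subset_n: int
    n_nonsignificant: int
    n_vs_wins: int

    @property
    def fraction_vs_wins(self) -> float:
        return self.n_vs_wins / self.n_nonsignificant if self.n_nonsignificant else float("nan")


def half_cohort_resampling(
    table: pd.DataFrame,
    reps: int = 100_000,
    subset_n: int = 55,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ResamplingResult:
    """Half-cohort resampling of the drift-scale vs Weber-fraction contrast.

    In each repetition, ``subset_n`` participants are drawn without
    replacement; if their accuracy-RT correlation is non-significant
    (p > alpha), the magnitudes of r(v_S, math) and r(w, math) are
    compared.  Rows are sorted by participant id internally, and each draw
    is seeded by (seed, draw index), so results do not depend on input row
    order.
    """
    required = ["participant_id", "accuracy", "mean_rt", "v_S", "w", "math"]
    missing = set(required) - set(table.columns)
    if missing:
        raise ValueError(f"table missing column(s): {sorted(missing)}")
    if subset_n > len(table):
        raise ValueError("subset_n exceeds cohort size")
    tab = table.sort_values("participant_id").reset_index(drop=True)
    cols = tab[["accuracy", "mean_rt", "v_S", "w", "math"]].to_numpy(dtype=float)
    n_nonsig = 0
    n_wins = 0
    tdist_df = subset_n - 2
    for i in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence((0 if seed is None else seed, i)))
        idx = rng.choice(len(tab), size=subset_n, replace=False)
        sub = cols[idx]
        c = np.corrcoef(sub, rowvar=False)
        r_acc_rt = c[0, 1]
        t = abs(r_acc_rt) * math.sqrt(tdist_df / max(1 - r_acc_rt**2, 1e-15))
        p = 2 * sps.t.sf(t, tdist_df)
        if p > alpha:
            n_nonsig += 1
            if abs(c[2, 4]) > abs(c[3, 4]):  # |r(v_S, math)| vs |r(w, math)|
                n_wins += 1
    return ResamplingResult(reps=reps, subset_n=subset_n,
                            n_nonsignificant=n_nonsig, n_vs_wins=n_wins)


# ----------------------------------------------------------------------
# cohort assembly
# ----------------------------------------------------------------------


@dataclass
class CohortResult:
    """Per-participant estimates plus the named cohort statistics."""

    participants: pd.DataFrame
    statistics: pd.DataFrame
    resampling: ResamplingResult | None = None


def analyze_cohort(
    participants: pd.DataFrame,
    resample_reps: int = 10_000,
    resample_subset: int | None = None,
    seed: int = 0,
) -> CohortResult:
    """Standard battery of cohort statistics from a per-participant table.

    Expects columns participant_id, w, log_w, v_S, a, accuracy, mean_rt and
    optionally math.  Computes the named correlations, Steiger's test of
    the two math correlations, the two regressions (v_S controlling log w;
    v_S controlling inverse efficiency), and the half-cohort resampling
    summary (subset defaulting to half the cohort).
    """
    tab = participants.copy()
    tab["log_a"] = np.log(tab["a"])
    tab["ies"] = tab["mean_rt"] / tab["accuracy"]
    has_math = "math" in tab.columns and tab["math"].notna().all()
    stats_rows = []

    def add_corr(name, xcol, ycol):
        r, p = pearson(tab[xcol], tab[ycol])
        stats_rows.append({"statistic": f"r({name})", "value": r, "p": p})
        return r

    add_corr("accuracy, mean_rt", "accuracy", "mean_rt")
    add_corr("log_w, accuracy", "log_w", "accuracy")
    add_corr("log_w, mean_rt", "log_w", "mean_rt")
    add_corr("v_S, accuracy", "v_S", "accuracy")
    add_corr("v_S, mean_rt", "v_S", "mean_rt")
    add_corr("log_w, log_a", "log_w", "log_a")
    resampling = None
    if has_math:
        r_vm = add_corr("v_S, math", "v_S", "math")
        r_wm = add_corr("log_w, math", "log_w", "math")
        add_corr("ies, math", "ies", "math")
        r_vw, _ = pearson(tab["v_S"], tab["log_w"])
        z, p = steiger_test(r_vm, r_wm, r_vw, len(tab))
        stats_rows.append({"statistic": "steiger_z(v_S-math vs log_w-math)", "value": z, "p": p})
        for preds in (["v_S", "log_w"], ["v_S", "ies"]):
            reg = regression_math(tab, preds)
            row = reg[reg.term == "v_S"].iloc[0]
            stats_rows.append({
                "statistic": f"t(v_S | {preds[1]})", "value": float(row.t), "p": float(row.p),
            })
        if resample_reps > 0:
            resampling = half_cohort_resampling(
                tab, reps=resample_reps,
                subset_n=resample_subset or max(4, len(tab) // 2),
                seed=seed,
            )
            stats_rows.append({
                "statistic": "resampling fraction |r(v_S,math)| > |r(w,math)|",
                "value": resampling.fraction_vs_wins,
                "p": float("nan"),
            })
    return CohortResult(
        participants=tab,
        statistics=pd.DataFrame(stats_rows),
        resampling=resampling,
    )
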