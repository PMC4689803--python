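# Methods

## Models

**Weber-fraction model.** Numerosity n is represented on a logarithmic
mental number line with constant noise. For a comparison of n_L > n_S the
decision variable is Gaussian with mean Δ = ln n_L − ln n_S and SD √2·w,
so P(error) = ½·erfc(Δ/(2w)). Per participant, w is estimated by maximum
likelihood over the four ratio conditions' binomial error counts, by
bounded scalar minimization on w ∈ [0.01, 2] (bracketing the plausible
empirical range ~0.08–0.4 with wide margin). All-correct data pin w at the
lower bound, chance data at the upper bound; both cases are flagged. The
likelihood reading of "fit the accuracy data" is the statistically
standard one and coincides with least squares at balanced designs.

**Diffusion model.** Within a trial, evidence X(t) follows a Wiener
process with drift v and diffusion coefficient s between absorbing
boundaries 0 and a, starting at z = a/2; s = 0.1 is a pure gauge
convention (model predictions are invariant under common scaling of
a, z, s_Z, v, η and s — a property test asserts this). The drift toward
the correct boundary in ratio condition L:S is v = v_S·(ln n_L − ln n_S)
with one participant-level drift scale v_S; natural logs (the published
worked example, drift scale 1.16 → drifts 0.33/0.18/0.14/0.12, reproduces
only under natural log). Across trials, drift is Normal(v, η) with η
shared across ratios, the start point Uniform(z ± s_Z/2), the non-decision
time Uniform(T_ER ± s_T/2). A proportion p_O of trials is *delayed* by a
contaminant process: RT uniform over a window, choice probabilities
untouched. The window defaults to (0.25 s, 3 s) and, during fitting, to
the condition's observed RT range; the literature leaves both the
contaminant distribution and the response rule of contaminants open, and
the delay-only reading keeps accuracy interpretable.

## First-passage numerics

Two classical series give the defective first-passage CDF through a
boundary: a reflection-image sum of Gaussian-CDF terms (efficient at small
t·s²/a²) and an eigenfunction sum with rates λ_k = (v²/s² + k²π²s²/a²)/2
(efficient at large t). Both are truncated adaptively to an absolute 1e-7
tolerance; the scalar API switches branches by comparing estimated term
counts (crossover at πs²t = 2a²), and a property test checks the branches
agree to 1e-6 across a (t, v, z) grid. Exponent overflow in the image
terms is handled by evaluating exp(b)·Φ(x) through log-space with an
asymptotic Mills-ratio expansion for x < −8.

For the across-trial mixture, the batch kernel shares the
drift-independent factors exp(−k²π²s²t/(2a²)) across all quadrature nodes
and time points, with per-time early termination; nodes with overflowing
prefactors fall back to the adaptive scalar series.

## Quadrature over across-trial parameters

Predictions integrate the first-passage quantities over drift, start
point and non-decision time with 11 nodes per dimension by default:

- drift ~ Normal: **Gauss–Hermite** (probabilists') nodes. Hermite
  quadrature is exact against the Gaussian weight and converges
  spectrally here; a Legendre rule on this dimension (truncated interval
  or probit-transformed) converges only algebraically and still has ~3e-5
  error at 31 nodes, which would violate the refinement tolerance below.
- start point ~ Uniform: Gauss–Legendre on the interval (the integrand is
  nearly linear in z; error is at machine level).
- non-decision time ~ Uniform: Gauss–Legendre on the **clipped** interval
  ter ∈ [ter_lo, min(t, ter_hi)]. The integrand F(t − ter) vanishes
  non-analytically where t − ter crosses zero; clipping the integration
  interval at that point restores spectral convergence (unclipped error
  ~2.4e-4 at 11 nodes; clipped ~1e-6).

With these rules, doubling all node counts moves any predicted bin
probability by < 1e-5 at the cohort reference parameters (asserted in the
suite). The deterministic tensor-product construction keeps the χ²
objective smooth for the simplex optimizer.

## χ² quantile estimation

Per ratio condition and response type: ≥ 9 observations → six bins cut at
the empirical 0.1/0.3/0.5/0.7/0.9 RT quantiles (linear-interpolation
quantile convention; bin edges move by a few ms across conventions, so
the convention is fixed here and used consistently); 2–8 observations
(inclusive) → two bins split at the median (observations equal to the
median fall in the lower bin); < 2 → a single count-only bin. The
objective is Σ(O − E)²/E with E = N_condition × model probability,
floored at 1e-4 to keep the search finite at extreme parameters. Degrees
of freedom: per condition, number of observed frequencies − 1 (12 − 1 =
11 when fully populated; 44 over four conditions).

Seven parameters (a, s_Z, v_S, η, T_ER, s_T, p_O) are estimated by
Nelder–Mead (adaptive simplex) on a sigmoid-transformed box:

| parameter | box | note |
| --- | --- | --- |
| a | 0.02–0.5 | s = 0.1 gauge |
| s_Z | (0–0.98)·a | keeps s_Z < a |
| v_S | 0–5 | several SD beyond the plausible cohort range |
| η | 0–0.45 | see below |
| T_ER | 0.05–1.5 s | |
| s_T | (0–0.95)·2(T_ER − 0.025) | keeps T_ER − s_T/2 > 0.025 s |
| p_O | 0–0.1 | contaminants are rare by construction |

The first start is a heuristic: T_ER at the 5 % RT quantile, a small
grid over (a, v_S) scored by the objective; further restarts jitter the
transformed start (seeded, so fits are bit-reproducible). The best
restart is returned.

**The η box matters.** A single 768-trial session leaves a near-flat χ²
ridge along which v_S and η inflate together (all four accuracies stay
nearly constant when both grow in proportion, and sparse error-RT bins
barely discriminate). Unconstrained fits occasionally wander to η of
0.5–0.9 in the 0.1 gauge — far beyond values reported in applied work —
carrying v_S with them and adding large cross-participant noise.
Restricting η to [0, 0.45] (the cohort reference mean 0.167 + ~2.5 SD)
acts as the tie-break on ridge-flat data while leaving well-identified
data untouched: with 20,000 trials per condition the fit recovers the
generating values nearly exactly (the consistency test asserts v_S within
0.1, a within 0.005, η within 0.06, T_ER within 0.01 of truth). At 768
trials the estimator retains a known small-sample behavior of χ² quantile
fitting — a modest joint upward drift of v_S and η and appreciable
cross-participant spread — but the *ordering* of participants is
preserved (the recovery test asserts cross-participant correlations
≥ 0.8 for v_S and a, with cross-correlations below 0.3), which is what
the cohort-level analyses rely on.

## Simulator

Trials are simulated by Euler–Maruyama with step dt = 1e-4 s
(configurable), augmented with a Brownian-bridge crossing check inside
each step: after the exact Gaussian increment, the bridge probability
exp(−2·d₁·d₂/(s²dt)) of having touched each boundary within the step is
evaluated (skipped when the product of distances makes it < 2e-16). This
removes the O(√dt) boundary-miss bias of plain Euler–Maruyama — which at
this parameter scale (~1.6e-3 in P(correct)) would otherwise dominate
Monte-Carlo error at 10⁶ trials — leaving only an O(dt) time-grid bias.
Accuracy and RT quantiles of 10⁶-trial simulations agree with the
quadrature predictions within 3 Monte-Carlo SE (asserted in the suite),
which cross-validates two fully independent computational routes.
Non-crossing trials (10 s horizon) are resampled and counted; RTs beyond
the 3 s response window are truncated to it and counted.

The cohort generator reproduces the study design: 12 blocks × 64 trials;
each block balances 4 ratios × 2 sides × 2 surface-area controls × 2
field controls; numerosity pairs are drawn uniformly from the admissible
9–21 integer pairs per ratio (exact pair frequencies are not constrained
by the design description, so uniform is the neutral choice). Participant
parameters are independent truncated Gaussians with the cohort reference
means/SDs (a: 0.093 ± 0.023, s_Z: 0.023 ± 0.018, v_S: 1.163 ± 0.471,
η: 0.167 ± 0.110, T_ER: 0.414 ± 0.081, s_T: 0.219 ± 0.109, p_O:
0.004 ± 0.010), resampled until the parameter invariants hold and
v_S ≥ 0.1 (the lower edge of above-chance performance); an optional
covariance matrix replaces independence for sensitivity studies. Math
scores emulate a timed arithmetic task: problems-solved counts with mean
40, SD 10 (a realistic 7-minute throughput), generated as ρ·z(v_S) +
√(1−ρ²)·noise with ρ = 0.3 by default, rounded and floored at zero —
the weakest structure sufficient to exercise the correlation analyses.

The contrast generator implements the linear-scale/scalar-variability
account: mean drift held constant (v₀ = 0.2) while the across-trial drift
SD grows with display size, η = 0.005·(n_L + n_S). These defaults put
accuracy on the matched-difference diagnostic pairs (12:9 vs 21:18,
14:12 vs 20:18) in the observed range while producing the account's
signature: accuracy falls *and mean RT gets faster* with more items,
the opposite RT direction from the log-scale model.

## Cohort statistics

Split-half reliability uses even/odd *blocks* and the Spearman–Brown
correction 2r/(1+r). Steiger's (1980) z compares the two dependent math
correlations sharing the math variable; the implementation is calibrated
against a Monte-Carlo null (type-I error ≈ 0.05 asserted in the suite).
Regressions are OLS with per-coefficient t tests; p-values are two-sided
throughout and no multiple-testing correction is applied. Inverse
efficiency is mean RT / proportion correct. Trial-subset curves take the
first k trials in presentation order (k ∈ {128, …, 768}) and refit both
estimators per subset. The half-cohort resampling draws subsets without
replacement, screens for a non-significant accuracy–RT correlation
(computed on all trials, not correct-only), and then compares
|r(v_S, math)| with |r(w, math)| — the raw Weber fraction, not its log,
matching the original analysis; each draw is seeded by (seed, draw
index) and participants are sorted by id first, so results are invariant
to row order.

## What the synthetic validation does and does not show

The generator emulates the study's design, parameter heterogeneity and a
linear acuity→math link. Passing tests therefore show: the analytic
machinery is correct (independent simulation oracle), the estimators are
consistent, recovery and selective influence hold at realistic session
lengths, and the full pipeline reproduces the qualitative signatures
(w–accuracy coupling near −1, RT-direction model diagnostic, drift scale
out-predicting w in accuracy–RT-null subsamples).

They do not show that real data behave this way. In particular, the
synthetic world is cleaner than a real cohort: with math scores generated
from the true drift scale alone and every accuracy difference traceable
to the seven parameters, overall accuracy is a much better proxy for true
acuity than it is empirically — real participants carry extra accuracy
variance (strategy, attention, non-numerical stimulus cues) that no
parameter of this generator models.
Consequently the margin by which the drift scale out-predicts w on math
is structurally narrower in simulation than in the published data, and
against log-transformed w (a nearly linear re-expression of accuracy) the
contest is close to a tie at these conditions. Non-numerical cue effects
on drift are deliberately out of scope; the control flags are carried
through the formats but do not influence the generative process.

## Problem sizes used in validation

Unit and acceptance tests run at: 10⁶ trials per condition for the
analytic-vs-simulation equivalence; 20 participants × 768 trials for
recovery/selective influence (single heuristic-start fit per participant
— restarts beyond it only wander along the flat ridge); 110 participants
for the resampling pipeline (10,000 repetitions, subsets of 55); 20,000
trials per condition for the large-sample consistency oracle. These sizes
were chosen to make Monte-Carlo bands decisive while keeping the full
suite convenient to run.
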