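# Methods and design notes

## The measurement chain

A split-belt session has three phases — Baseline (belts tied), Adaptation
(belts split 2:1, default 450 strides), De-adaptation (belts tied again,
default 450 strides) — with step-length visual feedback on during the first
40 Adaptation strides. Step length asymmetry on stride *s* is

    sla[s] = 100 · (fast[s] − slow[s]) / (fast[s] + slow[s])   [%]

baseline-corrected by subtracting the participant's mean Baseline value.
The per-phase **Adaptation Index** rescales asymmetry so that learning is
comparable across participants with different perturbation sizes:

    AI[s] = (sla[s] − condition·perturbation) / |perturbation|

with `condition = 1` while the belts are split and 0 otherwise, and
`perturbation` the most negative asymmetry over the first 10 retained
Adaptation strides (resp. the most positive over the first 10 retained
De-adaptation strides). During Adaptation, AI runs from 0 (full
perturbation) to 1 (full correction); during De-adaptation from 1 (peak
aftereffect) to 0 (washed out).

### Cleaning rules and their order

Strides outside a Tukey-style fence at `[Q1 − 3·IQR, Q3 + 3·IQR]` of the
participant's full asymmetry series are removed, and the first stride of
every phase is dropped (treadmill acceleration). The pipeline estimates the
per-phase perturbation **after outlier removal but before the first-stride
drop**. The ordering matters: the learning models start at zero output on
the first Adaptation stride, so that stride carries the full perturbation.
Estimating the perturbation with the first stride still present anchors the
index to the true perturbation scale and makes the synthetic generator and
the index computation exact inverses; dropping it first would rescale every
index value by the amount already learned within the estimation window. On
real data the first stride is acceleration-contaminated and the two orders
differ by a few percent of scale; on simulated (acceleration-free) strides
the chosen order is exact.

### An intrinsic normalization asymmetry

During De-adaptation the index divides by the *observed* peak aftereffect,
pinning the data's early washout values at 1, while the model trajectory
decays from its end-Adaptation implicit state (typically 0.5–0.8). Model
fits therefore carry a systematic residual during early washout even on
noise-free data (group-level r² ≈ 0.7 instead of 1 on noise-free cohorts
pushed through the full pipeline). This is a property of the index
definition, not of the optimizer; fits to series expressed directly in
model units recover parameters exactly. The synthetic generator resolves
the same asymmetry by defining its latent De-adaptation index as the model
trajectory rescaled by its own peak over the estimation window, which is
what the measured index converges to as noise goes to zero.

## The candidate learning models

All three models are driven by `error[s] = perturbation[s] − x_implicit[s]`
with the perturbation signal equal to 1 during Adaptation and 0 during
De-adaptation, and all states start at 0 (Baseline is not modeled):

- **single-rate** (k = 2): `x[s+1] = A·x[s] + B·error[s]`.
- **dual-rate** (k = 4): `x = x_fast + x_slow`, each state with its own
  retention rate `A` and learning rate `B`; the fast process learns and
  forgets quickly, the slow one slowly.
- **voluntary correction** (k = 5): the dual-rate implicit system plus a
  memoryless explicit state, `x_explicit[s+1] = B_explicit·error[s]` on
  strides where feedback is on and 0 otherwise. Total output
  `x = x_explicit + x_implicit`. Because the explicit state has no
  retention term, it vanishes on the first stride after feedback offset —
  the discontinuity that identifies explicit learning. The very first
  feedback stride has `x_explicit = 0` (there is no prior error).

The explicit state does not enter the error, so the implicit trajectory is
identical whether or not feedback is on; turning feedback off removes
exactly the counterfactual explicit component (an exact invariant used in
the tests).

A caution on the admissible parameter box: the closed-loop fast/slow update
matrix can have spectral radius above 1 for extreme rate combinations
(e.g. `A_fast = 0, B_fast = 1, A_slow = 1, B_slow = 0.2`), so trajectories
are not globally bounded. Within the spectrally stable region
`|x_implicit|` obeys the geometric bound `(B_fast + B_slow)/(1 − ρ)`,
which the property tests assert.

## Fitting

Per participant, the objective is the sum of squared errors between the
model output and the Adaptation Index on retained strides (the model is
simulated on the full raw stride grid; removed strides are skipped in the
residual only). Constraints: every parameter in [0, 1], `B_fast ≥ 5·B_slow`
and `A_slow ≥ A_fast + ε` with ε = 1e-4 standing in for the strict
inequality. The optimizer is SLSQP with the compiled simulators inside the
objective. Implicit parameters start at literature values
(`A_fast = 0.92, B_fast = 0.03, A_slow = 0.996, B_slow = 0.004`) on every
restart; `B_explicit` starts uniformly at random, 10 restarts by default;
the single-rate start is `A = 0.96, B = 0.017` (midpoints of the dual
values). Ties across restarts break to the lowest SSE, then the lowest
restart index. Each richer model's restart pool gets one extra start seeded
from the nested model's solution (dual from single with `A_fast = A − ε`;
voluntary correction from dual with `B_explicit = 0`), and each restart
keeps the better of its start point and the polished result — together
these enforce `SSE(vc) ≤ SSE(dual) ≤ SSE(single)` up to the O(ε²) slack the
strict-inequality tolerance introduces.

r² is `1 − SSE/SS_total` about the observed mean (negative values allowed).
The group-level bootstrap resamples participants with replacement (1000
samples by default), averages the index stride-by-stride within each
sample, fits the model to the average, and reports the mean and percentile
95% interval of the r² values.

## Model comparison and recovery

AIC and BIC use the Gaussian least-squares form `n·ln(SSE/n) + 2k` and
`n·ln(SSE/n) + k·ln(n)` (an SSE of exactly 0 returns −∞ with a warning).
The recovery analysis simulates each model 100 times at the study noise
level (Gaussian, SD 0.05 in index units, applied directly to the model
trajectory), fits all three models to every dataset, and tallies criterion
winners into a 3×3 confusion matrix.

At these conditions the AIC matrix is diagonally dominant, but **BIC
separates the models better than AIC** (mean diagonal ≈ 1.00 vs ≈ 0.95).
The mechanism is structural: the models are exactly nested, so on data from
a reduced model the richer model's SSE gain behaves like a χ²(1) draw —
AIC's 2-point penalty admits it roughly 16% of the time, BIC's
`ln(900)·Δk ≈ 6.8` almost never — while the voluntary-correction row is at
ceiling for both criteria because an explicit rate of 0.2 against noise of
0.05 over 40 feedback strides is overwhelmingly detectable. AIC can only
outperform BIC when detection of the explicit component is marginal (much
higher noise or a near-zero explicit rate), conditions outside the default
study settings. The recovery matrix reports both criteria so the choice can
be re-examined for any given dataset.

## Behavioral timepoints

Four 5-stride windows on raw stride indices, intersected with retained
strides (windows shrink, never shift): Feedback On (last 5 strides of the
feedback window), Feedback Off (the next 5), End Adaptation (last 5
Adaptation strides), Implicit Aftereffect (first 5 De-adaptation strides —
typically strides 2–5 after the first-stride drop).
`explicit_magnitude = FeedbackOn − FeedbackOff` is the behavioral measure of
explicit learning; on noise-free trajectories it equals the mean explicit
state in the On window minus the implicit drift between the windows, so it
is small but not exactly zero even without explicit learning (≈ 0.01 at the
default parameters).

## Bayesian layer

The 2×2 model assumes each participant's timepoint value is normal with a
common SD and mean `b0 + b_g·g + b_t·t + b_gt·g·t` under ±½ sum-to-zero
coding, so `b_g`, `b_t` and `b_gt` are directly the marginal group
difference, marginal time difference, and difference-of-differences.
Priors are wide and data-scaled — effects ~ Normal(0, 10·SD(y)), residual
SD ~ Uniform(0, 10·SD(y)) — and a 10× widening moves posterior means by
less than Monte-Carlo error (asserted in the tests). Participant-level
random effects are deliberately omitted to match the three-parameter mean
structure; the covariate regressions use the same machinery with a
slope prior scaled by SD(y)/SD(x).

Sampling uses an affine-invariant ensemble sampler (emcee): 24 walkers,
draws thinned ×8 by default, `n_draws = 10,000` retained draws after
`n_tune = 2,000` warm-up draws (both counted across walkers). Walkers start
overdispersed at ~2× the least-squares standard errors around the
least-squares solution — a deliberately wide start, since the ensemble's
proposal scale adapts to its own spread and a too-tight initial ball mixes
slowly and understates posterior width. Convergence is monitored with the
split-chain diagnostic at threshold 1.01 over walker groups; failures are
warned about alongside the summaries, never hidden. With these settings the
95% HDI of a known interaction covers the truth in ~94/100 replicate
datasets.

The HDI is the narrowest contiguous window over the sorted draws containing
⌈0.95·n⌉ of them; `p_difference` is the percentage of draws on the majority
side of zero (zeros split evenly). Posterior-predictive checks replicate
datasets from posterior draws and report two-sided posterior-predictive
p-values for each cell's mean and SD, flagging p < 0.05. The likelihood
comparison refits the model with a Student-t likelihood (ν ~ Uniform(1,
100)) and compares expected log predictive density via WAIC.

## Synthetic study conditions

Defaults emulate a two-group clinical study: 18 control-like and 17
stroke-like participants; phases of 150/450/450 strides (roughly 8-minute
Adaptation and De-adaptation blocks at typical belt speeds); perturbation
−20% asymmetry; baseline total step length 120 cm; stride noise SD 0.05 in
index units (entering through the asymmetry at a common step-length scale,
so fast + slow always equals the baseline total); group parameter means of
`(0.92, 0.03, 0.996, 0.004, 0.28)` for controls and
`(0.83, 0.03, 0.996, 0.004, 0.05)` for the stroke-like group — i.e. a large
explicit-learning deficit and a reduced fast-state retention rate, the two
contrasts the analysis is designed to detect — drawn per participant from
truncated normals that respect the rate-ordering constraints. The
stroke-like group carries a Fugl-Meyer-like covariate (25.4 ± 6.3 points).

What the generator does **not** emulate: gait kinematics and kinetics,
treadmill-speed dynamics beyond the perturbation scalar, acceleration
contamination of first strides, non-Gaussian or autocorrelated stride
noise, and the idiosyncratic non-stationarities of real post-stroke
walking. Consequently, passing tests demonstrate that the pipeline's
machinery is correct and well-calibrated under its own assumptions — not
that those assumptions hold for any particular clinical dataset. One
visible instance: Gaussian stride noise at the default level essentially
never breaches the 3×IQR fence (clean-cohort removal ≈ 0%, versus the small
positive removal rates typical of real recordings), so outlier handling is
exercised through explicitly injected gross strides instead.

## Numerical choices

- Strict inequality `A_slow > A_fast` as `A_slow ≥ A_fast + 1e-4`.
- SLSQP `ftol = 1e-12`, `maxiter = 500`; parameters clipped to bounds after
  polishing; a polished point that violates constraints beyond 1e-8 is
  discarded in favor of its (feasible) start.
- Degenerate inputs: zero perturbation raises; an all-ties asymmetry series
  skips outlier removal with a warning; phases with fewer than 10 retained
  strides estimate the perturbation from what remains, with a warning;
  fully-removed timepoint windows yield NaN with a warning.
- Determinism: every stochastic component (cohort draws, restart
  initializations, bootstrap, recovery simulations, MCMC) is driven by an
  explicit seed; identical seeds give bit-identical outputs.
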