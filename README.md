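# splitbelt

Stride-by-stride analysis of explicit and implicit locomotor learning on the
split-belt treadmill.

When the two belts of a split-belt treadmill run at a 2:1 speed ratio, step
length asymmetry is perturbed and then corrected by two dissociable
processes: slow, error-driven **implicit adaptation**, and fast, strategic
**explicit learning** that can be switched on by visual step-length feedback
and switched off with it. This package implements the full analysis chain
used to separate the two processes in clinical cohorts (e.g. chronic stroke
survivors vs age-matched controls):

1. **Synthetic cohorts** — stride-level step-length series generated from the
   voluntary-correction model below, with group-level parameter
   heterogeneity, Gaussian stride noise and optional gross outliers, so the
   whole pipeline is testable without any data download.
2. **Preprocessing** — step length asymmetry
   `sla = 100·(fast − slow)/(fast + slow)` per stride, baseline correction,
   3×IQR outlier removal, first-stride removal, and the per-phase
   **Adaptation Index** `AI = (sla − condition·perturbation)/|perturbation|`
   (0 = full perturbation, 1 = full correction; scale reversed during
   washout).
3. **State-space models** — three nested candidates for the AI trajectory
   `x[s]`, driven by `error[s] = perturbation[s] − x_implicit[s]`:
   - single-rate: `x[s+1] = A·x[s] + B·error[s]`
   - dual-rate: fast + slow implicit states
     `x_f[s+1] = A_fast·x_f[s] + B_fast·error[s]` (likewise slow)
   - voluntary correction: dual-rate implicit plus a memoryless explicit
     state `x_explicit[s+1] = B_explicit·error[s]` active only while
     feedback is on.
4. **Fitting** — constrained least squares (parameters in [0, 1],
   `B_fast ≥ 5·B_slow`, `A_slow > A_fast`) with fixed implicit
   initializations, 10 random explicit-rate restarts, nested-model seeding,
   per-participant r², and a participant-resampling bootstrap of the group
   fit.
5. **Model selection** — least-squares AIC/BIC (`n·ln(SSE/n) + penalty`)
   with a model-recovery (confusion-matrix) analysis.
6. **Behavioral timepoints** — 5-stride means at Feedback On, Feedback Off,
   End Adaptation, Implicit Aftereffect; `explicit_magnitude = On − Off`.
7. **Bayesian statistics** — a 2×2 group-by-time model with wide data-scaled
   priors sampled by ensemble MCMC; 95% highest-density intervals,
   `p_difference`, posterior-predictive checks, covariate regressions and a
   normal-vs-Student-t likelihood comparison.

## Worked example

```python
import splitbelt as sb

# simulate a small two-group cohort at the default study conditions
cfg = sb.default_cohort_config(seed=7, n_control=6, n_stroke=6)
strides, truth = sb.simulate_cohort(cfg)

# preprocess: asymmetry -> cleaning -> Adaptation Index
ai = sb.preprocess_cohort(strides)

# fit the three models to one control participant
sch = cfg.schedule
one = ai[ai.participant_id == "control_01"]
fits = sb.fit_all_models(one, sch, sb.FitOptions(seed=0))
for name, f in fits.items():
    print(name, f"sse={f.sse:.2f}", f"r2={f.r2:.3f}",
          f"aic={sb.aic(f.sse, f.n_obs, f.k):.1f}")
```

prints (exactly, at these seeds):

```
single sse=15.88 r2=0.558 aic=-3619.7
dual sse=13.34 r2=0.629 aic=-3771.8
vc sse=10.77 r2=0.700 aic=-3962.1
```

The voluntary-correction model wins by a wide AIC margin because this
participant's series contains a genuine feedback-gated explicit component
(truth table: `b_explicit ≈ 0.23` for this draw); the dual- and single-rate
models cannot produce the discontinuity at feedback offset. Timepoints and
the Bayesian group contrast continue from there:

```python
tp = sb.cohort_timepoints(ai, sch)
summary, long = sb.group_summary(tp)
data = long[long.timepoint.isin(["feedback_off", "feedback_on"])]
fit = sb.fit_group_time_model(
    data.rename(columns={"timepoint": "time"}),
    sb.GroupTimeModelSpec(seed=1))
s = fit["interaction"]
print(f"interaction {s.mean:.3f} [{s.hdi_low:.3f} {s.hdi_high:.3f}] "
      f"p_difference={s.p_difference:.1f}%")
```

```
interaction -0.093 [-0.265 0.080] p_difference=86.9%
```

i.e. the feedback On−Off gain is probably smaller in the stroke-like group
(the sign is stroke-minus-control): the generative explicit-learning deficit
shows up behaviorally, though at n = 6 + 6 the evidence is moderate rather
than decisive — exactly the graded reading `p_difference` is meant to give.

A command-line interface mirrors the pipeline:

```bash
splitbelt simulate --out raw/ --seed 3
splitbelt preprocess --in raw/ --out ai.csv
splitbelt fit --in ai.csv --out fits.csv --seed 1
splitbelt analyze --in ai.csv --out timepoints.csv
splitbelt bayes --in timepoints.csv --out posterior.csv --seed 2
splitbelt recover --nsims 100 --seed 0 --out recovery.csv
```

## Layout

- `src/splitbelt/` — library (`schedule`, `models`, `synthetic`,
  `preprocess`, `fitting`, `selection`, `timepoints`, `bayes`, `io`, `cli`)
- `tests/` — pytest suite, including independent stride-loop oracles
- `docs/methods.md` — modelling and design notes
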