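"""Synthetic split-belt cohorts with the statistical structure the analysis assumes.

The generator works backwards through the measurement chain: it
forward-simulates the voluntary-correction model to obtain a latent
Adaptation Index trajectory, inverts the index definition to produce
step length asymmetry (%), adds zero-mean Gaussian stride noise on the
asymmetry scale, optionally injects gross outlier strides, and finally
reconstructs fast/slow step lengths holding their sum at the baseline
total (noise enters through the asymmetry, not the total).

Inversion conventions
---------------------
* Adaptation: ``sla = AI * |P| + P`` with ``P`` the perturbation
  magnitude in asymmetry % (negative: the split belts shorten the
  fast-limb step). AI = 0 reproduces the full perturbation, AI = 1 full
  correction.
* De-adaptation: the measured index is normalized by the peak observed
  aftereffect (max asymmetry over the first 10 strides), which pins the
  data peak at 1. The latent trajectory is therefore the model output
  rescaled by its own peak over that window, and
  ``sla = x * |P|`` on the physical asymmetry scale. This makes the
  generator and the preprocessing module exact inverses on noise-free
  data.
* Baseline: zero-mean noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .models import (
    DualRateParams,
    ModelTrajectory,
    SingleRateParams,
    VCParams,
    simulate_dual,
    simulate_single,
    simulate_vc,
)
from .schedule import PhaseSchedule

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "default_cohort_config",
    "simulate_trajectory",
    "simulate_ai_series",
    "ai_frame",
    "simulate_participant",
    "simulate_cohort",
]

_PARAM_FIELDS = ("a_fast", "b_fast", "a_slow", "b_slow", "b_explicit")


def simulate_trajectory(params, schedule: PhaseSchedule) -> ModelTrajectory:
    """Dispatch forward simulation on the parameter type."""
    if isinstance(params, VCParams):
        return simulate_vc(params, schedule)
    if isinstance(params, DualRateParams):
        return simulate_dual(params, schedule)
    if isinstance(params, SingleRateParams):
        return simulate_single(params, schedule)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def simulate_ai_series(params, schedule: PhaseSchedule, noise_sd: float, rng) -> np.ndarray:
    """Model Adaptation Index over the modeled strides plus Gaussian stride noise.

    This is the observation model used by the parameter- and
    model-recovery studies: noise is added directly in Adaptation Index
    units to the forward-simulated trajectory.
    """
    rng = np.random.default_rng(rng)
    x = simulate_trajectory(params, schedule).x
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return x.copy()
    return x + rng.normal(0.0, noise_sd, size=x.size)


def _inject_outliers(sla: np.ndarray, rate: float, rng) -> np.ndarray:
    """Replace a Bernoulli(rate) subset of strides with values beyond the 3xIQR fence."""
    flags = rng.random(sla.size) < rate
    if not flags.any():
        return flags
    q1, q3 = np.percentile(sla, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        iqr = max(1.0, np.abs(sla).max())
    for i in np.flatnonzero(flags):
        margin = (0.5 + rng.random()) * iqr
        if rng.random() < 0.5:
            sla[i] = min(q3 + 3.0 * iqr + margin, 95.0)
        else:
            sla[i] = max(q1 - 3.0 * iqr - margin, -95.0)
    return flags


def ai_frame(y: np.ndarray, schedule: PhaseSchedule, *, participant_id: str = "P01",
             group: str = "g") -> pd.DataFrame:
    """Wrap an Adaptation Index array over the modeled strides in table form.

    Produces the ``phase/stride/ai/retained`` layout the fitting,
    timepoint and bootstrap APIs consume, for series simulated directly
    in Adaptation Index units.
    """
    y = np.asarray(y, dtype=float)
    if y.size != schedule.n_modeled:
        raise ValueError("series length does not match schedule")
    n_a, n_d = schedule.n_adaptation, schedule.n_deadaptation
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": group,
            "phase": ["Adaptation"] * n_a + ["Deadaptation"] * n_d,
            "stride": list(range(1, n_a + 1)) + list(range(1, n_d + 1)),
            "ai": y,
            "retained": True,
        }
    )


def simulate_participant(
    params: VCParams,
    schedule: PhaseSchedule | None = None,
    *,
    noise_sd: float = 0.05,
    perturbation_pct: float = -20.0,
    baseline_total: float = 120.0,
    outlier_rate: float = 0.0,
    seed=None,
    participant_id: str = "P01",
    group: str = "control",
    covariate: float | None = None,
) -> pd.DataFrame:
    """Simulate one participant's stride-by-stride step-length series.

    Returns a tidy table with columns ``participant_id, group, phase,
    stride, fast_step_cm, slow_step_cm, feedback_on, ai_latent,
    injected_outlier`` (plus ``lefm`` if a covariate is given).
    ``ai_latent`` holds the noise-free latent Adaptation Index on the
    modeled strides and NaN during Baseline.
    """
    schedule = schedule or PhaseSchedule()
    if perturbation_pct == 0:
        raise ValueError("perturbation_pct must be nonzero (degenerate normalization)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    traj = simulate_vc(params, schedule)
    n_a, n_d = schedule.n_adaptation, schedule.n_deadaptation
    x_adapt = traj.x[:n_a]
    x_dead = traj.x[n_a:]
    p_abs = abs(perturbation_pct)

    # latent index: model output during Adaptation; peak-normalized during
    # De-adaptation (the measured index divides by the observed aftereffect peak)
    peak = float(x_dead[: min(10, n_d)].max())
    latent_adapt = x_adapt
    if peak > 1e-12:
        latent_dead = x_dead / peak
        sla_dead = x_dead * p_abs
    else:  # degenerate aftereffect: nothing stored to wash out
        latent_dead = np.zeros(n_d)
        sla_dead = np.zeros(n_d)

    sla_adapt = latent_adapt * p_abs + perturbation_pct
    sla_base = np.zeros(schedule.n_baseline)
    sla = np.concatenate([sla_base, sla_adapt, sla_dead])
    if noise_sd > 0:
        sla = sla + rng.normal(0.0, noise_sd * p_abs, size=sla.size)

    if not 0 <= outlier_rate < 1:
        raise ValueError("outlier_rate must lie in [0, 1)")
    flags = (
        _inject_outliers(sla, outlier_rate, rng)
        if outlier_rate > 0
        else np.zeros(sla.size, dtype=bool)
    )

    fast = baseline_total * (1.0 + sla / 100.0) / 2.0
    slow = baseline_total - fast

    phase = np.concatenate(
        [np.repeat(name, n) for name, n in schedule.phases]
    )
    stride = np.concatenate([np.arange(1, n + 1) for _, n in schedule.phases])
    fb = np.concatenate(
        [np.zeros(schedule.n_baseline, dtype=bool), schedule.feedback_mask()]
    )
    ai_latent = np.concatenate(
        [np.full(schedule.n_baseline, np.nan), latent_adapt, latent_dead]
    )

    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": group,
            "phase": phase,
            "stride": stride,
            "fast_step_cm": fast,
            "slow_step_cm": slow,
            "feedback_on": fb,
            "ai_latent": ai_latent,
            "injected_outlier": flags,
        }
    )
    if covariate is not None:
        out["lefm"] = covariate
    return out


@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one participant group.

    ``means`` are the group-level voluntary-correction parameter means;
    ``sds`` maps parameter names to between-participant SDs (truncated
    normal on [0, 1]). ``covariate_mean``/``covariate_sd`` optionally
    generate a clinical covariate (e.g. a Lower Extremity Fugl-Meyer
    score) per participant.
    """

    n_participants: int
    means: VCParams
    sds: Mapping[str, float] = field(default_factory=dict)
    covariate_mean: float | None = None
    covariate_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for k, v in self.sds.items():
            if k not in _PARAM_FIELDS:
                raise ValueError(f"unknown parameter {k!r} in sds")
            if v < 0:
                raise ValueError("parameter SDs must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort recipe: groups, schedule, noise and perturbation levels."""

    groups: Mapping[str, GroupSpec]
    schedule: PhaseSchedule = PhaseSchedule()
    noise_sd: float = 0.05
    perturbation_pct: float = -20.0
    baseline_total: float = 120.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must lie in [0, 1)")


def default_cohort_config(
    seed: int = 0,
    *,
    n_control: int = 18,
    n_stroke: int = 17,
    noise_sd: float = 0.05,
    outlier_rate: float = 0.0,
    schedule: PhaseSchedule | None = None,
) -> CohortConfig:
    """Two-group study conditions: a control-like and a stroke-like cohort.

    Group means are set so the generative contrasts mirror the effects the
    analysis is meant to detect: a large explicit-learning deficit
    (b_explicit 0.28 vs 0.05) and a reduced fast-state retention rate
    (a_fast 0.92 vs 0.83) in the stroke-like group, with shared slow-state
    parameters. The stroke-like group carries a Fugl-Meyer-like covariate.
    """
    groups: dict[str, GroupSpec] = {}
    if n_control > 0:
        groups["control"] = GroupSpec(
            n_participants=n_control,
            means=VCParams(0.92, 0.03, 0.996, 0.004, 0.28),
            sds={"a_fast": 0.05, "b_fast": 0.01, "a_slow": 0.003, "b_slow": 0.002,
                 "b_explicit": 0.10},
        )
    if n_stroke > 0:
        groups["stroke"] = GroupSpec(
            n_participants=n_stroke,
            means=VCParams(0.83, 0.03, 0.996, 0.004, 0.05),
            sds={"a_fast": 0.05, "b_fast": 0.01, "a_slow": 0.003, "b_slow": 0.002,
                 "b_explicit": 0.05},
            covariate_mean=25.4,
            covariate_sd=6.3,
        )
    return CohortConfig(
        groups=groups,
        schedule=schedule or PhaseSchedule(),
        noise_sd=noise_sd,
        outlier_rate=outlier_rate,
        seed=seed,
    )


def _draw_params(spec: GroupSpec, rng, max_tries: int = 1000) -> VCParams:
    """Truncated-normal parameter draw honoring the model's rate-ordering constraints."""
    for _ in range(max_tries):
        vals = {}
        for name in _PARAM_FIELDS:
            mu = getattr(spec.means, name)
            sd = spec.sds.get(name, 0.0)
            if sd == 0:
                vals[name] = mu
                continue
            v = rng.normal(mu, sd)
            while not 0.0 <= v <= 1.0:
                v = rng.normal(mu, sd)
            vals[name] = v
        if vals["b_fast"] >= 5.0 * vals["b_slow"] and vals["a_slow"] >= vals["a_fast"]:
            return VCParams(**vals)
    raise RuntimeError("could not draw constraint-satisfying parameters")


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every participant of a cohort.

    Returns ``(strides, truth)``: the concatenated stride tables and a
    per-participant table of the generating parameters (and covariate),
    for recovery checks. Identical config (including seed) reproduces the
    cohort bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    stride_tables = []
    truth_rows = []
    for group_name, spec in config.groups.items():
        for i in range(spec.n_participants):
            pid = f"{group_name}_{i + 1:02d}"
            params = _draw_params(spec, rng)
            covariate = None
            if spec.covariate_mean is not None:
                covariate = float(rng.normal(spec.covariate_mean, spec.covariate_sd))
            child_seed = int(rng.integers(0, 2**31 - 1))
            stride_tables.append(
                simulate_participant(
                    params,
                    config.schedule,
                    noise_sd=config.noise_sd,
                    perturbation_pct=config.perturbation_pct,
                    baseline_total=config.baseline_total,
                    outlier_rate=config.outlier_rate,
                    seed=child_seed,
                    participant_id=pid,
                    group=group_name,
                    covariate=covariate,
                )
            )
            row = {"participant_id": pid, "group": group_name, "seed": child_seed}
            row.update({f: getattr(params, f) for f in _PARAM_FIELDS})
            if covariate is not None:
                row["lefm"] = covariate
            truth_rows.append(row)
    return pd.concat(stride_tables, ignore_index=True), pd.DataFrame(truth_rows)
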