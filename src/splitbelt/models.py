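"""State-space models of split-belt locomotor adaptation.

Three nested candidate models describe the stride-by-stride Adaptation
Index x[s] over the Adaptation and De-adaptation phases:

* **single-rate** — one process: ``x[s+1] = A*x[s] + B*error[s]`` with
  ``error[s] = perturbation[s] - x[s]``.
* **dual-rate** — implicit adaptation as the sum of a fast process
  (learns and forgets quickly) and a slow process (learns slowly,
  retains long): ``x_f[s+1] = A_fast*x_f[s] + B_fast*error[s]`` and
  likewise for the slow state, with ``error[s] = perturbation[s] -
  (x_f[s] + x_s[s])``.
* **voluntary correction** — the dual-rate implicit system plus a
  memoryless explicit state that is only active while visual feedback
  is on: ``x_explicit[s+1] = B_explicit*error[s]`` on feedback strides,
  0 otherwise. Total output ``x = x_explicit + x_implicit``; both
  processes correct for the same implicit error.

The perturbation signal is 1 while the belts are split (Adaptation) and
0 while they are tied (De-adaptation). All states start at 0 on the
first Adaptation stride; Baseline is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import _kernels
from .schedule import PhaseSchedule

__all__ = [
    "SingleRateParams",
    "DualRateParams",
    "VCParams",
    "ModelTrajectory",
    "simulate_single",
    "simulate_dual",
    "simulate_vc",
]


def _check_unit_interval(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not np.isfinite(v):
            raise ValueError(f"{f.name} must be finite, got {v!r}")
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{f.name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class SingleRateParams:
    """Single-rate model: retention rate ``a`` and learning rate ``b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        _check_unit_interval(self)


@dataclass(frozen=True)
class DualRateParams:
    """Dual-rate implicit adaptation parameters (all dimensionless, per stride)."""

    a_fast: float
    b_fast: float
    a_slow: float
    b_slow: float

    def __post_init__(self) -> None:
        _check_unit_interval(self)


@dataclass(frozen=True)
class VCParams:
    """Voluntary-correction model parameters.

    ``a_fast``/``a_slow`` are retention rates and ``b_fast``/``b_slow``
    learning rates of the implicit fast and slow states; ``b_explicit``
    is the explicit (strategic) learning rate applied to the previous
    stride's error while feedback is on.
    """

    a_fast: float
    b_fast: float
    a_slow: float
    b_slow: float
    b_explicit: float

    def __post_init__(self) -> None:
        _check_unit_interval(self)

    def implicit(self) -> DualRateParams:
        return DualRateParams(self.a_fast, self.b_fast, self.a_slow, self.b_slow)


#: Implicit-parameter initialization used for fitting, from prior
#: locomotor-adaptation work in stroke survivors.
PAPER_INIT = VCParams(a_fast=0.92, b_fast=0.03, a_slow=0.996, b_slow=0.004, b_explicit=0.0)


@dataclass(frozen=True)
class ModelTrajectory:
    """Per-stride model states over the modeled (Adaptation + De-adaptation) strides.

    ``x = x_explicit + x_implicit`` holds on every stride;
    ``x_explicit`` is identically 0 for the single- and dual-rate models.
    """

    x: np.ndarray
    x_fast: np.ndarray
    x_slow: np.ndarray
    x_explicit: np.ndarray
    x_implicit: np.ndarray
    error: np.ndarray
    perturbation: np.ndarray
    feedback_on: np.ndarray
    schedule: PhaseSchedule

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-stride table (stride index 1-based within phase)."""
        n_a = self.schedule.n_adaptation
        n_d = self.schedule.n_deadaptation
        phase = ["Adaptation"] * n_a + ["Deadaptation"] * n_d
        stride = list(range(1, n_a + 1)) + list(range(1, n_d + 1))
        return pd.DataFrame(
            {
                "phase": phase,
                "stride": stride,
                "x": self.x,
                "x_fast": self.x_fast,
                "x_slow": self.x_slow,
                "x_explicit": self.x_explicit,
                "x_implicit": self.x_implicit,
                "error": self.error,
                "perturbation": self.perturbation,
                "feedback_on": self.feedback_on,
            }
        )


def _trajectory(schedule, x, xf, xs, xe, xi, err) -> ModelTrajectory:
    return ModelTrajectory(
        x=x,
        x_fast=xf,
        x_slow=xs,
        x_explicit=xe,
        x_implicit=xi,
        error=err,
        perturbation=schedule.perturbation_signal(),
        feedback_on=schedule.feedback_mask(),
        schedule=schedule,
    )


def simulate_vc(params: VCParams, schedule: PhaseSchedule) -> ModelTrajectory:
    """Forward-simulate the voluntary-correction model on a schedule."""
    pert = schedule.perturbation_signal()
    fb = schedule.feedback_mask()
    out = _kernels.vc_loop(
        params.a_fast, params.b_fast, params.a_slow, params.b_slow,
        params.b_explicit, pert, fb,
    )
    return _trajectory(schedule, *out)


def simulate_dual(params: DualRateParams, schedule: PhaseSchedule) -> ModelTrajectory:
    """Forward-simulate the dual-rate model (voluntary correction with no explicit state)."""
    pert = schedule.perturbation_signal()
    fb = schedule.feedback_mask()
    out = _kernels.vc_loop(
        params.a_fast, params.b_fast, params.a_slow, params.b_slow, 0.0, pert, fb,
    )
    return _trajectory(schedule, *out)


def simulate_single(params: SingleRateParams, schedule: PhaseSchedule) -> ModelTrajectory:
    """Forward-simulate the single-rate model."""
    pert = schedule.perturbation_signal()
    x, err = _kernels.single_loop(params.a, params.b, pert)
    zeros = np.zeros_like(x)
    return ModelTrajectory(
        x=x,
        x_fast=zeros,
        x_slow=x.copy(),
        x_explicit=zeros,
        x_implicit=x.copy(),
        error=err,
        perturbation=pert,
        feedback_on=schedule.feedback_mask(),
        schedule=schedule,
    )
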