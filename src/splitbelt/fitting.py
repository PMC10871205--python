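"""Constrained least-squares fitting of the candidate learning models.

Each model is fit to a participant's Adaptation Index series over the
Adaptation and De-adaptation strides by minimizing the sum of squared
errors between the forward-simulated trajectory and the data, subject to

* box bounds: every parameter in [0, 1],
* rate ordering: ``b_fast >= 5 * b_slow`` and ``a_slow >= a_fast + eps``
  (the strict inequality implemented with a small tolerance).

Implicit parameters are initialized at fixed literature values on every
restart; the explicit learning rate is initialized uniformly at random,
with (by default) 10 restarts per participant. To protect model
comparison from local minima, each richer model's restart pool is
additionally seeded with the best fit of the model nested inside it
(single -> dual -> voluntary correction), which enforces the SSE
ordering SSE(vc) <= SSE(dual) <= SSE(single).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .models import (
    DualRateParams,
    PAPER_INIT,
    SingleRateParams,
    VCParams,
)
from .schedule import PhaseSchedule

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_model",
    "fit_all_models",
    "r_squared",
    "bootstrap_group_fit",
]

MODEL_NAMES = ("single", "dual", "vc")
_K = {"single": 2, "dual": 4, "vc": 5}
#: Single-rate initialization: midpoints of the dual-rate literature values.
SINGLE_INIT = (0.96, 0.017)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    ``n_restarts`` random explicit-rate initializations (voluntary
    correction only); ``eps`` is the strict-inequality tolerance for
    ``a_slow > a_fast``; ``nested_seeding`` adds one deterministic
    restart seeded from the nested model's solution.
    """

    n_restarts: int = 10
    eps: float = 1e-4
    seed: int = 0
    ftol: float = 1e-12
    maxiter: int = 500
    nested_seeding: bool = True

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


@dataclass
class FitResult:
    """Best-fit parameters for one model on one series, with a restart audit."""

    model: str
    params: object
    sse: float
    n_obs: int
    r2: float
    restarts: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return _K[self.model]

    def params_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self.params)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, ``1 - SSE/SS_total`` about the observed mean.

    May be negative when the model fits worse than the mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero total variance in observed data")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def _extract_series(ai_series, schedule: PhaseSchedule):
    """Normalize input to (y, mask) on the modeled raw stride grid.

    Accepts a plain array of Adaptation Index values over the
    Adaptation + De-adaptation strides, or a preprocessed participant
    table with ``phase``/``stride``/``ai``/``retained`` columns.
    """
    if isinstance(ai_series, pd.DataFrame):
        sub = ai_series[ai_series["phase"].isin(["Adaptation", "Deadaptation"])]
        sub = sub.sort_values(["phase", "stride"], key=_phase_sort_key(sub))
        y = np.full(schedule.n_modeled, np.nan)
        mask = np.zeros(schedule.n_modeled, dtype=bool)
        offs = {"Adaptation": 0, "Deadaptation": schedule.n_adaptation}
        idx = sub["stride"].to_numpy() - 1 + np.array(
            [offs[p] for p in sub["phase"]]
        )
        y[idx] = sub["ai"].to_numpy()
        retained = sub["retained"].to_numpy() if "retained" in sub else np.ones(len(sub), bool)
        mask[idx] = retained & np.isfinite(sub["ai"].to_numpy())
        return y, mask
    y = np.asarray(ai_series, dtype=float)
    if y.size != schedule.n_modeled:
        raise ValueError(
            f"series length {y.size} does not match schedule ({schedule.n_modeled})"
        )
    return y, np.isfinite(y)


def _phase_sort_key(sub):
    order = {"Adaptation": 0, "Deadaptation": 1}

    def key(col):
        if col.name == "phase":
            return col.map(order)
        return col

    return key


def _objective(model: str, pert, fb, y, mask):
    yy = np.where(mask, y, 0.0)
    if model == "single":
        def f(theta):
            return _kernels.single_sse(theta[0], theta[1], pert, yy, mask)
    elif model == "dual":
        def f(theta):
            return _kernels.vc_sse(theta[0], theta[1], theta[2], theta[3], 0.0,
                                   pert, fb, yy, mask)
    else:
        def f(theta):
            return _kernels.vc_sse(theta[0], theta[1], theta[2], theta[3], theta[4],
                                   pert, fb, yy, mask)
    return f


def _constraints(model: str, eps: float):
    if model == "single":
        return []
    return [
        {"type": "ineq", "fun": lambda th: th[1] - 5.0 * th[3]},
        {"type": "ineq", "fun": lambda th: th[2] - th[0] - eps},
    ]


def _feasible(model: str, theta, eps: float, tol: float = 1e-8) -> bool:
    if np.any(theta < -tol) or np.any(theta > 1 + tol):
        return False
    if model == "single":
        return True
    return (theta[1] - 5.0 * theta[3] >= -tol) and (theta[2] - theta[0] - eps >= -tol)


def _starts(model: str, options: FitOptions, rng, seed_params) -> list[tuple[str, np.ndarray]]:
    pi = PAPER_INIT
    starts: list[tuple[str, np.ndarray]] = []
    if model == "single":
        starts.append(("default", np.array(SINGLE_INIT)))
    elif model == "dual":
        starts.append(("default", np.array([pi.a_fast, pi.b_fast, pi.a_slow, pi.b_slow])))
        if seed_params is not None:  # single-rate solution lifted into dual space
            a, b = seed_params.a, seed_params.b
            af = max(a - options.eps, 0.0)
            as_ = min(max(a, af + options.eps), 1.0)
            starts.append(("nested", np.array([af, 5.0 * b / 6.0, as_, b / 6.0])))
    else:
        for i in range(options.n_restarts):
            be = rng.uniform(0.0, 1.0)
            starts.append(
                (f"random_{i}", np.array([pi.a_fast, pi.b_fast, pi.a_slow, pi.b_slow, be]))
            )
        if seed_params is not None:  # dual-rate solution with no explicit learning
            p = seed_params
            starts.append(
                ("nested", np.array([p.a_fast, p.b_fast, p.a_slow, p.b_slow, 0.0]))
            )
    return starts


def _to_params(model: str, theta):
    theta = np.clip(theta, 0.0, 1.0)
    if model == "single":
        return SingleRateParams(*theta)
    if model == "dual":
        return DualRateParams(*theta)
    return VCParams(*theta)


def _fit_one(model, y, mask, schedule, options, rng, seed_params) -> FitResult:
    pert = schedule.perturbation_signal()
    fb = schedule.feedback_mask()
    obj = _objective(model, pert, fb, y, mask)
    cons = _constraints(model, options.eps)
    ndim = _K[model]
    if int(mask.sum()) <= ndim:
        raise ValueError("series has fewer retained strides than parameters")
    bounds = [(0.0, 1.0)] * ndim

    records = []
    candidates = []  # (sse, order, theta, label)
    any_success = False
    for order, (label, x0) in enumerate(_starts(model, options, rng, seed_params)):
        sse0 = float(obj(x0))
        best_theta, best_sse = x0, sse0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(
                obj, x0, method="SLSQP", bounds=bounds, constraints=cons,
                options={"ftol": options.ftol, "maxiter": options.maxiter},
            )
        theta = np.clip(res.x, 0.0, 1.0)
        sse = float(obj(theta))
        # keep the better of {start, polished}; protects the nested-SSE ordering
        if np.isfinite(sse) and sse < best_sse and _feasible(model, theta, options.eps):
            best_theta, best_sse = theta, sse
        any_success = any_success or bool(res.success)
        records.append(
            {"label": label, "init": tuple(x0), "params": tuple(best_theta),
             "sse": best_sse, "success": bool(res.success)}
        )
        candidates.append((best_sse, order, best_theta, label))

    if not any(np.isfinite(c[0]) for c in candidates):
        raise RuntimeError(f"{model} fit failed to produce a finite SSE on any restart")
    if not any_success:
        warnings.warn(f"{model}: optimizer reported non-convergence on all restarts")
    best_sse, _, best_theta, best_label = min(candidates, key=lambda c: (c[0], c[1]))
    params = _to_params(model, best_theta)
    n_obs = int(mask.sum())
    obs = y[mask]
    pred_sse_mean = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - best_sse / pred_sse_mean if pred_sse_mean > 0 else math.nan
    flags = {
        "bound_hit": bool(np.any(np.isclose(best_theta, 0)) or np.any(np.isclose(best_theta, 1))),
        "constraint_active": (
            model != "single"
            and (np.isclose(best_theta[1], 5 * best_theta[3], atol=1e-6)
                 or np.isclose(best_theta[2] - best_theta[0], options.eps, atol=1e-6))
        ),
        "best_restart": best_label,
    }
    return FitResult(model=model, params=params, sse=best_sse, n_obs=n_obs,
                     r2=r2, restarts=records, flags=flags)


def fit_all_models(ai_series, schedule: PhaseSchedule,
                   options: FitOptions | None = None) -> dict[str, FitResult]:
    """Fit single-rate, dual-rate and voluntary-correction models to one series.

    The nested-seeding chain runs single -> dual -> vc so each richer
    model starts (among other restarts) from the reduced model's optimum.
    """
    options = options or FitOptions()
    y, mask = _extract_series(ai_series, schedule)
    rng = np.random.default_rng(options.seed)
    out: dict[str, FitResult] = {}
    out["single"] = _fit_one("single", y, mask, schedule, options, rng, None)
    seed_d = out["single"].params if options.nested_seeding else None
    out["dual"] = _fit_one("dual", y, mask, schedule, options, rng, seed_d)
    seed_v = out["dual"].params if options.nested_seeding else None
    out["vc"] = _fit_one("vc", y, mask, schedule, options, rng, seed_v)
    return out


def fit_model(model_name: str, ai_series, schedule: PhaseSchedule,
              options: FitOptions | None = None) -> FitResult:
    """Fit one named model (``single``, ``dual`` or ``vc``) to a series.

    With nested seeding enabled (default) the reduced models are fit
    first to seed the requested model's restart pool.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")
    options = options or FitOptions()
    if not options.nested_seeding or model_name == "single":
        y, mask = _extract_series(ai_series, schedule)
        rng = np.random.default_rng(options.seed)
        return _fit_one(model_name, y, mask, schedule, options, rng, None)
    return fit_all_models(ai_series, schedule, options)[model_name]


def participant_matrix(ai_df: pd.DataFrame, schedule: PhaseSchedule):
    """Stack per-participant AI series (NaN at removed strides) into a matrix.

    Returns ``(ids, Y)`` with ``Y`` of shape (n_participants, n_modeled).
    Participants are truncated to the schedule's raw stride grid.
    """
    ids, rows = [], []
    for pid, grp in ai_df.groupby("participant_id", sort=False):
        y, mask = _extract_series(grp, schedule)
        y = np.where(mask, y, np.nan)
        ids.append(pid)
        rows.append(y)
    return ids, np.vstack(rows)


def bootstrap_group_fit(ai_df: pd.DataFrame, model_name: str,
                        schedule: PhaseSchedule, n_boot: int = 1000,
                        options: FitOptions | None = None, seed: int = 0):
    """Bootstrap the group-level model fit.

    Resamples participants with replacement ``n_boot`` times, averages
    the Adaptation Index stride-by-stride within each bootstrap sample,
    fits the model to the averaged series, and records its r-squared.

    Returns ``(mean_r2, (ci_low, ci_high), records)`` with a percentile
    95% interval over bootstrap samples.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    options = options or FitOptions()
    ids, Y = participant_matrix(ai_df, schedule)
    if len(ids) < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    records = []
    for b in range(n_boot):
        take = rng.integers(0, len(ids), size=len(ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_series = np.nanmean(Y[take], axis=0)
        opts_b = FitOptions(
            n_restarts=options.n_restarts, eps=options.eps,
            seed=int(rng.integers(0, 2**31 - 1)), ftol=options.ftol,
            maxiter=options.maxiter, nested_seeding=options.nested_seeding,
        )
        fit = fit_model(model_name, mean_series, schedule, opts_b)
        rec = {"sample": b, "r2": fit.r2, "sse": fit.sse}
        rec.update({f"param_{k}": v for k, v in fit.params_dict().items()})
        records.append(rec)
    records = pd.DataFrame(records)
    r2 = records["r2"].to_numpy()
    lo, hi = np.percentile(r2, [2.5, 97.5])
    return float(r2.mean()), (float(lo), float(hi)), records
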