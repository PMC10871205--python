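"""Information-criterion model comparison and model-recovery analysis.

Because fitting is least-squares under an implicit Gaussian error model,
the criteria use the SSE form

* ``AIC = n * ln(SSE / n) + 2k``
* ``BIC = n * ln(SSE / n) + k * ln(n)``

with ``n`` retained strides and ``k`` free parameters (single = 2,
dual = 4, voluntary correction = 5).

The model-recovery analysis simulates noisy experiments from each
candidate model, fits all three to every simulated dataset, and tallies
how often each criterion picks the generating model — the check that
justifies using one criterion over the other.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitOptions, FitResult, MODEL_NAMES, fit_all_models
from .models import DualRateParams, SingleRateParams, VCParams
from .schedule import PhaseSchedule
from .synthetic import simulate_ai_series

__all__ = [
    "aic",
    "bic",
    "compare_models",
    "model_recovery",
    "RecoveryMatrix",
    "DEFAULT_GENERATING_PARAMS",
]

#: Generating parameters for recovery: the literature initialization values,
#: with a moderate explicit rate for the voluntary-correction model.
DEFAULT_GENERATING_PARAMS = {
    "single": SingleRateParams(0.96, 0.017),
    "dual": DualRateParams(0.92, 0.03, 0.996, 0.004),
    "vc": VCParams(0.92, 0.03, 0.996, 0.004, 0.2),
}


def _ic(sse: float, n_obs: int, k: int, penalty: float) -> float:
    if n_obs <= k:
        raise ValueError("n_obs must exceed the parameter count")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if sse == 0:
        warnings.warn("SSE = 0: information criterion is -inf")
        return -math.inf
    return n_obs * math.log(sse / n_obs) + penalty


def aic(sse: float, n_obs: int, k: int) -> float:
    """Akaike Information Criterion for a least-squares fit."""
    return _ic(sse, n_obs, k, 2.0 * k)


def bic(sse: float, n_obs: int, k: int) -> float:
    """Bayesian Information Criterion for a least-squares fit."""
    return _ic(sse, n_obs, k, k * math.log(n_obs))


@dataclass
class ComparisonRecord:
    """Per-participant criterion table plus pairwise AIC-difference summaries."""

    table: pd.DataFrame
    differences: pd.DataFrame


def compare_models(fits: dict[str, dict[str, FitResult]], n_boot: int = 1000,
                   seed: int = 0) -> ComparisonRecord:
    """Tabulate AIC/BIC per participant and summarize AIC differences vs ``vc``.

    ``fits`` maps participant id -> model name -> FitResult; all three
    models must have been fit on the same retained strides. Differences
    (simpler-model AIC minus voluntary-correction AIC; positive favors
    the voluntary-correction model) are summarized with a mean and a
    percentile 95% interval from a participant-level bootstrap.
    """
    rows = []
    for pid, per_model in fits.items():
        n_obs = {m: f.n_obs for m, f in per_model.items()}
        if len(set(n_obs.values())) != 1:
            raise ValueError(f"participant {pid}: n_obs differs across models {n_obs}")
        for m, f in per_model.items():
            rows.append(
                {"participant_id": pid, "model": m, "k": f.k, "n_obs": f.n_obs,
                 "sse": f.sse, "r2": f.r2,
                 "aic": aic(f.sse, f.n_obs, f.k), "bic": bic(f.sse, f.n_obs, f.k)}
            )
    table = pd.DataFrame(rows)

    wide = table.pivot(index="participant_id", columns="model", values="aic")
    rng = np.random.default_rng(seed)
    diff_rows = []
    for other in ("single", "dual"):
        d = (wide[other] - wide["vc"]).to_numpy()
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = d[rng.integers(0, d.size, d.size)].mean()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        diff_rows.append(
            {"contrast": f"{other}_minus_vc", "mean": float(d.mean()),
             "ci_low": float(lo), "ci_high": float(hi)}
        )
    return ComparisonRecord(table=table, differences=pd.DataFrame(diff_rows))


@dataclass
class RecoveryMatrix:
    """3x3 confusion counts from the model-recovery analysis.

    Rows are the generating model, columns the best-fitting model under
    each criterion; every row sums to ``n_sims``.
    """

    counts_aic: pd.DataFrame
    counts_bic: pd.DataFrame
    n_sims: int

    def mean_diagonal(self, criterion: str = "aic") -> float:
        counts = self.counts_aic if criterion == "aic" else self.counts_bic
        return float(np.mean(np.diag(counts.to_numpy()) / self.n_sims))

    @property
    def better_criterion(self) -> str:
        """Criterion with the higher mean recovery rate (AIC wins ties)."""
        return "aic" if self.mean_diagonal("aic") >= self.mean_diagonal("bic") else "bic"


def model_recovery(n_sims: int = 100, generating_params: dict | None = None,
                   noise_sd: float = 0.05, schedule: PhaseSchedule | None = None,
                   seed: int = 0, options: FitOptions | None = None) -> RecoveryMatrix:
    """Simulate each model ``n_sims`` times, fit all three, tally criterion winners.

    Noise is Gaussian in Adaptation Index units on every modeled stride.
    Identical seeds reproduce the matrix exactly.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    generating_params = generating_params or DEFAULT_GENERATING_PARAMS
    schedule = schedule or PhaseSchedule()
    options = options or FitOptions()
    rng = np.random.default_rng(seed)

    counts = {c: pd.DataFrame(0, index=list(MODEL_NAMES), columns=list(MODEL_NAMES))
              for c in ("aic", "bic")}
    for gen_name in MODEL_NAMES:
        params = generating_params[gen_name]
        for _ in range(n_sims):
            y = simulate_ai_series(params, schedule, noise_sd,
                                   rng.integers(0, 2**31 - 1))
            opts = FitOptions(
                n_restarts=options.n_restarts, eps=options.eps,
                seed=int(rng.integers(0, 2**31 - 1)), ftol=options.ftol,
                maxiter=options.maxiter, nested_seeding=options.nested_seeding,
            )
            fits = fit_all_models(y, schedule, opts)
            for crit, fn in (("aic", aic), ("bic", bic)):
                vals = {m: fn(f.sse, f.n_obs, f.k) for m, f in fits.items()}
                winner = min(vals, key=vals.get)
                counts[crit].loc[gen_name, winner] += 1
    return RecoveryMatrix(counts_aic=counts["aic"], counts_bic=counts["bic"],
                          n_sims=n_sims)
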