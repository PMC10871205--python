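"""From step lengths to the Adaptation Index.

The pipeline operates on a tidy per-participant stride table with columns
``phase`` (Baseline / Adaptation / Deadaptation), ``stride`` (1-based within
phase), ``fast_step_cm``, ``slow_step_cm`` and ``feedback_on``. It

1. computes **step length asymmetry** per stride,
   ``sla = 100 * (fast - slow) / (fast + slow)`` (%),
2. **baseline-corrects** by subtracting the participant's mean Baseline
   asymmetry,
3. flags **outlier strides** outside a Tukey-style fence at 3x the
   interquartile range of the participant's full asymmetry series,
4. estimates the per-phase **perturbation** — the most negative asymmetry
   over the first 10 retained Adaptation strides, and the most positive
   over the first 10 retained De-adaptation strides,
5. drops the **first stride of each phase** (treadmill acceleration), and
6. computes the **Adaptation Index**
   ``AI[s] = (sla[s] - condition*perturbation) / |perturbation|``,
   where ``condition`` is 1 while the belts are split and 0 otherwise.

During Adaptation, AI = 0 at the peak perturbation and 1 at full
correction; during De-adaptation the scale is reversed (1 at the peak
aftereffect, 0 at symmetry). The perturbation is estimated before the
first-stride drop so that the index is anchored to the true initial
perturbation, which a simulated (acceleration-free) first stride carries
exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "step_length_asymmetry",
    "compute_asymmetry",
    "baseline_correct",
    "remove_outliers",
    "removed_fraction",
    "drop_first_strides",
    "adaptation_index",
    "preprocess",
    "preprocess_cohort",
]


def step_length_asymmetry(fast_step, slow_step):
    """Step length asymmetry in %, ``100*(fast - slow)/(fast + slow)``.

    Accepts scalars or arrays. Raises on a zero denominator.
    """
    fast = np.asarray(fast_step, dtype=float)
    slow = np.asarray(slow_step, dtype=float)
    denom = fast + slow
    if np.any(denom == 0):
        raise ValueError("fast_step + slow_step must be nonzero")
    out = 100.0 * (fast - slow) / denom
    if out.ndim == 0:
        return float(out)
    return out


def compute_asymmetry(strides: pd.DataFrame) -> pd.DataFrame:
    """Add ``sla`` (%) and ``retained`` columns to a stride table."""
    out = strides.copy()
    out["sla"] = step_length_asymmetry(
        out["fast_step_cm"].to_numpy(), out["slow_step_cm"].to_numpy()
    )
    if "retained" not in out.columns:
        out["retained"] = True
    return out


def baseline_correct(series: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean retained-Baseline asymmetry from every stride.

    Idempotent once the Baseline mean is zero.
    """
    base = series[(series["phase"] == "Baseline") & series["retained"]]
    if base.empty:
        raise ValueError("no retained Baseline strides to correct against")
    out = series.copy()
    out["sla"] = out["sla"] - base["sla"].mean()
    return out


def remove_outliers(series: pd.DataFrame) -> pd.DataFrame:
    """Flag strides outside ``[Q1 - 3*IQR, Q3 + 3*IQR]`` as not retained.

    Quartiles are computed over the participant's full retained asymmetry
    series. With a degenerate spread (IQR = 0 from ties) the series is
    returned unchanged with a warning.
    """
    sla = series.loc[series["retained"], "sla"]
    if len(sla) < 4:
        raise ValueError("need at least 4 strides for outlier detection")
    q1, q3 = np.percentile(sla, [25, 75])
    iqr = q3 - q1
    out = series.copy()
    if iqr == 0:
        if sla.nunique() > 1:
            warnings.warn("IQR is 0 with ties; no outlier removal applied")
        out["outlier"] = False
        return out
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    flag = series["retained"] & ((series["sla"] < lo) | (series["sla"] > hi))
    out["outlier"] = flag
    out.loc[flag, "retained"] = False
    return out


def removed_fraction(series: pd.DataFrame) -> float:
    """Percent of strides flagged as outliers (0-100)."""
    if "outlier" not in series.columns:
        return 0.0
    return 100.0 * float(series["outlier"].mean())


def drop_first_strides(series: pd.DataFrame) -> pd.DataFrame:
    """Mark stride 1 of every phase as not retained (treadmill acceleration)."""
    for phase, grp in series.groupby("phase"):
        if len(grp) < 2:
            raise ValueError(f"phase {phase!r} has fewer than 2 strides")
    out = series.copy()
    out.loc[out["stride"] == 1, "retained"] = False
    return out


def _phase_perturbation(series: pd.DataFrame, phase: str, reducer) -> float:
    sub = series[(series["phase"] == phase) & series["retained"]]
    if sub.empty:
        raise ValueError(f"no retained strides in phase {phase!r}")
    first10 = sub.head(10)
    if len(first10) < 10:
        warnings.warn(
            f"fewer than 10 retained strides in {phase}; using all {len(first10)}"
        )
    return float(reducer(first10["sla"]))


def adaptation_index(series: pd.DataFrame) -> pd.DataFrame:
    """Compute the Adaptation Index from a baseline-corrected asymmetry series.

    Adds ``condition`` (1 during Adaptation, else 0), ``perturbation``
    (per-phase normalizer, NaN during Baseline) and ``ai`` columns. The
    Baseline phase carries no index (belts tied, no perturbation to
    normalize by).
    """
    for phase in ("Adaptation", "Deadaptation"):
        if not (series["phase"] == phase).any():
            raise ValueError(f"phase {phase!r} missing from series")
    pert_adapt = _phase_perturbation(series, "Adaptation", np.min)
    pert_dead = _phase_perturbation(series, "Deadaptation", np.max)
    if pert_adapt == 0 or pert_dead == 0:
        raise ValueError("degenerate normalization: phase perturbation is 0")

    out = series.copy()
    out["condition"] = (out["phase"] == "Adaptation").astype(int)
    pert = np.full(len(out), np.nan)
    pert[(out["phase"] == "Adaptation").to_numpy()] = pert_adapt
    pert[(out["phase"] == "Deadaptation").to_numpy()] = pert_dead
    out["perturbation"] = pert
    out["ai"] = (out["sla"] - out["condition"] * out["perturbation"]) / np.abs(
        out["perturbation"]
    )
    return out


def preprocess(strides: pd.DataFrame) -> pd.DataFrame:
    """Full single-participant pipeline: asymmetry -> cleaning -> Adaptation Index.

    The perturbation normalizers are estimated after outlier removal but
    before the first-stride drop (see module docstring); the dropped
    strides remain in the table with ``retained == False``.
    """
    out = compute_asymmetry(strides)
    out = baseline_correct(out)
    out = remove_outliers(out)
    out = adaptation_index(out)
    out = drop_first_strides(out)
    return out


def preprocess_cohort(strides: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`preprocess` per participant of a multi-participant table."""
    parts = []
    for _, grp in strides.groupby("participant_id", sort=False):
        parts.append(preprocess(grp.reset_index(drop=True)))
    return pd.concat(parts, ignore_index=True)
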