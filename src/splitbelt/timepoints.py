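"""Behavioral timepoints of the Adaptation Index series.

Four 5-stride windows summarize each participant:

* **Feedback On** — the final five strides of the visual-feedback window
  during Adaptation (explicit + implicit learning),
* **Feedback Off** — the first five strides after the feedback is turned
  off (implicit only),
* **End Adaptation** — the last five Adaptation strides,
* **Implicit Aftereffect** — the first five De-adaptation strides, the
  measure of stored implicit adaptation.

``explicit_magnitude = feedback_on - feedback_off`` quantifies explicit
learning. Windows are defined on raw stride indices and intersected with
retained strides; a window thinned by cleaning shrinks rather than
shifts (e.g. the aftereffect window is typically strides 2-5 after the
first-stride drop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import PhaseSchedule

__all__ = ["TimepointSummary", "TIMEPOINTS", "timepoint_means", "cohort_timepoints",
           "group_summary"]

TIMEPOINTS = ("feedback_on", "feedback_off", "end_adaptation", "implicit_aftereffect")


@dataclass(frozen=True)
class TimepointSummary:
    """Per-participant 5-stride window means (Adaptation Index units)."""

    feedback_on: float
    feedback_off: float
    end_adaptation: float
    implicit_aftereffect: float
    n_strides: dict

    @property
    def explicit_magnitude(self) -> float:
        """Feedback On minus Feedback Off: the behavioral explicit-learning measure."""
        return self.feedback_on - self.feedback_off


def _window_mean(df: pd.DataFrame, phase: str, lo: int, hi: int, name: str):
    sub = df[(df["phase"] == phase) & df["retained"]
             & df["stride"].between(lo, hi)]
    vals = sub["ai"].to_numpy()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn(f"timepoint {name}: window {phase} strides {lo}-{hi} "
                      "fully removed by cleaning")
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def timepoint_means(ai_df: pd.DataFrame, schedule: PhaseSchedule) -> TimepointSummary:
    """Extract the four timepoint means from one participant's AI table.

    ``ai_df`` needs ``phase``, ``stride``, ``ai`` and ``retained``
    columns (the preprocessing output). Fully-removed windows yield NaN
    with a warning.
    """
    fb_lo, fb_hi = schedule.feedback_window
    windows = {
        "feedback_on": ("Adaptation", fb_hi - 4, fb_hi),
        "feedback_off": ("Adaptation", fb_hi + 1, fb_hi + 5),
        "end_adaptation": ("Adaptation", schedule.n_adaptation - 4, schedule.n_adaptation),
        "implicit_aftereffect": ("Deadaptation", 1, 5),
    }
    means, counts = {}, {}
    for name, (phase, lo, hi) in windows.items():
        means[name], counts[name] = _window_mean(ai_df, phase, lo, hi, name)
    return TimepointSummary(**means, n_strides=counts)


def cohort_timepoints(ai_df: pd.DataFrame, schedule: PhaseSchedule) -> pd.DataFrame:
    """Per-participant timepoint table for a multi-participant AI table."""
    rows = []
    for (pid,), grp in ai_df.groupby(["participant_id"], sort=False):
        tp = timepoint_means(grp, schedule)
        row = {"participant_id": pid, "group": grp["group"].iloc[0]}
        for name in TIMEPOINTS:
            row[name] = getattr(tp, name)
        row["explicit_magnitude"] = tp.explicit_magnitude
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(timepoint_df: pd.DataFrame):
    """Group-level summary and the tidy long table for Bayesian contrasts.

    Returns ``(summary, long)``: per-group mean/SD of each timepoint, and
    a long table with columns ``participant_id, group, timepoint, value``.
    """
    if timepoint_df.empty or timepoint_df.groupby("group").size().min() < 1:
        raise ValueError("need at least 1 participant per group")
    long = timepoint_df.melt(
        id_vars=["participant_id", "group"],
        value_vars=list(TIMEPOINTS) + ["explicit_magnitude"],
        var_name="timepoint", value_name="value",
    )
    summary = (
        long.groupby(["group", "timepoint"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return summary, long
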