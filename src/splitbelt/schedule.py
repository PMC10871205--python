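"""Phase schedule for a split-belt adaptation session.

A session is three ordered phases — Baseline (belts tied), Adaptation
(belts split 2:1), De-adaptation (belts tied again) — with a visual
feedback window covering an initial block of Adaptation strides.
"""

from __future__ import annotations

from dataclasses import dataclass

PHASES = ("Baseline", "Adaptation", "Deadaptation")


@dataclass(frozen=True)
class PhaseSchedule:
    """Stride counts per phase plus the feedback window.

    Parameters
    ----------
    n_baseline, n_adaptation, n_deadaptation
        Number of strides in each phase. Defaults approximate 8-minute
        Adaptation / De-adaptation phases at typical belt speeds.
    feedback_window
        1-based inclusive stride range *within Adaptation* during which
        the step-length visual feedback is on. Default: strides 1-40.
    """

    n_baseline: int = 150
    n_adaptation: int = 450
    n_deadaptation: int = 450
    feedback_window: tuple[int, int] = (1, 40)

    def __post_init__(self) -> None:
        for name in ("n_baseline", "n_adaptation", "n_deadaptation"):
            n = getattr(self, name)
            if not (isinstance(n, (int,)) and n > 0):
                raise ValueError(f"{name} must be a positive integer, got {n!r}")
        lo, hi = self.feedback_window
        if not (1 <= lo <= hi <= self.n_adaptation):
            raise ValueError(
                f"feedback_window {self.feedback_window} must lie within "
                f"Adaptation (1..{self.n_adaptation})"
            )

    @property
    def phases(self) -> list[tuple[str, int]]:
        """Ordered (phase name, stride count) pairs."""
        return [
            ("Baseline", self.n_baseline),
            ("Adaptation", self.n_adaptation),
            ("Deadaptation", self.n_deadaptation),
        ]

    @property
    def n_modeled(self) -> int:
        """Strides covered by the learning models (Adaptation + De-adaptation)."""
        return self.n_adaptation + self.n_deadaptation

    def feedback_mask(self) -> "np.ndarray":
        """Boolean mask over the modeled strides: True while feedback is on."""
        import numpy as np

        mask = np.zeros(self.n_modeled, dtype=np.bool_)
        lo, hi = self.feedback_window
        mask[lo - 1 : hi] = True
        return mask

    def perturbation_signal(self) -> "np.ndarray":
        """Model perturbation over the modeled strides: 1 while belts are split."""
        import numpy as np

        sig = np.zeros(self.n_modeled)
        sig[: self.n_adaptation] = 1.0
        return sig
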