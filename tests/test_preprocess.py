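"""Asymmetry computation, cleaning rules and the Adaptation Index."""

import numpy as np
import pandas as pd
import pytest

from splitbelt import (
    PhaseSchedule,
    VCParams,
    adaptation_index,
    baseline_correct,
    drop_first_strides,
    preprocess,
    remove_outliers,
    simulate_participant,
    step_length_asymmetry,
)
from splitbelt.preprocess import compute_asymmetry, removed_fraction


def series_from_sla(sla_by_phase):
    """Build a minimal asymmetry series from {phase: [sla, ...]}."""
    rows = []
    for phase, values in sla_by_phase.items():
        for i, v in enumerate(values, start=1):
            rows.append({"phase": phase, "stride": i, "sla": float(v),
                         "retained": True})
    return pd.DataFrame(rows)


class TestStepLengthAsymmetry:
    @pytest.mark.parametrize("fast,slow,expected", [
        (50, 50, 0.0),
        (60, 40, 20.0),
        (40, 60, -20.0),
    ])
    def test_direct_values(self, fast, slow, expected):
        assert step_length_asymmetry(fast, slow) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            step_length_asymmetry(0.0, 0.0)

    def test_vectorized(self):
        out = step_length_asymmetry([60, 40], [40, 60])
        np.testing.assert_allclose(out, [20, -20])


class TestBaselineCorrect:
    def test_constant_series_zeroed(self):
        s = series_from_sla({"Baseline": [5] * 10, "Adaptation": [5] * 10})
        out = baseline_correct(s)
        assert np.all(out["sla"] == 0)

    def test_shift_by_baseline_mean(self):
        s = series_from_sla({"Baseline": [2] * 10, "Adaptation": [-18]})
        out = baseline_correct(s)
        assert out.loc[out["phase"] == "Adaptation", "sla"].iloc[0] == pytest.approx(-20)

    def test_idempotent_after_first_pass(self):
        rng = np.random.default_rng(0)
        s = series_from_sla({"Baseline": rng.normal(3, 1, 20),
                             "Adaptation": rng.normal(-15, 2, 20)})
        once = baseline_correct(s)
        twice = baseline_correct(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(series_from_sla({"Adaptation": [1, 2]}))


class TestRemoveOutliers:
    def test_extreme_point_removed(self):
        rng = np.random.default_rng(1)
        vals = list(rng.normal(0, 1, 49)) + [100.0]
        out = remove_outliers(series_from_sla({"Adaptation": vals}))
        assert not out["retained"].iloc[49]
        assert out["retained"][:49].all()
        assert removed_fraction(out) == pytest.approx(2.0)

    def test_identical_strides_untouched(self):
        out = remove_outliers(series_from_sla({"Adaptation": [3.0] * 20}))
        assert out["retained"].all()

    def test_no_inlier_removed(self):
        rng = np.random.default_rng(2)
        s = series_from_sla({"Adaptation": rng.normal(0, 1, 200)})
        out = remove_outliers(s)
        q1, q3 = np.percentile(s["sla"], [25, 75])
        iqr = q3 - q1
        inside = (s["sla"] >= q1 - 3 * iqr) & (s["sla"] <= q3 + 3 * iqr)
        assert out.loc[inside, "retained"].all()
        assert removed_fraction(out) == pytest.approx(
            100 * (~out["retained"]).mean())

    def test_too_few_strides_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(series_from_sla({"Adaptation": [1, 2, 3]}))

    def test_clean_synthetic_removal_rate_low(self, short_schedule):
        """Gaussian stride noise alone rarely breaches the 3xIQR fence."""
        params = VCParams(0.92, 0.03, 0.996, 0.004, 0.2)
        fracs = []
        for seed in range(50):
            df = simulate_participant(params, short_schedule, noise_sd=0.05,
                                      seed=seed)
            s = compute_asymmetry(df)
            s = baseline_correct(s)
            fracs.append(removed_fraction(remove_outliers(s)))
        assert np.mean(fracs) < 3.0


class TestDropFirstStrides:
    def test_counts_and_idempotence(self):
        s = series_from_sla({p: range(10) for p in
                             ("Baseline", "Adaptation", "Deadaptation")})
        out = drop_first_strides(s)
        assert int(out["retained"].sum()) == 27
        pd.testing.assert_frame_equal(drop_first_strides(out), out)
        assert list(out["phase"]) == list(s["phase"])

    def test_single_stride_phase_rejected(self):
        with pytest.raises(ValueError):
            drop_first_strides(series_from_sla({"Baseline": [0], "Adaptation": [1, 2]}))


class TestAdaptationIndex:
    def make_series(self):
        # Adaptation perturbation (min of first 10) = -20; De-adaptation max = +15
        adapt = [-20, -18, -16, -10, -5, -2, 0, -1, -3, -4, 0.0]
        dead = [15, 12, 10, 8, 6, 5, 4, 3, 2, 1, 0.0]
        return series_from_sla({"Adaptation": adapt, "Deadaptation": dead})

    def test_adaptation_scale(self):
        out = adaptation_index(self.make_series())
        ad = out[out["phase"] == "Adaptation"]
        assert ad["ai"].iloc[0] == pytest.approx(0.0)   # at the perturbation
        assert ad["ai"].iloc[6] == pytest.approx(1.0)   # fully corrected
        assert (ad["condition"] == 1).all()

    def test_deadaptation_scale_reversed(self):
        out = adaptation_index(self.make_series())
        de = out[out["phase"] == "Deadaptation"]
        assert de["ai"].iloc[0] == pytest.approx(1.0)   # at the aftereffect peak
        assert de["ai"].iloc[-1] == pytest.approx(0.0)  # back to symmetry
        assert (de["condition"] == 0).all()

    def test_constant_shift_invariance(self):
        """Adding a constant before baseline correction leaves the index unchanged."""
        rng = np.random.default_rng(3)
        base = series_from_sla({
            "Baseline": rng.normal(0, 1, 20),
            "Adaptation": rng.normal(-15, 3, 30),
            "Deadaptation": rng.normal(10, 3, 30),
        })
        shifted = base.copy()
        shifted["sla"] = shifted["sla"] + 7.5
        a = adaptation_index(baseline_correct(base))
        b = adaptation_index(baseline_correct(shifted))
        np.testing.assert_allclose(a["ai"], b["ai"], atol=1e-10)

    def test_zero_perturbation_rejected(self):
        s = series_from_sla({"Adaptation": [0.0] * 12, "Deadaptation": [1.0] * 12})
        with pytest.raises(ValueError):
            adaptation_index(s)

    def test_short_phase_warns(self):
        s = series_from_sla({"Adaptation": [-20, -10, 0, -5, -2],
                             "Deadaptation": [10, 5, 2, 1, 0]})
        with pytest.warns(UserWarning, match="fewer than 10"):
            adaptation_index(s)


class TestRoundTrip:
    def test_noise_free_pipeline_recovers_latent(self, short_schedule):
        """Generator inversion and index computation are exact inverses."""
        params = VCParams(0.92, 0.03, 0.996, 0.004, 0.25)
        df = simulate_participant(params, short_schedule, noise_sd=0.0, seed=0)
        out = preprocess(df)
        mod = out[out["phase"].isin(["Adaptation", "Deadaptation"]) & out["retained"]]
        err = np.abs(mod["ai"].to_numpy() - mod["ai_latent"].to_numpy())
        assert err.max() <= 1e-8

    def test_pipeline_keeps_stride_bookkeeping(self, short_schedule, paper_params):
        df = simulate_participant(paper_params, short_schedule, noise_sd=0.05, seed=4)
        out = preprocess(df)
        assert len(out) == len(df)
        # first stride of every phase dropped
        assert not out.loc[out["stride"] == 1, "retained"].any()
        # stride indices contiguous within phases
        for _, grp in out.groupby("phase"):
            assert list(grp["stride"]) == list(range(1, len(grp) + 1))
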