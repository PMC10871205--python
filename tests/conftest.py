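import pandas as pd
import pytest

from splitbelt import PhaseSchedule, VCParams, default_cohort_config, simulate_cohort


@pytest.fixture(scope="session")
def schedule():
    return PhaseSchedule()


@pytest.fixture(scope="session")
def short_schedule():
    """Small schedule for fast end-to-end tests."""
    return PhaseSchedule(n_baseline=30, n_adaptation=120, n_deadaptation=100,
                         feedback_window=(1, 40))


@pytest.fixture(scope="session")
def paper_params():
    """Literature initialization values with a moderate explicit rate."""
    return VCParams(0.92, 0.03, 0.996, 0.004, 0.2)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy two-group cohort shared across tests."""
    cfg = default_cohort_config(seed=11, n_control=4, n_stroke=4)
    return simulate_cohort(cfg)


def make_group_time_data(rng, effects=(0.5, 0.1, 0.05, 0.09), sd=0.1,
                         n_per_group=(18, 17)):
    """Balanced 2x2 dataset; effects = (intercept, group, time, interaction)."""
    b0, bg, bt, bgt = effects
    rows = []
    for g, gi, n in (("control", -0.5, n_per_group[0]), ("stroke", 0.5, n_per_group[1])):
        for t, ti in (("FeedbackOff", -0.5), ("FeedbackOn", 0.5)):
            mu = b0 + bg * gi + bt * ti + bgt * gi * ti
            for i in range(n):
                rows.append({"participant": f"{g}{i}", "group": g, "time": t,
                             "value": rng.normal(mu, sd)})
    return pd.DataFrame(rows)
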