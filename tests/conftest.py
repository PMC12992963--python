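import numpy as np
import pandas as pd
import pytest

from timingpriors.design import LONG_PRIOR, SHORT_PRIOR
from timingpriors.observer import predict_from_ratio
from timingpriors.pipeline import PipelineConfig, simulate_trials
from timingpriors.preprocess import preprocess

TS_SHORT = np.asarray(SHORT_PRIOR.support)
TS_LONG = np.asarray(LONG_PRIOR.support)
TS_ALL = np.concatenate([TS_SHORT, TS_LONG])


def curve_points(mu_short, mu_long, r_short, r_long, noise=0.0, rng=None):
    """(t_s, t_r_mean) table generated from known two-prior curves."""
    y_s = predict_from_ratio(TS_SHORT, mu_short, r_short)
    y_l = predict_from_ratio(TS_LONG, mu_long, r_long)
    y = np.concatenate([y_s, y_l])
    if noise:
        y = y + rng.normal(0.0, noise, size=y.size)
    return pd.DataFrame(
        {
            "prior_label": ["short"] * 5 + ["long"] * 5,
            "t_s": TS_ALL,
            "t_r_mean": y,
        }
    )


@pytest.fixture(scope="session")
def independent_cohort_run():
    """Simulated 20-participant run with two independent acquired priors.

    Every observer carries the canonical parameters (means 750/1500 ms,
    ratios 237/0.15, w = 0.15, motor SD 50 ms, no bias) so that recovery
    error reflects trial noise and the estimator, not cohort sampling;
    returns (trials, binned, grand).
    """
    from timingpriors.cohort import CohortConfig

    cohort = CohortConfig(
        n_participants=20,
        mu_hat_short=(750.0, 0.0),
        mu_hat_long=(1500.0, 0.0),
        r_short=(237.0 / 0.15, 0.0),
        r_long=(237.0 / 0.15, 0.0),
        w=(0.15, 0.0),
        sigma_motor=(50.0, 0.0),
    )
    cfg = PipelineConfig(seed=11, cohort=cohort)
    trials, _, _ = simulate_trials(cfg)
    _, binned, grand = preprocess(trials)
    return trials, binned, grand


@pytest.fixture(scope="session")
def merged_cohort_run():
    """Simulated 20-participant run with one fully generalized prior.

    The default (heterogeneous) cohort with the acquired prior means fully
    merged (lambda = 1); inter-participant variability provides the noise
    floor against which the one-prior model should win the comparison.
    """
    from timingpriors.cohort import CohortConfig, merged

    cfg = PipelineConfig(seed=12, cohort=merged(CohortConfig()))
    trials, _, _ = simulate_trials(cfg)
    _, binned, grand = preprocess(trials)
    return trials, binned, grand
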