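import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tygdyn as tg

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> tg.SyntheticCohort:
    """A modest synthetic cohort shared by read-only tests."""
    cfg = tg.SyntheticCohortConfig(n_patients=600, seed=7)
    return tg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def standardized_series(small_cohort):
    series, _ = tg.build_series(small_cohort.measurements)
    series, constants = tg.standardize_by_database(series)
    return series, constants


def make_survival_frame(rng, n=400, log_hr=0.0, base_rate=0.08, censor_scale=12.0):
    """Simple exponential survival data with one binary covariate."""
    x = rng.binomial(1, 0.5, n).astype(float)
    t_ev = rng.exponential(1.0 / (base_rate * np.exp(log_hr * x)))
    c = rng.exponential(censor_scale, n)
    return pd.DataFrame(
        {
            "followup_days": np.minimum(t_ev, c),
            "event": (t_ev <= c).astype(int),
            "x": x,
            "grp": np.where(x > 0, "exposed", "reference"),
        }
    )
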