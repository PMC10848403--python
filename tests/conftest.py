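import numpy as np
import pandas as pd
import pytest

import lfevents as lf


@pytest.fixture
def bil_scale():
    return lf.DEFAULT_SCALES["BIL"]


@pytest.fixture
def toy_intervals():
    """Two subjects, one event: the closed-form partial-likelihood case."""
    return pd.DataFrame(
        {
            "cluster_id": [1, 2],
            "start": [0.0, 0.0],
            "stop": [1.0, 2.0],
            "status": [1, 0],
            "x": [1.0, 0.0],
        }
    )


def make_intervals(rng, n_subjects=5, n_cov=2, max_events=2):
    """Random small tie-free interval set for derivative/oracle checks.

    The first three subjects are guaranteed an event and covariates are kept
    moderate so the partial-likelihood maximum stays finite (no separation).
    """
    rows = []
    for i in range(n_subjects):
        x = 0.6 * rng.normal(size=n_cov)
        n_ev = rng.integers(1 if i < 3 else 0, max_events + 1)
        times = np.sort(rng.uniform(0.5, 10.0, size=n_ev))
        censor = times[-1] + rng.uniform(0.1, 3.0) if len(times) else rng.uniform(1, 10)
        prev = 0.0
        for t in times:
            rows.append((i, prev, t, 1, *x))
            prev = t
        rows.append((i, prev, censor, 0, *x))
    cols = ["cluster_id", "start", "stop", "status"] + [f"x{j}" for j in range(n_cov)]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def random_intervals():
    return make_intervals(np.random.default_rng(42))


def simulate_fitted_cohort(seed, n_patients=300, **spec_kwargs):
    """Event-tier cohort with default effects, as counting-process intervals."""
    spec = lf.CohortSpec(
        n_patients=n_patients, seed=seed, dropout_rate=0.0, max_months=24, **spec_kwargs
    )
    cov = lf.simulate_covariates(spec)
    events, fu = lf.simulate_recurrent_events(spec, cov)
    intervals = lf.build_intervals(
        events, fu, cov, scope=spec.composite, covariate_cols=["score", "female"]
    )
    return spec, cov, events, fu, intervals
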