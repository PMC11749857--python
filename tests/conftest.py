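import logging

import numpy as np
import pytest

import litbayes as lb

# The hierarchical fits used in tests intentionally run at desk scale; the
# package logs (not raises) marginal diagnostics, which would swamp test output.
logging.getLogger("py.warnings").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort():
    """Default 12-factor synthetic cohort (n = 2000) with ground truth."""
    cfg = lb.default_cohort_template(seed=3)
    return lb.generate_patient_table(cfg)


@pytest.fixture(scope="session")
def cohort_fit(cohort):
    """Reference posterior on the default cohort, shared across tests."""
    design = lb.build_design(cohort, cohort.factor_names)
    fit = lb.sample_posterior(design, cohort.outcome, chains=2,
                              iterations=800, warmup=400, seed=11)
    return cohort, design, fit


@pytest.fixture(scope="session")
def toy_effects():
    """Five-study effect estimates used for grid-versus-MCMC comparisons."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "label": [f"s{i}" for i in range(5)],
            "d1": [50, 30, 60, 45, 80],
            "n1": [100, 60, 110, 90, 150],
            "d0": [25, 20, 40, 30, 50],
            "n0": [100, 60, 110, 90, 150],
        }
    )
    return lb.compute_effects(lb.StudyTable(df))


def iid_normal_draws(n_chains=4, n_iter=1000, dim=1, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_chains, n_iter, dim))
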