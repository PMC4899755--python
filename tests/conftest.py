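import numpy as np
import pytest

import bsignal as b
from bsignal.presets import demo_feedback_inputs, demo_kinase_params, demo_model_b_params

KINASE_GRID = np.arange(0.0, 121.0, 10.0)
REGIMES = ("no_feedback", "no_positive", "full")


@pytest.fixture(scope="session")
def p0():
    return demo_kinase_params()


@pytest.fixture(scope="session")
def model_b_params():
    return demo_model_b_params()


@pytest.fixture(scope="session")
def feedback_inputs():
    return demo_feedback_inputs(KINASE_GRID)


@pytest.fixture(scope="session")
def clean_datasets(p0, feedback_inputs):
    """Noiseless kinase time courses for all three perturbation regimes."""
    pf, nf = feedback_inputs
    return {
        r: b.generate_true_kinase_timecourse(p0, pf, nf, regime=r, grid=KINASE_GRID)
        for r in REGIMES
    }


@pytest.fixture(scope="session")
def fit_problem(clean_datasets, feedback_inputs):
    pf, nf = feedback_inputs
    return b.FitProblem(datasets=dict(clean_datasets), pf=pf, nf=nf, n_starts=8, seed=3)
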