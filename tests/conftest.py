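import numpy as np
import pandas as pd
import pytest

import methylpace as mp


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized noisy cohort with ground truth (default design constants)."""
    return mp.simulate_longitudinal_cohort(mp.SimCohortConfig(n_subjects=120, seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = mp.SimCohortConfig(
        n_subjects=40, seed=7, residual_sd=0.0, slope_dev_sd=0.0
    )
    return mp.simulate_longitudinal_cohort(cfg)


@pytest.fixture(scope="session")
def meth_small():
    """150-sample, 400-probe methylation fixture with 25 causal probes."""
    rng = np.random.default_rng(5)
    pace = pd.Series(
        1 + rng.normal(0, 0.29, 150), index=[f"S{i:03d}" for i in range(150)]
    )
    betas, truth = mp.simulate_methylation(pace, n_probes=400, n_causal=25, seed=6)
    return pace, betas, truth


@pytest.fixture(scope="session")
def tiny_model(meth_small):
    pace, betas, _ = meth_small
    weights = mp.train_elastic_net(
        betas, pace, betas.index, mp.TrainerConfig(cv_folds=5, seed=7)
    )
    panel = mp.build_reference_panel(weights, betas, panel_size=300, seed=8)
    return mp.TrainedModel(weights, panel)
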