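"""Shared fixtures.

The expensive end-to-end fixtures (grey-box + symbolic-regression pipelines
at several noise levels) are session-scoped so the acceptance tests can
share a single set of runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from odclearn.evaluation import run_pipeline
from odclearn.synthetic import SyntheticStudyConfig, generate_dataset
from odclearn import symreg

PIPELINE_SEEDS = (1, 2, 3, 4, 5)

#: reduced budgets for the mid/high-noise repetitions; the low-noise runs
#: use the default budget
SCALED_SR = dict(population_size=112, generations=14)
SCALED_NN = dict(restarts=4)


@pytest.fixture()
def rng():
    """Fresh, fixed-seed generator per test, so tests stay order-independent."""
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-point study at 5% noise for cheap unit tests."""
    config = SyntheticStudyConfig(n_train=50, n_val=10, seed=7)
    return generate_dataset(config, 0.05, seed=7)


def _run_level(noise_level, seeds, sr_kwargs=None, nn_kwargs=None):
    from odclearn import greybox

    out = []
    for seed in seeds:
        config = SyntheticStudyConfig(seed=seed)
        dataset = generate_dataset(config, noise_level, seed=seed)
        sr_config = symreg.SRConfig(seed=seed, **(sr_kwargs or {}))
        nn_config = (
            greybox.TrainingConfig(seed=seed, **nn_kwargs) if nn_kwargs else None
        )
        out.append(
            run_pipeline(
                dataset,
                seed=seed,
                fit_gp=False,
                sr_config=sr_config,
                nn_config=nn_config,
                noise_level=noise_level,
            )
        )
    return out


@pytest.fixture(scope="session")
def pipeline_runs_2pct():
    """Five seeded grey-box + SR pipelines at 2% noise (default SR budget)."""
    return _run_level(0.02, PIPELINE_SEEDS)


@pytest.fixture(scope="session")
def pipeline_runs_5pct():
    return _run_level(0.05, PIPELINE_SEEDS, SCALED_SR, SCALED_NN)


@pytest.fixture(scope="session")
def pipeline_runs_10pct():
    # full budget: at this noise level the reduced search is not reliable
    return _run_level(0.10, PIPELINE_SEEDS)


@pytest.fixture(scope="session")
def pipeline_run_15pct():
    return _run_level(0.15, (PIPELINE_SEEDS[0],), SCALED_SR, SCALED_NN)[0]
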