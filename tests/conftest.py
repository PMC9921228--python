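"""Shared fixtures: small synthetic cohorts and fitted models.

Expensive fixtures are session-scoped; every test works on the same
deterministic cohort unless it needs its own conditions.
"""

import warnings

import numpy as np
import pytest

import jcmica as j

COHORT_SEED = 42


@pytest.fixture(scope="session")
def truth():
    """Default study conditions: 4 shared + 2 FC-only + 2 SC-only sources."""
    return j.make_ground_truth((12, 12, 6), (10, 10, 6), 4, 2, 2, seed=COHORT_SEED, n_subjects=10)


@pytest.fixture(scope="session")
def cohort(truth):
    return j.simulate_cohort(
        truth, 10, t_len=300, noise_sd=0.5, mean_count=20.0, seed=COHORT_SEED
    )


@pytest.fixture(scope="session")
def fitted(truth, cohort):
    """Joint model at the reference order (c = 8) plus subject factors."""
    fmri, sc = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, reduced = j.fit_joint_cmica(
            fmri,
            sc,
            subject_r=4,
            m_per_modality=4,
            icasso_runs=10,
            seed=COHORT_SEED,
            return_reduced=True,
        )
    return model, reduced


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
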