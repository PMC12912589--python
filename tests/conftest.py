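import numpy as np
import pytest

from psimap.synthdata import (
    TruthFieldSpec, generate_admin_hierarchy, generate_covariates,
    generate_truth_and_survey,
)


@pytest.fixture(scope="session")
def small_hierarchy():
    """2 provinces x 2 districts on a 40 x 40 km extent."""
    return generate_admin_hierarchy(2, 2, (40_000.0, 40_000.0), seed=7)


@pytest.fixture(scope="session")
def small_stack(small_hierarchy):
    """11-layer covariate stack at 1 km cells (40 x 40 grid)."""
    return generate_covariates(small_hierarchy, cell_m=1000.0, seed=11)


@pytest.fixture(scope="session")
def small_survey(small_hierarchy, small_stack):
    """Two-component survey (one per direction) with modest sizes."""
    specs = [
        TruthFieldSpec("owns_car", "HSLS", -0.8, {"ACCESS": 0.9}, 15_000.0, 0.5,
                       table="households"),
        TruthFieldSpec("sickness", "HSHS", -1.2, {"LST": 0.7}, 15_000.0, 0.5,
                       table="roster"),
    ]
    survey, truths = generate_truth_and_survey(
        small_hierarchy, small_stack, specs, n_clusters=60,
        households_per_cluster=12, mask_jitter_m=1000.0, seed=13)
    return survey, truths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
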