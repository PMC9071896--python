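import numpy as np
import pandas as pd
import pytest

from tmescore import simulate


@pytest.fixture(scope="session")
def signature():
    """A 10-type, 150-gene synthetic cell-type signature matrix."""
    return simulate.synthetic_signature_matrix(
        n_cell_types=10, markers_per_type=15, seed=0
    )


@pytest.fixture(scope="session")
def planted_cohort(signature):
    """n=60 cohort with 3 separated clusters, markers and a protective axis."""
    expr, clin, truth = simulate.simulate_cohort(
        60, 40, 3, signature,
        cluster_separation=3.0, de_effect_log2fc=2.0,
        hazard_beta=-1.0, censor_rate=0.3, noise_sd=0.3, seed=11,
    )
    return expr, clin, truth


@pytest.fixture(scope="session")
def survival_cohort(signature):
    """n=300 protective-axis cohort used for survival-direction checks."""
    expr, clin, truth = simulate.simulate_cohort(
        300, 40, 3, signature,
        cluster_separation=3.0, de_effect_log2fc=2.0,
        hazard_beta=-1.0, censor_rate=0.3, noise_sd=0.3, seed=7,
    )
    return expr, clin, truth
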