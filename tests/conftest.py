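import numpy as np
import pytest

from neurogsp import (
    SyntheticConfig,
    eigendecompose,
    gen_cohort,
    validate_connectome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def p3_basis():
    """Path graph 1-2-3 with unit weights; spectrum (-sqrt2, 0, sqrt2)."""
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return eigendecompose(validate_connectome(A, ["a", "b", "c"], "p3"))


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject synthetic cohort with one planted low-band NfL feature."""
    cfg = SyntheticConfig(
        n_subjects=6,
        planted=(("rh_isthmuscingulate", "low", 1.0),),
        nfl_age_beta=0.0,
        nfl_noise_sd=1.0,
    )
    return gen_cohort(cfg, seed=99)


def random_connectome(rng, n=66, subject_id="rand"):
    """Dense random nonnegative symmetric test matrix."""
    G = np.abs(rng.standard_normal((n, n)))
    A = G + G.T
    np.fill_diagonal(A, 0.0)
    return validate_connectome(A, [f"r{i:02d}" for i in range(n)], subject_id)
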