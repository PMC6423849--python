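import numpy as np
import pytest

from replis import ChmmParams, ZMatrix


def random_chmm_params(rng: np.random.Generator, num_studies: int = 2) -> ChmmParams:
    """A random valid parameter set (Dirichlet rows, moderate effects)."""
    S = 2 ** num_studies
    return ChmmParams(
        pi=rng.dirichlet(np.ones(S)),
        A=rng.dirichlet(np.ones(S), size=S),
        alt_means=rng.uniform(1.0, 4.0, num_studies),
        alt_sds=rng.uniform(0.5, 2.0, num_studies),
    )


def random_zmatrix(rng: np.random.Generator, m: int, num_studies: int = 2) -> ZMatrix:
    return ZMatrix(rng.normal(scale=2.0, size=(m, num_studies)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
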