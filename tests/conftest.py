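import numpy as np
import pytest

from bvarburden import (
    DGPSpec,
    MinnesotaHyperparams,
    VARSpec,
    generate_var_panel,
)

BIVAR1 = {
    "coefficients": [np.array([[0.5, 0.1], [0.2, 0.4]])],
    "drift": np.array([0.5, 0.3]),
    "noise_covariance": np.array([[1.0, 0.3], [0.3, 0.8]]),
}


def make_panel(t_length=80, seed=7, **overrides):
    """Stable bivariate VAR(1) panel used across test modules."""
    params = {**BIVAR1, **overrides}
    n = params["drift"].shape[0]
    q = len(params["coefficients"])
    dgp = DGPSpec(
        n_variables=n,
        order=q,
        coefficients=params["coefficients"],
        drift=params["drift"],
        noise_covariance=params["noise_covariance"],
        initial_values=np.zeros((q, n)),
        length=t_length,
        seed=seed,
    )
    return generate_var_panel(dgp)


@pytest.fixture
def bivariate_panel():
    return make_panel()


@pytest.fixture
def long_bivariate_panel():
    return make_panel(t_length=300, seed=11)


@pytest.fixture
def var1_spec():
    return VARSpec(order=1)


@pytest.fixture
def loose_hyper():
    return MinnesotaHyperparams(lambda1=10.0, lambda2=1.0, lambda3=10.0,
                                lambda4=1.0)


@pytest.fixture
def moderate_hyper():
    return MinnesotaHyperparams(lambda1=0.2, lambda2=0.5, lambda3=1.0,
                                lambda4=1.0)
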