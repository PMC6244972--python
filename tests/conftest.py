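import numpy as np
import pytest

from pkpdkit.pk_model import PKParameters, human_default_params, mouse_default_params
from pkpdkit.tumor_pd import PDParameters, pd_default_params


@pytest.fixture(scope="session")
def human_params() -> PKParameters:
    return human_default_params()


@pytest.fixture(scope="session")
def mouse_params() -> PKParameters:
    return mouse_default_params()


@pytest.fixture(scope="session")
def tumor_params() -> PDParameters:
    return pd_default_params()


def biexponential_bolus(params: PKParameters, dose: float, times: np.ndarray) -> np.ndarray:
    """Closed-form concentration after an i.v. bolus for the linear
    (Vmax = 0) two-compartment model, via the macro-constants.

    Independent oracle: works from the textbook alpha/beta hybrid rate
    constants, not from the package's ODE machinery.
    """
    k10 = params.CL / params.V1
    k12 = params.Q / params.V1
    k21 = params.Q / params.V2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    c0 = dose / params.V1
    a_coef = c0 * (alpha - k21) / (alpha - beta)
    b_coef = c0 * (k21 - beta) / (alpha - beta)
    return a_coef * np.exp(-alpha * times) + b_coef * np.exp(-beta * times)
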