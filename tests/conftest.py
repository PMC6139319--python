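import numpy as np
import pytest

import ctloop as cl


@pytest.fixture(scope="session")
def params():
    return cl.default_parameters()


@pytest.fixture(scope="session")
def fr_en(params):
    return cl.frequency_response(
        cl.transfer_function(params, "e"), cl.default_grid()
    )


@pytest.fixture(scope="session")
def model6_en(fr_en):
    return cl.fit_rational(fr_en, 6)


@pytest.fixture(scope="session")
def model16_en(fr_en):
    return cl.fit_rational(fr_en, 16)


@pytest.fixture(scope="session")
def band_filters_en(model6_en):
    return cl.identify_bands(cl.band_decompose(model6_en))


def linear_system_solve(params, s, target):
    """Independent oracle: solve the 4-unknown linear perturbation system
    (phi_e, phi_i, phi_r, phi_s) directly at complex frequency s for unit
    external drive, without any closed-form elimination."""
    G = params.G
    L = 1.0 / ((1.0 + s / params.alpha) * (1.0 + s / params.beta))
    Dee = (1.0 + s / params.gamma_e) ** 2
    e_se = np.exp(-s * params.tau_se)
    e_es = np.exp(-s * params.tau_es)
    A = np.array(
        [
            # cortical excitatory: Dee phi_e = G_ee L phi_e + G_ei L phi_i
            #                                  + G_es L e^{-s tau_es} phi_s
            [Dee - G("ee") * L, -G("ei") * L, 0.0, -G("es") * L * e_es],
            # cortical inhibitory
            [-G("ie") * L, 1.0 - G("ii") * L, 0.0, -G("is") * L * e_es],
            # reticular nucleus
            [-G("re") * L * e_se, 0.0, 1.0, -G("rs") * L],
            # relay nuclei (driven by phi_n = 1)
            [-G("se") * L * e_se, 0.0, -G("sr") * L, 1.0],
        ],
        dtype=complex,
    )
    b = np.array([0.0, 0.0, 0.0, G("sn") * L], dtype=complex)
    x = np.linalg.solve(A, b)
    return x["eirs".index(target)]


@pytest.fixture(scope="session")
def oracle():
    return linear_system_solve
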