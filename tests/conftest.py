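import numpy as np
import pytest

import epichaos as ec

#: output grid shared by the obesity-model fixtures (weeks); includes the
#: reporting times 520/572/780 (years 2010/2011/2015).
OBESITY_TIMES = np.unique(np.concatenate([np.arange(0.0, 801.0, 20.0), [520.0, 572.0, 780.0]]))


@pytest.fixture(scope="session")
def basis42():
    """Order-2 Legendre chaos basis over four germ dimensions (15 functions)."""
    return ec.generate_multi_indices(4, 2)


@pytest.fixture(scope="session")
def tensors42(basis42):
    return ec.build_inner_product_tensors(basis42)


@pytest.fixture(scope="session")
def obesity_params(basis42):
    """Obesity parameter set, transmission parameters Uniform(0, 2*theta_hat)."""
    return ec.obesity_parameter_set(random=True).bind_chaos(basis42)


@pytest.fixture(scope="session")
def obesity_params_fixed():
    return ec.obesity_parameter_set(random=False)


@pytest.fixture(scope="session")
def reduced_model(obesity_params):
    return ec.build_obesity_model("reduced", obesity_params)


@pytest.fixture(scope="session")
def full_model(obesity_params):
    return ec.build_obesity_model("full", obesity_params)


@pytest.fixture(scope="session")
def chaos_solution(reduced_model, obesity_params, basis42, tensors42):
    """Reduced-form Galerkin solve of the obesity model over [0, 800] weeks."""
    system = ec.assemble_galerkin(reduced_model, obesity_params, basis42, tensors42)
    return ec.integrate_chaos(system, 800.0, OBESITY_TIMES)


@pytest.fixture(scope="session")
def deterministic_solution(obesity_params_fixed):
    model = ec.build_obesity_model("full", obesity_params_fixed)
    return ec.solve_deterministic(model, obesity_params_fixed.means(), OBESITY_TIMES)
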