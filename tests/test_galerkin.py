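"""Stochastic-Galerkin assembly and integration.

Oracles: exact symbolic projection matrices (sympy) for a scalar linear
model, high-resolution quadrature projection of its closed-form solution,
and the deterministic solver in the zero-width limit.
"""

import itertools

import numpy as np
import pytest
import sympy

import epichaos as ec
from epichaos.epidemic_model import PolynomialODEModel, RHSTerm
from epichaos.random_params import ParameterSet, RandomParameter, deterministic


def make_decay_model(x0=1.0):
    """dX/dt = -theta X with theta ~ Uniform(0.05, 0.15) on one germ."""
    model = PolynomialODEModel(
        states=("X",),
        initial_values=(x0,),
        terms={"X": (RHSTerm(-1, ("theta",), 1.0, ("X",)),)},
    )
    params = ParameterSet.from_parameters(
        RandomParameter("theta", 0.05, 0.15, germ_dim=0)
    )
    return model, params


class TestAssembly:
    def test_reduced_obesity_has_thirty_unknowns(
        self, reduced_model, obesity_params, basis42, tensors42
    ):
        system = ec.assemble_galerkin(reduced_model, obesity_params, basis42, tensors42)
        assert system.n_unknowns == 30

    def test_degenerate_parameters_reduce_to_deterministic_block(
        self, basis42, tensors42, obesity_params_fixed
    ):
        """Zero-width parameters: mode-0 equations equal the deterministic RHS
        and all higher modes stay identically zero."""
        model = ec.build_obesity_model("reduced", obesity_params_fixed)
        system = ec.assemble_galerkin(model, obesity_params_fixed, basis42, tensors42)
        y = system.initial_coefficients()
        dy = system.rhs(0.0, y).reshape(2, len(basis42))
        det = ec.eval_rhs(model, [0.362, 0.116], obesity_params_fixed.means())
        np.testing.assert_allclose(dy[:, 0], det, rtol=1e-14)
        np.testing.assert_allclose(dy[:, 1:], 0.0, atol=1e-18)

    def test_linear_model_matches_hand_projection(self):
        """Assembled coefficient equations for dX/dt = -theta X equal the
        symbolically derived projection  dx_L = -(1/n_L) sum_ij theta_i x_j E3[ijL]."""
        model, params = make_decay_model()
        basis = ec.generate_multi_indices(1, 2)
        tensors = ec.build_inner_product_tensors(basis)
        bound = params.bind_chaos(basis)
        system = ec.assemble_galerkin(model, bound, basis, tensors)

        xi = sympy.Symbol("xi")
        m3 = {
            (a, b, c): sympy.Rational(1, 2)
            * sympy.integrate(
                sympy.legendre(a, xi) * sympy.legendre(b, xi) * sympy.legendre(c, xi),
                (xi, -1, 1),
            )
            for a, b, c in itertools.product(range(3), repeat=3)
        }
        theta = {0: sympy.Rational(1, 10), 1: sympy.Rational(1, 20), 2: 0}
        norms = {L: sympy.Rational(1, 2 * L + 1) for L in range(3)}
        M = np.array(
            [
                [
                    float(-sum(theta[i] * m3[(i, j, L)] for i in range(3)) / norms[L])
                    for j in range(3)
                ]
                for L in range(3)
            ]
        )
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=3)
            np.testing.assert_allclose(system.rhs(0.0, x), M @ x, rtol=0, atol=1e-13)

    def test_rejects_mismatched_tensors(self, reduced_model, obesity_params, basis42):
        wrong = ec.build_inner_product_tensors(ec.generate_multi_indices(4, 1))
        with pytest.raises(ValueError):
            ec.assemble_galerkin(reduced_model, obesity_params, basis42, wrong)


class TestIntegration:
    def test_deterministic_limit_equals_deterministic_solve(
        self, basis42, tensors42, obesity_params_fixed, deterministic_solution
    ):
        """All widths zero: mode-0 trajectories match solve_deterministic to
        1e-8 and the higher modes stay below 1e-10."""
        model = ec.build_obesity_model("reduced", obesity_params_fixed)
        system = ec.assemble_galerkin(model, obesity_params_fixed, basis42, tensors42)
        times = deterministic_solution["time"]
        sol = ec.integrate_chaos(system, 800.0, times)
        for state in ("S", "O"):
            C = sol.coefficients(state)
            np.testing.assert_allclose(
                C[:, 0], deterministic_solution[state], atol=1e-8, rtol=0
            )
            assert np.abs(C[:, 1:]).max() <= 1e-10

    def test_initial_coefficients_are_deterministic(self, chaos_solution):
        for state in ("S", "O"):
            c0 = chaos_solution.coefficients(state)[0]
            assert c0[0] == pytest.approx(
                {"S": 0.362, "O": 0.116}[state], abs=1e-12
            )
            assert np.all(c0[1:] == 0.0)

    def test_closure_consistency(self, chaos_solution):
        """Derived N coefficients satisfy N_0+S_0+O_0 = 1, N_i+S_i+O_i = 0."""
        total = (
            chaos_solution.coefficients("N")
            + chaos_solution.coefficients("S")
            + chaos_solution.coefficients("O")
        )
        np.testing.assert_allclose(total[:, 0], 1.0, atol=1e-12, rtol=0)
        np.testing.assert_allclose(total[:, 1:], 0.0, atol=1e-12, rtol=0)

    def test_linear_model_matches_quadrature_projection(self):
        """Chaos trajectories vs projection of the exact X(t) = e^{-theta t},
        computed by high-resolution Gauss-Legendre quadrature over theta."""
        model, params = make_decay_model()
        basis = ec.generate_multi_indices(1, 6)
        tensors = ec.build_inner_product_tensors(basis)
        bound = params.bind_chaos(basis)
        system = ec.assemble_galerkin(model, bound, basis, tensors)
        times = np.array([0.0, 2.0, 5.0, 10.0])
        sol = ec.integrate_chaos(system, 10.0, times)

        nodes, weights = np.polynomial.legendre.leggauss(60)
        theta = 0.1 + 0.05 * nodes
        from scipy.special import eval_legendre

        C = sol.coefficients("X")
        for k, t in enumerate(times):
            x_exact = np.exp(-theta * t)
            for i in range(len(basis)):
                proj = np.sum(weights / 2.0 * x_exact * eval_legendre(i, nodes))
                proj /= basis.norms_sq[i]
                assert C[k, i] == pytest.approx(proj, abs=2e-7)

    def test_full_and_reduced_chaos_agree(
        self, obesity_params, basis42, tensors42, chaos_solution
    ):
        """The 3-state Galerkin form reproduces the reduced form's coefficients."""
        full = ec.build_obesity_model("full", obesity_params)
        system = ec.assemble_galerkin(full, obesity_params, basis42, tensors42)
        times = np.array([0.0, 260.0, 520.0, 780.0])
        sol_full = ec.integrate_chaos(system, 800.0, times)
        for state in ("N", "S", "O"):
            got = sol_full.coefficients(state)
            want = np.stack([chaos_solution.at_time(state, t) for t in times])
            np.testing.assert_allclose(got, want, atol=5e-8)

    def test_order_two_and_three_means_agree(self, obesity_params):
        """Truncation robustness: order-2 vs order-3 means at t = 520 differ
        by far less than 0.1 percentage points."""
        means = {}
        for order in (2, 3):
            basis = ec.generate_multi_indices(4, order)
            tensors = ec.build_inner_product_tensors(basis)
            ps = ec.obesity_parameter_set(random=True).bind_chaos(basis)
            model = ec.build_obesity_model("reduced", ps)
            sol = ec.integrate_chaos(
                ec.assemble_galerkin(model, ps, basis, tensors), 520.0, [520.0]
            )
            means[order] = {s: sol.at_time(s, 520.0)[0] for s in ("S", "O")}
        for state in ("S", "O"):
            assert abs(means[2][state] - means[3][state]) < 0.001

    def test_output_time_validation(
        self, reduced_model, obesity_params, basis42, tensors42
    ):
        system = ec.assemble_galerkin(reduced_model, obesity_params, basis42, tensors42)
        with pytest.raises(ValueError):
            ec.integrate_chaos(system, -1.0, [0.0])
        with pytest.raises(ValueError):
            ec.integrate_chaos(system, 10.0, [0.0, 20.0])


class TestDeterministicSolve:
    @pytest.mark.parametrize(
        "t, state, expected",
        [(520.0, "S", 0.3786), (520.0, "O", 0.1520), (572.0, "S", 0.3799), (572.0, "O", 0.1552)],
    )
    def test_printed_prevalences(self, deterministic_solution, t, state, expected):
        i = np.nonzero(np.isclose(deterministic_solution["time"], t))[0][0]
        assert deterministic_solution[state][i] == pytest.approx(expected, abs=5e-5)

    def test_time_zero_returns_initial_conditions(self, obesity_params_fixed):
        model = ec.build_obesity_model("full", obesity_params_fixed)
        out = ec.solve_deterministic(model, obesity_params_fixed.means(), [0.0])
        assert out["N"][0] == 0.522
        assert out["S"][0] == 0.362
        assert out["O"][0] == 0.116

    def test_tidy_export_schema(self, chaos_solution):
        frame = chaos_solution.to_frame()
        assert list(frame.columns) == ["time", "state", "coefficient_index", "value"]
        assert set(frame["state"]) == {"S", "O", "N"}
        assert frame["coefficient_index"].max() == 14
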