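"""Intrusive stochastic-Galerkin assembly and integration.

Substituting the chaos expansions of the states and the random parameters
into the model equations and projecting onto each basis polynomial Psi_L
yields a closed deterministic ODE system for the chaos coefficients:

* a constant source term with coefficient expansion ``c`` contributes
  ``c_L`` to the equation of mode L (orthogonality collapses the product);
* a (parameter x state) term contracts the parameter coefficients and the
  state coefficients against the 3-way tensor ``<Psi_i Psi_j, Psi_L>``;
* a (parameter x state x state) term contracts against the 4-way tensor
  ``<Psi_i Psi_j Psi_k, Psi_L>``;

each projection is divided by ``<Psi_L, Psi_L>``.  The parameter
coefficients are folded into the tensors once at assembly, so the per-step
cost is linear/bilinear in the state coefficient vectors.  The assembled
system is integrated with an adaptive explicit Runge-Kutta 4(5) scheme at
tight tolerances, making the results integrator-independent at reporting
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .epidemic_model import PolynomialODEModel, RHSTerm, eval_rhs
from .pc_basis import InnerProductTensors, MultiIndexBasis
from .random_params import ParameterSet

__all__ = [
    "GalerkinSystem",
    "ChaosSolution",
    "assemble_galerkin",
    "integrate_chaos",
    "solve_deterministic",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class GalerkinSystem:
    """Assembled coefficient ODE system ready for integration.

    ``n_unknowns`` is (number of modeled states) x (basis size); the
    compiled per-state contributions are stored as projected vectors,
    matrices and 3-way tensors with the parameter chaos coefficients and
    the sign already folded in.
    """

    basis: MultiIndexBasis
    tensors: InnerProductTensors
    model: PolynomialODEModel
    params: ParameterSet
    _const: dict[str, np.ndarray] = field(repr=False)
    _linear: dict[str, list[tuple[int, np.ndarray]]] = field(repr=False)
    _bilinear: dict[str, list[tuple[int, int, np.ndarray]]] = field(repr=False)

    @property
    def n_unknowns(self) -> int:
        return self.model.n_states * len(self.basis)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        B = len(self.basis)
        C = y.reshape(self.model.n_states, B)
        dC = np.empty_like(C)
        for s, state in enumerate(self.model.states):
            acc = self._const[state].copy()
            for j, A in self._linear[state]:
                acc += A @ C[j]
            for j, k, T in self._bilinear[state]:
                acc += np.einsum("ljk,j,k->l", T, C[j], C[k])
            dC[s] = acc
        return dC.reshape(-1)

    def initial_coefficients(self) -> np.ndarray:
        """Deterministic initial conditions: mode 0 carries the value, rest 0."""
        B = len(self.basis)
        y0 = np.zeros(self.model.n_states * B)
        for s, value in enumerate(self.model.initial_values):
            y0[s * B] = value
        return y0


@dataclass(frozen=True)
class ChaosSolution:
    """Chaos coefficient trajectories on a time grid (weeks).

    ``coeffs[state]`` has shape (n_times, basis size).  If the model
    declares a closure state, its coefficients are derived on access:
    mode 0 is one minus the sum of the modeled modes 0 and every higher
    mode is minus the sum of the corresponding modeled modes.
    """

    time_grid: np.ndarray
    coeffs: dict[str, np.ndarray] = field(repr=False)
    basis: MultiIndexBasis
    closure: str | None = None

    def states(self) -> tuple[str, ...]:
        return tuple(self.coeffs) + ((self.closure,) if self.closure else ())

    def coefficients(self, state: str) -> np.ndarray:
        if state in self.coeffs:
            return self.coeffs[state]
        if state == self.closure:
            derived = -sum(self.coeffs.values())
            derived[:, 0] += 1.0
            return derived
        raise KeyError(state)

    def at_time(self, state: str, t: float) -> np.ndarray:
        """Coefficient vector of ``state`` at a grid time ``t``."""
        (idx,) = np.nonzero(np.isclose(self.time_grid, t))
        if idx.size == 0:
            raise KeyError(f"time {t} not on the solution grid")
        return self.coefficients(state)[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time, state, coefficient_index, value."""
        rows = []
        for state in self.states():
            C = self.coefficients(state)
            for i in range(C.shape[1]):
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.time_grid,
                            "state": state,
                            "coefficient_index": i,
                            "value": C[:, i],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _coefficient_chaos(
    term: RHSTerm, params: ParameterSet, basis: MultiIndexBasis
) -> np.ndarray:
    """Chaos expansion of a term's coefficient (sign folded in).

    The coefficient is const x product of referenced parameters; at most
    one of them may be random (products of independent random parameters
    would need a joint expansion the degree-2 truncation cannot carry).
    """
    scalar = term.sign * term.const
    random_vec = None
    for name in term.params:
        p = params[name]
        if p.is_random:
            if random_vec is not None:
                raise ValueError(
                    f"term coefficient {term.params} references more than one "
                    "random parameter; not supported"
                )
            random_vec = p.chaos_coeffs if p.chaos_coeffs is not None else p.chaos_on(basis)
            if len(random_vec) != len(basis):
                random_vec = p.chaos_on(basis)
        else:
            scalar *= p.mean
    if random_vec is None:
        c = np.zeros(len(basis))
        c[0] = scalar
        return c
    return scalar * random_vec


def assemble_galerkin(
    model: PolynomialODEModel,
    params: ParameterSet,
    basis: MultiIndexBasis,
    tensors: InnerProductTensors,
) -> GalerkinSystem:
    """Project the model onto the chaos basis.

    For each modeled state and each RHS term, precompute the projected
    contribution: a vector for constant sources, a (B x B) matrix for
    linear terms, a (B x B x B) tensor for bilinear terms, each divided by
    the test-function norms.
    """
    if tensors.size != len(basis):
        raise ValueError(
            f"tensor size {tensors.size} does not match basis size {len(basis)}"
        )
    model.validate_parameters(params)
    B = len(basis)
    inv_norm = 1.0 / tensors.E2  # (B,)
    state_index = {s: i for i, s in enumerate(model.states)}

    const: dict[str, np.ndarray] = {}
    linear: dict[str, list[tuple[int, np.ndarray]]] = {}
    bilinear: dict[str, list[tuple[int, int, np.ndarray]]] = {}

    for state in model.states:
        const[state] = np.zeros(B)
        linear[state] = []
        bilinear[state] = []
        for term in model.terms[state]:
            for s in term.monomial:
                if s not in state_index:
                    raise ValueError(
                        f"Galerkin assembly requires monomials in modeled states; "
                        f"term of {state!r} references {s!r} (use the full variant "
                        "or substitute the closure before assembly)"
                    )
            c = _coefficient_chaos(term, params, basis)
            if len(term.monomial) == 0:
                # <sum_i c_i Psi_i, Psi_L> / <Psi_L,Psi_L> = c_L
                const[state] += c
            elif len(term.monomial) == 1:
                A = np.einsum("i,ijl->lj", c, tensors.E3) * inv_norm[:, None]
                linear[state].append((state_index[term.monomial[0]], A))
            else:
                T = np.einsum("i,ijkl->ljk", c, tensors.E4) * inv_norm[:, None, None]
                x, y = term.monomial
                bilinear[state].append((state_index[x], state_index[y], T))

    return GalerkinSystem(
        basis=basis,
        tensors=tensors,
        model=model,
        params=params,
        _const=const,
        _linear=linear,
        _bilinear=bilinear,
    )


def integrate_chaos(
    system: GalerkinSystem,
    t_end: float,
    output_times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ChaosSolution:
    """Integrate the coefficient system with adaptive explicit RK 4(5)."""
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    output_times = np.atleast_1d(np.asarray(output_times, dtype=float))
    if output_times.min() < 0 or output_times.max() > t_end:
        raise ValueError("output_times must lie within [0, t_end]")
    output_times = np.unique(output_times)

    sol = solve_ivp(
        system.rhs,
        (0.0, float(t_end)),
        system.initial_coefficients(),
        method="RK45",
        t_eval=output_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"chaos integration failed near t = {t_fail}: {sol.message}")

    B = len(system.basis)
    coeffs = {
        state: sol.y[s * B : (s + 1) * B].T.copy()
        for s, state in enumerate(system.model.states)
    }
    return ChaosSolution(
        time_grid=sol.t,
        coeffs=coeffs,
        basis=system.basis,
        closure=system.model.closure,
    )


def solve_deterministic(
    model: PolynomialODEModel,
    point_params: dict,
    output_times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> dict[str, np.ndarray]:
    """Solve the model at fixed parameter values (same integrator settings).

    Returns trajectories for every state, including a derived closure
    state, keyed by state name; ``"time"`` holds the grid.
    """
    output_times = np.unique(np.atleast_1d(np.asarray(output_times, dtype=float)))
    y0 = np.array(model.initial_values, dtype=float)

    def rhs(t, y):
        return eval_rhs(model, y, point_params)

    sol = solve_ivp(
        rhs,
        (0.0, float(output_times.max()) if output_times.max() > 0 else 1e-12),
        y0,
        method="RK45",
        t_eval=output_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"deterministic solve failed near t = {t_fail}: {sol.message}")

    out = {"time": sol.t}
    for s, state in enumerate(model.states):
        out[state] = sol.y[s]
    if model.closure is not None:
        out[model.closure] = 1.0 - sum(sol.y[s] for s in range(model.n_states))
    return out
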