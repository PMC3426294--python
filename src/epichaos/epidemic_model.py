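"""Polynomial-right-hand-side compartmental ODE models.

A model is a list of states with initial values plus, per state, a list of
signed terms ``sign * coefficient * (state monomial)`` where the coefficient
is a product of parameter references and a literal constant, and the
monomial has degree at most two (constant sources, linear transits and
bilinear contact terms — enough for classical compartmental epidemics).

An optional *closure* declares that one named state equals one minus the sum
of the modeled states, which lets conservation-obeying systems drop one
equation.

The bundled worked example is a three-compartment obesity model for adults
classified by body-mass index: normal weight N, overweight S and obese O
(proportions of the population, time in weeks):

    N' = mu*N0 - mu*N - beta*N*(S + O) + rho*S
    S' = mu*S0 + beta*N*(S + O) - (mu + gamma + rho)*S + eps*O
    O' = mu*O0 + gamma*S - (mu + eps)*O

with demographic inflow proportions N0 + S0 + O0 = 1, so N + S + O = 1 is
conserved and the system reduces to the (S, O) pair with N = 1 - S - O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .random_params import ParameterSet, RandomParameter, deterministic, uniform_about

__all__ = [
    "RHSTerm",
    "PolynomialODEModel",
    "build_obesity_model",
    "obesity_parameter_set",
    "eval_rhs",
    "OBESITY_INITIAL_CONDITIONS",
    "OBESITY_POINT_ESTIMATES",
]


@dataclass(frozen=True)
class RHSTerm:
    """One signed term of a state's time derivative.

    ``params`` are names of model parameters whose product (times ``const``)
    forms the coefficient; ``monomial`` is a multiset of 0-2 state names.
    """

    sign: int
    params: tuple[str, ...] = ()
    const: float = 1.0
    monomial: tuple[str, ...] = ()

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if len(self.monomial) > 2:
            raise ValueError(
                f"state monomial degree must be <= 2, got {self.monomial}"
            )


@dataclass(frozen=True)
class PolynomialODEModel:
    """States, initial values and per-state term lists.

    ``closure`` optionally names a state defined as 1 minus the sum of the
    modeled states; it carries no equation of its own.
    """

    states: tuple[str, ...]
    initial_values: tuple[float, ...]
    terms: dict[str, tuple[RHSTerm, ...]] = field(repr=False)
    closure: str | None = None

    def __post_init__(self):
        if len(self.states) != len(self.initial_values):
            raise ValueError("states and initial_values must have equal length")
        if any(v < 0 for v in self.initial_values):
            raise ValueError(f"initial values must be non-negative: {self.initial_values}")
        if self.closure is not None and self.closure in self.states:
            raise ValueError(f"closure state {self.closure!r} also appears as a modeled state")
        known = set(self.states) | ({self.closure} if self.closure else set())
        for state, tlist in self.terms.items():
            if state not in self.states:
                raise ValueError(f"terms given for undeclared state {state!r}")
            for t in tlist:
                for s in t.monomial:
                    if s not in known:
                        raise ValueError(
                            f"term of {state!r} references undeclared state {s!r}"
                        )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def initial_value(self, state: str) -> float:
        if state == self.closure:
            return 1.0 - sum(self.initial_values)
        return self.initial_values[self.states.index(state)]

    def all_states(self) -> tuple[str, ...]:
        """Modeled states plus the closure state, if any."""
        return self.states + ((self.closure,) if self.closure else ())

    def referenced_parameters(self) -> tuple[str, ...]:
        seen: list[str] = []
        for state in self.states:
            for t in self.terms[state]:
                for name in t.params:
                    if name not in seen:
                        seen.append(name)
        return tuple(seen)

    def validate_parameters(self, params: ParameterSet) -> None:
        missing = [n for n in self.referenced_parameters() if n not in params]
        if missing:
            raise KeyError(f"model references undeclared parameters: {missing}")


def _coefficient_value(term: RHSTerm, param_values: dict) -> float:
    value = term.const
    for name in term.params:
        try:
            value = value * param_values[name]
        except KeyError:
            raise KeyError(f"unresolved parameter reference {name!r}") from None
    return term.sign * value


def eval_rhs(model: PolynomialODEModel, state_values, param_values: dict) -> np.ndarray:
    """Deterministic evaluation of every state's time derivative.

    ``state_values`` is a mapping or a vector in model state order; values
    (and parameter values) may be numpy arrays for vectorized ensemble
    evaluation.  If the model has a closure, the closed state's value is
    derived as 1 minus the sum of the modeled states.
    """
    if isinstance(state_values, dict):
        values = dict(state_values)
    else:
        arr = list(state_values)
        if len(arr) != model.n_states:
            raise ValueError(
                f"expected {model.n_states} state values, got {len(arr)}"
            )
        values = dict(zip(model.states, arr))
    if model.closure is not None and model.closure not in values:
        total = sum(values[s] for s in model.states)
        values[model.closure] = 1.0 - total

    derivs = []
    for state in model.states:
        d = 0.0
        for term in model.terms[state]:
            contrib = _coefficient_value(term, param_values)
            for s in term.monomial:
                contrib = contrib * values[s]
            d = d + contrib
        derivs.append(d)
    return np.array(derivs) if np.ndim(derivs[0]) == 0 else np.stack(derivs)


# --- bundled obesity worked example -----------------------------------------

#: proportions of normal-weight, overweight and obese adults at t = 0
#: (region of Valencia, year 2000 health survey).
OBESITY_INITIAL_CONDITIONS = {"N": 0.522, "S": 0.362, "O": 0.116}

#: point estimates of the model parameters (weeks^-1 for rates; the last
#: three are inflow proportions of the 23-year-old age group).
OBESITY_POINT_ESTIMATES = {
    "beta": 0.00085,
    "mu": 0.000469,
    "gamma": 0.0003,
    "epsilon": 0.000004,
    "rho": 0.000035,
    "N0": 0.704,
    "S0": 0.25,
    "O0": 0.046,
}


def obesity_parameter_set(random: bool = True) -> ParameterSet:
    """Parameter set of the obesity model.

    With ``random=True`` the four transmission parameters beta, gamma,
    epsilon, rho are Uniform(0, 2*theta_hat) on germ dimensions 0-3 (the
    noninformative choice whose mean is the point estimate); mu and the
    inflow proportions stay deterministic.  With ``random=False`` every
    parameter is fixed at its point estimate.
    """
    est = OBESITY_POINT_ESTIMATES
    if random:
        transmission = [
            uniform_about("beta", est["beta"], germ_dim=0),
            uniform_about("gamma", est["gamma"], germ_dim=1),
            uniform_about("epsilon", est["epsilon"], germ_dim=2),
            uniform_about("rho", est["rho"], germ_dim=3),
        ]
    else:
        transmission = [
            deterministic(name, est[name]) for name in ("beta", "gamma", "epsilon", "rho")
        ]
    fixed = [deterministic(name, est[name]) for name in ("mu", "N0", "S0", "O0")]
    return ParameterSet.from_parameters(*transmission, *fixed)


def build_obesity_model(variant: str, params: ParameterSet) -> PolynomialODEModel:
    """Obesity model in ``"full"`` (N, S, O) or ``"reduced"`` (S, O) form.

    The reduced form substitutes N = 1 - S - O into the overweight
    equation, expanding beta*(1 - S - O)*(S + O) into constant-free linear
    and bilinear terms, and records N as the closure state.
    """
    for name in ("mu", "beta", "gamma", "epsilon", "rho", "N0", "S0", "O0"):
        if name not in params:
            raise KeyError(f"obesity model requires parameter {name!r}")

    ic = OBESITY_INITIAL_CONDITIONS
    n0 = params["N0"].mean
    s0 = params["S0"].mean
    o0 = params["O0"].mean

    o_terms = (
        RHSTerm(+1, ("mu",), o0),
        RHSTerm(+1, ("gamma",), 1.0, ("S",)),
        RHSTerm(-1, ("mu",), 1.0, ("O",)),
        RHSTerm(-1, ("epsilon",), 1.0, ("O",)),
    )

    if variant == "full":
        terms = {
            "N": (
                RHSTerm(+1, ("mu",), n0),
                RHSTerm(-1, ("mu",), 1.0, ("N",)),
                RHSTerm(-1, ("beta",), 1.0, ("N", "S")),
                RHSTerm(-1, ("beta",), 1.0, ("N", "O")),
                RHSTerm(+1, ("rho",), 1.0, ("S",)),
            ),
            "S": (
                RHSTerm(+1, ("mu",), s0),
                RHSTerm(+1, ("beta",), 1.0, ("N", "S")),
                RHSTerm(+1, ("beta",), 1.0, ("N", "O")),
                RHSTerm(-1, ("mu",), 1.0, ("S",)),
                RHSTerm(-1, ("gamma",), 1.0, ("S",)),
                RHSTerm(-1, ("rho",), 1.0, ("S",)),
                RHSTerm(+1, ("epsilon",), 1.0, ("O",)),
            ),
            "O": o_terms,
        }
        return PolynomialODEModel(
            states=("N", "S", "O"),
            initial_values=(ic["N"], ic["S"], ic["O"]),
            terms=terms,
        )
    if variant == "reduced":
        terms = {
            # beta*(1-S-O)*(S+O) expanded: +bS +bO -bS^2 -2bSO -bO^2
            "S": (
                RHSTerm(+1, ("mu",), s0),
                RHSTerm(+1, ("beta",), 1.0, ("S",)),
                RHSTerm(+1, ("beta",), 1.0, ("O",)),
                RHSTerm(-1, ("beta",), 1.0, ("S", "S")),
                RHSTerm(-1, ("beta",), 2.0, ("S", "O")),
                RHSTerm(-1, ("beta",), 1.0, ("O", "O")),
                RHSTerm(-1, ("mu",), 1.0, ("S",)),
                RHSTerm(-1, ("gamma",), 1.0, ("S",)),
                RHSTerm(-1, ("rho",), 1.0, ("S",)),
                RHSTerm(+1, ("epsilon",), 1.0, ("O",)),
            ),
            "O": o_terms,
        }
        return PolynomialODEModel(
            states=("S", "O"),
            initial_values=(ic["S"], ic["O"]),
            terms=terms,
            closure="N",
        )
    raise ValueError(f"variant must be 'full' or 'reduced', got {variant!r}")
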