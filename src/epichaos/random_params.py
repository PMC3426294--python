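"""Model parameters: uniform random coefficients and their chaos expansions.

Each uniform random parameter lives on its own germ dimension (the
parameters are mutually independent), so its Legendre chaos expansion is a
function of a single Uniform[-1, 1] variable:

    theta(w) = (a + b)/2 + (b - a)/2 * xi_d(w),        xi_d ~ Uniform[-1, 1]

i.e. the constant coefficient is the mean and the degree-1 coefficient on
the assigned germ is the half-width.  The degree-2 (and higher) coefficients
of a uniform variable in Legendre chaos are exactly zero; the slots are kept
in the coefficient vector so variance gathers over "all basis functions in
one germ" remain well-defined.  Deterministic parameters are zero-width
uniforms with no germ dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pc_basis import MultiIndexBasis

__all__ = [
    "RandomParameter",
    "ParameterSet",
    "uniform_to_chaos",
    "uniform_about",
    "deterministic",
    "sample_parameters",
]


@dataclass(frozen=True)
class RandomParameter:
    """A model coefficient with a (possibly degenerate) uniform distribution.

    ``germ_dim`` is the index of the germ dimension carrying this
    parameter's randomness, or ``None`` for a deterministic parameter.
    ``chaos_coeffs`` is its coefficient vector over the full multivariate
    basis, populated by :func:`uniform_to_chaos` or
    :meth:`ParameterSet.bind_chaos`.
    """

    name: str
    lower: float
    upper: float
    germ_dim: int | None = None
    chaos_coeffs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.upper < self.lower:
            raise ValueError(
                f"parameter {self.name!r}: upper ({self.upper}) < lower ({self.lower})"
            )

    @property
    def mean(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.upper - self.lower)

    @property
    def is_random(self) -> bool:
        return self.germ_dim is not None and self.upper > self.lower

    @property
    def variance(self) -> float:
        return (self.upper - self.lower) ** 2 / 12.0

    def chaos_on(self, basis: MultiIndexBasis) -> np.ndarray:
        """Chaos coefficient vector of this parameter over ``basis``."""
        coeffs = np.zeros(len(basis))
        coeffs[0] = self.mean
        if self.germ_dim is not None:
            if self.germ_dim >= basis.n_dims:
                raise ValueError(
                    f"parameter {self.name!r}: germ dimension {self.germ_dim} "
                    f"not available in a {basis.n_dims}-dimensional basis"
                )
            if self.half_width > 0.0:
                lin = tuple(
                    1 if d == self.germ_dim else 0 for d in range(basis.n_dims)
                )
                coeffs[basis.index_of(lin)] = self.half_width
        return coeffs


def deterministic(name: str, value: float) -> RandomParameter:
    """A fixed-value parameter (zero-width distribution, no germ)."""
    return RandomParameter(name=name, lower=float(value), upper=float(value))


def uniform_about(name: str, mean: float, germ_dim: int | None = None) -> RandomParameter:
    """Uniform(0, 2*mean): the noninformative choice whose mean is the point estimate."""
    if mean < 0:
        raise ValueError(f"parameter {name!r}: mean must be non-negative, got {mean}")
    return RandomParameter(name=name, lower=0.0, upper=2.0 * float(mean), germ_dim=germ_dim)


def uniform_to_chaos(
    lower: float,
    upper: float,
    germ_dim: int,
    basis: MultiIndexBasis,
    name: str = "theta",
) -> RandomParameter:
    """Expand Uniform(lower, upper) in Legendre chaos on ``germ_dim``.

    The constant coefficient is ``(lower + upper)/2``; the degree-1
    coefficient on the germ is ``(upper - lower)/2``; everything else is 0.
    """
    param = RandomParameter(name=name, lower=float(lower), upper=float(upper), germ_dim=int(germ_dim))
    return replace(param, chaos_coeffs=param.chaos_on(basis))


@dataclass(frozen=True)
class ParameterSet:
    """Ordered collection of parameters with distinct germ assignments.

    The random parameters' germ dimensions must exactly cover
    ``0 .. n_random-1``: each independent uniform input owns one dimension
    of the germ vector.
    """

    parameters: tuple[RandomParameter, ...]

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate parameter names in {names}")
        dims = sorted(p.germ_dim for p in self.parameters if p.germ_dim is not None)
        if dims != list(range(len(dims))):
            raise ValueError(
                f"germ dimensions must be distinct and cover 0..n_random-1, got {dims}"
            )

    @classmethod
    def from_parameters(cls, *params: RandomParameter) -> "ParameterSet":
        return cls(parameters=tuple(params))

    @property
    def n_random(self) -> int:
        return sum(1 for p in self.parameters if p.germ_dim is not None)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def __getitem__(self, name: str) -> RandomParameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.parameters)

    def __iter__(self):
        return iter(self.parameters)

    def means(self) -> dict[str, float]:
        """Point values at the distribution means (the deterministic limit)."""
        return {p.name: p.mean for p in self.parameters}

    def random_parameters(self) -> tuple[RandomParameter, ...]:
        return tuple(
            sorted(
                (p for p in self.parameters if p.germ_dim is not None),
                key=lambda p: p.germ_dim,
            )
        )

    def bind_chaos(self, basis: MultiIndexBasis) -> "ParameterSet":
        """Return a copy with every parameter's chaos coefficients on ``basis``."""
        if basis.n_dims < self.n_random:
            raise ValueError(
                f"basis has {basis.n_dims} germ dimensions but the set has "
                f"{self.n_random} random parameters"
            )
        return ParameterSet(
            parameters=tuple(replace(p, chaos_coeffs=p.chaos_on(basis)) for p in self.parameters)
        )


def sample_parameters(pset: ParameterSet, n_samples: int, seed: int) -> pd.DataFrame:
    """Draw i.i.d. joint samples of all parameters (deterministic ones constant).

    Reproducible under a fixed seed; one column per parameter in set order.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    columns = {}
    for p in pset.parameters:
        if p.is_random:
            columns[p.name] = rng.uniform(p.lower, p.upper, size=n_samples)
        else:
            columns[p.name] = np.full(n_samples, p.mean)
    return pd.DataFrame(columns)
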