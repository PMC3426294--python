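"""Truncated multivariate Legendre chaos basis and its inner-product tensors.

The chaos basis for ``n_dims`` independent Uniform[-1, 1] germ variables is
the set of products of univariate (unnormalized) Legendre polynomials with
total degree at most ``order``.  Inner products are taken against the uniform
product density ``(1/2)**n_dims`` on ``[-1, 1]**n_dims``, so each
n-dimensional moment factorizes into a product of univariate moments; the
2-, 3- and 4-way tensors needed by the Galerkin projection are assembled
from per-dimension univariate moment tables computed by Gauss-Legendre
quadrature of sufficient exactness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

__all__ = [
    "MultiIndexBasis",
    "InnerProductTensors",
    "generate_multi_indices",
    "eval_univariate_legendre",
    "eval_basis_function",
    "build_inner_product_tensors",
]

#: entries of the 3-/4-way tensors smaller than this in magnitude are zeroed;
#: they are quadrature noise on exact zeros and would otherwise pollute sums.
SPARSITY_EPS = 1e-14


@dataclass(frozen=True)
class MultiIndexBasis:
    """Truncated tensor-Legendre basis of total degree <= ``order``.

    Attributes
    ----------
    n_dims:
        Number of germ dimensions (independent Uniform[-1,1] variables).
    order:
        Maximum total polynomial degree retained.
    indices:
        One multi-index per basis function: a tuple of per-dimension degrees.
        Position 0 is always the all-zeros index (the constant function).
    norms_sq:
        Squared norms ``<Psi_i, Psi_i>`` under the uniform product measure;
        for unnormalized Legendre polynomials this is
        ``prod_d 1/(2*l_{i,d} + 1)``.
    """

    n_dims: int
    order: int
    indices: tuple[tuple[int, ...], ...]
    norms_sq: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def size(self) -> int:
        return len(self.indices)

    def index_of(self, multi_index: tuple[int, ...]) -> int:
        """Position of a multi-index in the canonical ordering."""
        return self.indices.index(tuple(multi_index))

    def active_dims(self, i: int) -> tuple[int, ...]:
        """Germ dimensions on which basis function ``i`` actually depends."""
        return tuple(d for d, l in enumerate(self.indices[i]) if l > 0)

    @property
    def degrees(self) -> np.ndarray:
        """Degrees as an integer array of shape (size, n_dims)."""
        return np.asarray(self.indices, dtype=np.intp).reshape(len(self.indices), self.n_dims)


@dataclass(frozen=True)
class InnerProductTensors:
    """Dense inner-product tensors of a :class:`MultiIndexBasis`.

    ``E2[i] = <Psi_i, Psi_i>`` (off-diagonal 2-way products vanish by
    orthogonality), ``E3[i, j, L] = <Psi_i Psi_j, Psi_L>`` and
    ``E4[i, j, k, L] = <Psi_i Psi_j Psi_k, Psi_L>``.  E3 and E4 are fully
    symmetric under permutation of their index arguments.
    """

    E2: np.ndarray = field(repr=False)
    E3: np.ndarray = field(repr=False)
    E4: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.E2.shape[0]


def _check_count(value, name: str, minimum: int):
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {value}")
    return int(value)


def generate_multi_indices(n_dims: int, order: int) -> MultiIndexBasis:
    """Enumerate the total-degree-truncated multi-index set.

    The count is the binomial ``(n_dims + order)! / (n_dims! order!)``.  The
    canonical ordering groups indices by total degree; within a degree group,
    functions of fewer germ dimensions come first (pure powers before cross
    products), and ties order by dimension (terms in the first germ first).
    For ``order=2`` this yields: constant; the ``n_dims`` linear terms; the
    ``n_dims`` pure quadratic terms; the cross products ``xi_i xi_j`` with
    ``i < j`` in lexicographic order — so with four germs, position 5 is the
    quadratic term in the first germ.
    """
    n_dims = _check_count(n_dims, "n_dims", 1)
    order = _check_count(order, "order", 0)

    indices = [
        idx
        for idx in itertools.product(range(order + 1), repeat=n_dims)
        if sum(idx) <= order
    ]
    indices.sort(key=lambda idx: (sum(idx), sum(1 for l in idx if l > 0), tuple(-l for l in idx)))

    expected = math.comb(n_dims + order, order)
    assert len(indices) == expected, "multi-index enumeration out of step with the count formula"

    norms_sq = np.array([
        math.prod(1.0 / (2 * l + 1) for l in idx) for idx in indices
    ])
    return MultiIndexBasis(n_dims=n_dims, order=order, indices=tuple(indices), norms_sq=norms_sq)


def eval_univariate_legendre(degree: int, x: float) -> float:
    """Standard (unnormalized) Legendre polynomial ``P_degree(x)`` on [-1, 1].

    ``P_0 = 1``, ``P_1(x) = x``, ``P_2(x) = (3x^2 - 1)/2``, ...
    """
    degree = _check_count(degree, "degree", 0)
    if abs(x) > 1.0 + 1e-12:
        raise ValueError(f"x must lie in [-1, 1], got {x}")
    return float(eval_legendre(degree, float(np.clip(x, -1.0, 1.0))))


def eval_basis_function(basis: MultiIndexBasis, i: int, point) -> float:
    """Evaluate multivariate basis function ``Psi_i`` at a germ point.

    The value is the product over dimensions of the univariate Legendre
    polynomial of the corresponding degree.
    """
    if not 0 <= i < len(basis):
        raise IndexError(f"basis index {i} out of range for basis of size {len(basis)}")
    point = np.asarray(point, dtype=float)
    if point.shape != (basis.n_dims,):
        raise ValueError(
            f"point must have {basis.n_dims} entries, got shape {point.shape}"
        )
    value = 1.0
    for degree, x in zip(basis.indices[i], point):
        if degree > 0:
            value *= eval_univariate_legendre(degree, x)
    return value


def _univariate_moment_tables(order: int, n_nodes: int):
    """Univariate expectation tables E[P_a P_b], E[P_a P_b P_c], E[P_a P_b P_c P_d].

    Expectations are under the Uniform[-1, 1] density 1/2, computed by
    Gauss-Legendre quadrature exact for polynomials of the degrees involved.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    weights = weights / 2.0  # density 1/2 on [-1, 1]
    # P[a, q] = P_a(node_q)
    P = np.stack([eval_legendre(a, nodes) for a in range(order + 1)])
    m2 = np.einsum("aq,bq,q->ab", P, P, weights)
    m3 = np.einsum("aq,bq,cq,q->abc", P, P, P, weights)
    m4 = np.einsum("aq,bq,cq,dq,q->abcd", P, P, P, P, weights)
    # canonicalize over sorted indices so permutation symmetry is exact,
    # not merely within contraction-order rounding
    r = range(order + 1)
    for t in itertools.product(r, repeat=2):
        m2[t] = m2[tuple(sorted(t))]
    for t in itertools.product(r, repeat=3):
        m3[t] = m3[tuple(sorted(t))]
    for t in itertools.product(r, repeat=4):
        m4[t] = m4[tuple(sorted(t))]
    return m2, m3, m4


def build_inner_product_tensors(basis: MultiIndexBasis) -> InnerProductTensors:
    """Assemble dense E2, E3, E4 tensors for a basis.

    Each multivariate inner product factorizes over dimensions, so the
    tensors are products of univariate moment-table lookups.  The quadrature
    rule uses ``ceil((4*order + 1)/2) + 1`` nodes per dimension, exact for
    the 4-way products with margin.
    """
    order = basis.order
    n_nodes = math.ceil((4 * order + 1) / 2) + 1
    m2, m3, m4 = _univariate_moment_tables(order, n_nodes)

    deg = basis.degrees  # (B, n)
    B = len(basis)

    E2 = np.prod(m2[deg, deg], axis=1)

    di = deg[:, None, None, :]
    dj = deg[None, :, None, :]
    dL = deg[None, None, :, :]
    E3 = np.prod(m3[di, dj, dL], axis=-1)

    di4 = deg[:, None, None, None, :]
    dj4 = deg[None, :, None, None, :]
    dk4 = deg[None, None, :, None, :]
    dL4 = deg[None, None, None, :, :]
    E4 = np.prod(m4[di4, dj4, dk4, dL4], axis=-1)

    E3[np.abs(E3) < SPARSITY_EPS] = 0.0
    E4[np.abs(E4) < SPARSITY_EPS] = 0.0
    return InnerProductTensors(E2=E2, E3=E3, E4=E4)
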