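"""Moments, standard-deviation bands and chaos-based Sobol indices.

Because the chaos basis is orthogonal, the mean of a state is its mode-0
coefficient and its variance is the norm-weighted sum of squares of the
higher modes:

    Var X(t) = sum_{i>=1} x_i(t)^2 <Psi_i, Psi_i>.

The same sum, partitioned by which germ dimensions each basis function
depends on, is the Sobol variance decomposition: the first-order index of
the parameter on germ d gathers the basis functions depending on dimension
d alone; everything involving two or more dimensions is an interaction
contribution.  The reported uncertainty bands are mean +/- one standard
deviation of the output process — not Gaussian-quantile confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .galerkin import ChaosSolution
from .pc_basis import MultiIndexBasis
from .random_params import ParameterSet

__all__ = ["MomentSeries", "SobolSeries", "compute_moments", "compute_sobol"]

#: variances more negative than this trigger a warning before clamping;
#: milder negatives are silent floating-point cancellation.
NEGATIVE_VARIANCE_WARN = -1e-14

#: label of the pooled interaction (multi-germ) variance share.
INTERACTIONS = "interactions"


@dataclass(frozen=True)
class MomentSeries:
    """Per-state mean, variance and one-standard-deviation band over time."""

    time_grid: np.ndarray
    mean: dict[str, np.ndarray] = field(repr=False)
    variance: dict[str, np.ndarray] = field(repr=False)

    def states(self) -> tuple[str, ...]:
        return tuple(self.mean)

    def std(self, state: str) -> np.ndarray:
        return np.sqrt(self.variance[state])

    def band_low(self, state: str) -> np.ndarray:
        return self.mean[state] - self.std(state)

    def band_high(self, state: str) -> np.ndarray:
        return self.mean[state] + self.std(state)

    def at_time(self, state: str, t: float) -> tuple[float, float]:
        """(mean, variance) of ``state`` at grid time ``t``."""
        (idx,) = np.nonzero(np.isclose(self.time_grid, t))
        if idx.size == 0:
            raise KeyError(f"time {t} not on the moment grid")
        return float(self.mean[state][idx[0]]), float(self.variance[state][idx[0]])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time, state, quantity, value."""
        rows = []
        for state in self.states():
            for quantity, series in (
                ("mean", self.mean[state]),
                ("variance", self.variance[state]),
                ("band_low", self.band_low(state)),
                ("band_high", self.band_high(state)),
            ):
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.time_grid,
                            "state": state,
                            "quantity": quantity,
                            "value": series,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class SobolSeries:
    """First-order Sobol indices per (state, parameter) over time.

    ``indices[state][name]`` holds the variance fraction attributed to the
    parameter alone; the extra series ``indices[state]["interactions"]``
    pools the multi-germ contributions so the decomposition visibly sums
    to one.  Where the total variance is zero (e.g. t = 0 with
    deterministic initial conditions) the indices are NaN.
    """

    time_grid: np.ndarray
    indices: dict[str, dict[str, np.ndarray]] = field(repr=False)

    def states(self) -> tuple[str, ...]:
        return tuple(self.indices)

    def parameter_names(self, state: str) -> tuple[str, ...]:
        return tuple(n for n in self.indices[state] if n != INTERACTIONS)

    def series(self, state: str, name: str) -> np.ndarray:
        return self.indices[state][name]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time, state, quantity, value."""
        rows = []
        for state, per_param in self.indices.items():
            for name, series in per_param.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.time_grid,
                            "state": state,
                            "quantity": f"sobol_{name}",
                            "value": series,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _clamped_variance(raw: np.ndarray, state: str) -> np.ndarray:
    worst = raw.min(initial=0.0)
    if worst < NEGATIVE_VARIANCE_WARN:
        warnings.warn(
            f"variance of {state!r} reached {worst:.3e} < 0; clamping to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.maximum(raw, 0.0)


def compute_moments(solution: ChaosSolution, basis: MultiIndexBasis) -> MomentSeries:
    """Mean and variance trajectories from the chaos coefficients.

    Mean is mode 0; variance is the orthogonality sum over modes >= 1.
    Closure-state moments use the derived closure coefficients.
    """
    if len(basis) != len(solution.basis):
        raise ValueError("solution and basis have different sizes")
    mean: dict[str, np.ndarray] = {}
    variance: dict[str, np.ndarray] = {}
    for state in solution.states():
        C = solution.coefficients(state)  # (T, B)
        mean[state] = C[:, 0].copy()
        raw = (C[:, 1:] ** 2) @ basis.norms_sq[1:]
        variance[state] = _clamped_variance(raw, state)
    return MomentSeries(time_grid=solution.time_grid, mean=mean, variance=variance)


def compute_sobol(
    solution: ChaosSolution, basis: MultiIndexBasis, params: ParameterSet
) -> SobolSeries:
    """First-order Sobol indices gathered from the chaos coefficients.

    For the parameter on germ dimension d, the index at time t is

        S_d(t) = sum_{i : Psi_i depends only on dim d} x_i(t)^2 <Psi_i,Psi_i>
                 / Var X(t);

    at chaos order two this is the two-term gather over the linear and
    pure-quadratic basis functions of dimension d.  Deterministic (no-germ)
    parameters are reported with index identically zero.
    """
    groups: dict[str, np.ndarray] = {}
    multi_dim_mask = np.zeros(len(basis), dtype=bool)
    for i in range(1, len(basis)):
        if len(basis.active_dims(i)) > 1:
            multi_dim_mask[i] = True
    for p in params:
        mask = np.zeros(len(basis), dtype=bool)
        if p.germ_dim is not None:
            for i in range(1, len(basis)):
                if basis.active_dims(i) == (p.germ_dim,):
                    mask[i] = True
        groups[p.name] = mask
    groups[INTERACTIONS] = multi_dim_mask

    indices: dict[str, dict[str, np.ndarray]] = {}
    for state in solution.states():
        C = solution.coefficients(state)
        contrib_sq = C**2 * basis.norms_sq  # (T, B)
        total = contrib_sq[:, 1:].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_state = {
                name: np.where(total > 0.0, contrib_sq[:, mask].sum(axis=1) / total, np.nan)
                for name, mask in groups.items()
            }
        indices[state] = per_state
    return SobolSeries(time_grid=solution.time_grid, indices=indices)
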