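"""Brute-force Monte Carlo uncertainty propagation (independent oracle).

Parameter draws are propagated through the deterministic model and moments
are accumulated in a single streaming pass over batches.  Within a batch
the whole ensemble is integrated as one stacked ODE system — the model RHS
is polynomial, so it evaluates elementwise over sample arrays — which keeps
the cost of tens of thousands of draws at a few adaptive solver runs rather
than one per draw.  First-order Sobol indices are estimated with the
pick-and-freeze (two-matrix) scheme, with bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .epidemic_model import PolynomialODEModel, eval_rhs
from .random_params import ParameterSet, sample_parameters

__all__ = ["MCEstimate", "MCSobolEstimate", "mc_propagate", "mc_sobol"]

ENSEMBLE_RTOL = 1e-6
ENSEMBLE_ATOL = 1e-9
DEFAULT_BATCH = 20_000


@dataclass(frozen=True)
class MCEstimate:
    """Streaming Monte Carlo moments per state and output time."""

    n_samples: int
    seed: int
    time_grid: np.ndarray
    mean: dict[str, np.ndarray] = field(repr=False)
    variance: dict[str, np.ndarray] = field(repr=False)

    def sem(self, state: str) -> np.ndarray:
        """Standard error of the mean: sqrt(variance / n_samples)."""
        return np.sqrt(self.variance[state] / self.n_samples)

    def at_time(self, state: str, t: float) -> tuple[float, float, float]:
        """(mean, variance, standard error) of ``state`` at grid time ``t``."""
        (idx,) = np.nonzero(np.isclose(self.time_grid, t))
        if idx.size == 0:
            raise KeyError(f"time {t} not on the estimate grid")
        i = idx[0]
        return (
            float(self.mean[state][i]),
            float(self.variance[state][i]),
            float(self.sem(state)[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state in self.mean:
            for quantity, series in (
                ("mean", self.mean[state]),
                ("variance", self.variance[state]),
                ("sem", self.sem(state)),
            ):
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.time_grid,
                            "state": state,
                            "quantity": quantity,
                            "method": "mc",
                            "value": series,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class MCSobolEstimate:
    """Pick-and-freeze first-order Sobol estimates with bootstrap errors."""

    n_samples: int
    seed: int
    time_grid: np.ndarray
    estimates: dict[str, dict[str, np.ndarray]] = field(repr=False)
    std_errors: dict[str, dict[str, np.ndarray]] = field(repr=False)

    def at_time(self, state: str, name: str, t: float) -> tuple[float, float]:
        (idx,) = np.nonzero(np.isclose(self.time_grid, t))
        if idx.size == 0:
            raise KeyError(f"time {t} not on the estimate grid")
        i = idx[0]
        return float(self.estimates[state][name][i]), float(self.std_errors[state][name][i])


def solve_ensemble(
    model: PolynomialODEModel,
    param_table: pd.DataFrame,
    output_times,
    rtol: float = ENSEMBLE_RTOL,
    atol: float = ENSEMBLE_ATOL,
) -> dict[str, np.ndarray]:
    """Integrate the model for every parameter draw at once.

    Returns per-state arrays of shape (n_times, n_draws), including a
    derived closure state.
    """
    output_times = np.unique(np.atleast_1d(np.asarray(output_times, dtype=float)))
    n = len(param_table)
    params = {name: param_table[name].to_numpy() for name in param_table.columns}
    n_states = model.n_states
    y0 = np.repeat(np.asarray(model.initial_values, dtype=float), n)

    def rhs(t, y):
        Y = y.reshape(n_states, n)
        return eval_rhs(model, {s: Y[i] for i, s in enumerate(model.states)}, params).reshape(-1)

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
        raise RuntimeError(
            f"ensemble solve failed near t = {t_fail} for a draw in a batch of {n}: "
            f"{sol.message}"
        )

    Y = sol.y.reshape(n_states, n, -1)  # (states, draws, times)
    out = {state: Y[i].T.copy() for i, state in enumerate(model.states)}
    if model.closure is not None:
        out[model.closure] = 1.0 - sum(out[s] for s in model.states)
    out["time"] = sol.t
    return out


def _combine_moments(count, mean, M2, b_count, b_mean, b_M2):
    """Chan et al. pairwise update of streaming mean and sum of squared deviations."""
    total = count + b_count
    delta = b_mean - mean
    new_mean = mean + delta * (b_count / total)
    new_M2 = M2 + b_M2 + delta**2 * (count * b_count / total)
    return total, new_mean, new_M2


def mc_propagate(
    model: PolynomialODEModel,
    params: ParameterSet,
    output_times,
    n_samples: int,
    seed: int,
    batch_size: int = DEFAULT_BATCH,
) -> MCEstimate:
    """Monte Carlo moments of the model outputs at ``output_times``."""
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    output_times = np.unique(np.atleast_1d(np.asarray(output_times, dtype=float)))
    draws = sample_parameters(params, n_samples, seed)

    states = list(model.states) + ([model.closure] if model.closure else [])
    count = 0
    mean = {s: np.zeros(len(output_times)) for s in states}
    M2 = {s: np.zeros(len(output_times)) for s in states}

    for start in range(0, n_samples, batch_size):
        batch = draws.iloc[start : start + batch_size]
        out = solve_ensemble(model, batch, output_times)
        b_count = len(batch)
        for s in states:
            traj = out[s]  # (T, b)
            b_mean = traj.mean(axis=1)
            b_M2 = ((traj - b_mean[:, None]) ** 2).sum(axis=1)
            _, mean[s], M2[s] = _combine_moments(
                count, mean[s], M2[s], b_count, b_mean, b_M2
            )
        count += b_count

    variance = {s: M2[s] / (count - 1) for s in states}
    return MCEstimate(
        n_samples=n_samples,
        seed=seed,
        time_grid=output_times,
        mean=mean,
        variance=variance,
    )


def mc_sobol(
    model: PolynomialODEModel,
    params: ParameterSet,
    output_times,
    n_samples: int,
    seed: int,
    n_bootstrap: int = 200,
    batch_size: int = DEFAULT_BATCH,
) -> MCSobolEstimate:
    """Pick-and-freeze first-order Sobol indices for every random parameter.

    Two independent sample matrices A and B are drawn; for parameter i the
    hybrid matrix AB_i equals A with parameter i's column frozen from B.
    The first-order variance share is estimated as

        S_i = mean( f(B) * (f(AB_i) - f(A)) ) / Var(f)

    with Var(f) taken over the pooled A and B evaluations.  Bootstrap
    resampling of the sample index gives standard errors.
    """
    if n_samples < 100:
        raise ValueError(f"n_samples must be >= 100 for Sobol estimation, got {n_samples}")
    output_times = np.unique(np.atleast_1d(np.asarray(output_times, dtype=float)))
    random_params = params.random_parameters()
    if not random_params:
        raise ValueError("no random parameters to analyze")

    child = np.random.SeedSequence(seed).generate_state(3).astype(np.int64) % (2**31)
    A = sample_parameters(params, n_samples, int(child[0]))
    Bm = sample_parameters(params, n_samples, int(child[1]))
    boot_rng = np.random.default_rng(int(child[2]))

    states = list(model.states) + ([model.closure] if model.closure else [])

    def evaluate(table: pd.DataFrame) -> dict[str, np.ndarray]:
        parts = [
            solve_ensemble(model, table.iloc[s : s + batch_size], output_times)
            for s in range(0, len(table), batch_size)
        ]
        return {
            st: np.concatenate([p[st] for p in parts], axis=1) for st in states
        }

    f_A = evaluate(A)
    f_B = evaluate(Bm)
    f_AB = {}
    for p in random_params:
        hybrid = A.copy()
        hybrid[p.name] = Bm[p.name].to_numpy()
        f_AB[p.name] = evaluate(hybrid)

    estimates: dict[str, dict[str, np.ndarray]] = {s: {} for s in states}
    std_errors: dict[str, dict[str, np.ndarray]] = {s: {} for s in states}
    boot_idx = boot_rng.integers(0, n_samples, size=(n_bootstrap, n_samples))

    for st in states:
        yA, yB = f_A[st], f_B[st]  # (T, n)
        pooled = np.concatenate([yA, yB], axis=1)
        var = pooled.var(axis=1, ddof=1)
        for p in random_params:
            yAB = f_AB[p.name][st]
            prod = yB * (yAB - yA)  # (T, n)
            estimates[st][p.name] = prod.mean(axis=1) / var

            # bootstrap over the shared sample index
            boot = np.empty((n_bootstrap, len(output_times)))
            for b in range(n_bootstrap):
                idx = boot_idx[b]
                pooled_b = np.concatenate([yA[:, idx], yB[:, idx]], axis=1)
                var_b = pooled_b.var(axis=1, ddof=1)
                boot[b] = prod[:, idx].mean(axis=1) / var_b
            std_errors[st][p.name] = boot.std(axis=0, ddof=1)

    return MCSobolEstimate(
        n_samples=n_samples,
        seed=seed,
        time_grid=output_times,
        estimates=estimates,
        std_errors=std_errors,
    )
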