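"""Forward simulation and steady states of the Hill ODE system."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import GeneNetwork, ParameterSet, rhs, rhs_state_jacobian, _production

__all__ = [
    "Trajectory",
    "SteadyStateError",
    "simulate",
    "steady_state",
    "steady_state_sse",
]


@dataclass(frozen=True)
class Trajectory:
    """Simulated concentrations: ``states[k]`` is the state at ``times[k]``."""

    times: np.ndarray
    states: np.ndarray

    def final_state(self) -> np.ndarray:
        return self.states[-1]


class SteadyStateError(RuntimeError):
    """Raised when the fixed-point solve fails; carries the best iterate."""

    def __init__(self, message: str, best: np.ndarray, residual: float):
        super().__init__(message)
        self.best = best
        self.residual = residual


def simulate(
    network: GeneNetwork,
    params: ParameterSet,
    x0,
    t_span: tuple[float, float],
    grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the ODE from ``x0`` over ``t_span``.

    ``grid`` selects output times (defaults to 200 uniform points).  A
    stiff-capable adaptive method is used with the analytic state
    Jacobian; tiny negative excursions are clipped to zero in the output
    only, never inside the solver.
    """
    params.validate_against(network)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (network.N,):
        raise ValueError(f"x0 must have shape ({network.N},)")
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    if grid is None:
        grid = np.linspace(t_span[0], t_span[1], 200)
    grid = np.asarray(grid, dtype=float)

    def fun(t, x):
        return rhs(network, params, np.clip(x, 0.0, None))

    def jac(t, x):
        return rhs_state_jacobian(network, params, np.clip(x, 0.0, None))

    sol = solve_ivp(
        fun,
        t_span,
        x0,
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=sol.t, states=np.clip(sol.y.T, 0.0, None))


def _fixed_point_map(network: GeneNetwork, params: ParameterSet, x: np.ndarray) -> np.ndarray:
    """G(x) = production(x) / S; steady states satisfy x = G(x)."""
    return _production(network, params, x) / params.S


def steady_state(
    network: GeneNetwork,
    params: ParameterSet,
    x_guess,
    alpha: float = 0.5,
    max_iter: int = 500,
    rel_tol: float = 1e-8,
) -> np.ndarray:
    """Solve the fixed point ``x = production(x)/S``.

    Damped fixed-point iteration ``x <- (1-alpha) x + alpha G(x)`` — robust
    because G is bounded — with a Newton-type root solve on ``x - G(x)`` as
    fallback.  Converged when ``||x - G(x)||_inf < rel_tol * ||x||_inf``.
    """
    params.validate_against(network)
    x = np.asarray(x_guess, dtype=float).copy()
    if x.shape != (network.N,):
        raise ValueError(f"x_guess must have shape ({network.N},)")
    if np.any(x <= 0):
        raise ValueError("x_guess must be strictly positive")

    def residual_norm(x):
        return float(np.max(np.abs(x - _fixed_point_map(network, params, x))))

    best, best_res = x, residual_norm(x)
    for _ in range(max_iter):
        g = _fixed_point_map(network, params, x)
        x = (1.0 - alpha) * x + alpha * g
        res = residual_norm(x)
        if res < best_res:
            best, best_res = x, res
        if res < rel_tol * max(1e-300, float(np.max(np.abs(x)))):
            return np.clip(x, 0.0, None)
    # Newton fallback on F(x) = x - G(x)
    sol = root(
        lambda z: z - _fixed_point_map(network, params, np.clip(z, 0.0, None)),
        best,
        method="hybr",
    )
    if sol.success:
        x = np.clip(sol.x, 0.0, None)
        res = residual_norm(np.where(x > 0, x, 1e-300))
        if res < rel_tol * max(1e-300, float(np.max(np.abs(x)))):
            return x
        if res < best_res:
            best, best_res = x, res
    raise SteadyStateError(
        f"steady-state solve did not converge (residual {best_res:.3e})",
        best=best,
        residual=best_res,
    )


def steady_state_sse(model_ss, reference) -> float:
    """Sum of squared differences between two concentration vectors."""
    model_ss = np.asarray(model_ss, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model_ss.shape != reference.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sum((reference - model_ss) ** 2))
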