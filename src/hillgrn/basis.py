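"""Clamped uniform B-spline basis, quadrature grid, and smoothing fits.

The basis represents each gene trajectory as ``x_i(t) = c_i . phi(t)`` with
a shared basis system ``phi``.  ``n_knots`` counts the breakpoints of the
piecewise polynomial *including both endpoints*; with a clamped uniform
knot vector the basis dimension is ``n_knots + order - 2``.  "Order" is
degree + 1 (order 4 = cubic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "SplineCoefficients", "smoothing_fit"]


class SplineBasis:
    """Vector-valued B-spline basis on ``[t0, tf]``.

    Parameters
    ----------
    t0, tf
        Domain endpoints, ``t0 < tf``.
    order
        Polynomial order (degree + 1); default 4.
    n_knots
        Number of breakpoints including both endpoints; default 100.
    """

    def __init__(self, t0: float, tf: float, order: int = 4, n_knots: int = 100):
        if not tf > t0:
            raise ValueError("domain must satisfy t0 < tf")
        if order < 1:
            raise ValueError("order must be >= 1")
        if n_knots < 2:
            raise ValueError("need at least 2 knots (the domain endpoints)")
        self.t0 = float(t0)
        self.tf = float(tf)
        self.order = int(order)
        self.n_knots = int(n_knots)
        self.degree = self.order - 1
        self.breakpoints = np.linspace(self.t0, self.tf, self.n_knots)
        self.knot_vector = np.concatenate(
            [
                np.full(self.degree, self.t0),
                self.breakpoints,
                np.full(self.degree, self.tf),
            ]
        )
        self.n_basis = self.n_knots + self.order - 2
        eye = np.eye(self.n_basis)
        self._spline = BSpline(self.knot_vector, eye, self.degree, extrapolate=False)
        self._dspline = self._spline.derivative() if self.degree >= 1 else None

    def _check_domain(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tol = 1e-12 * (self.tf - self.t0)
        if np.any(t < self.t0 - tol) or np.any(t > self.tf + tol):
            raise ValueError(
                f"evaluation times must lie in [{self.t0}, {self.tf}]"
            )
        return np.clip(t, self.t0, self.tf)

    def eval(self, t) -> np.ndarray:
        """Design matrix of basis values; one row per time, one column per
        basis function.  Rows sum to 1 (partition of unity)."""
        t = self._check_domain(t)
        return self._spline(t)

    def eval_deriv(self, t) -> np.ndarray:
        """Design matrix of first-derivative values; rows sum to 0."""
        t = self._check_domain(t)
        if self._dspline is None:
            return np.zeros((len(t), self.n_basis))
        return self._dspline(t)

    def quadrature_grid(self, points_per_interval: int = 5) -> tuple[np.ndarray, np.ndarray]:
        """Composite Gauss-Legendre nodes and weights over the breakpoint
        intervals.  Weights sum to ``tf - t0``; the rule is exact for
        polynomials of degree ``2*points_per_interval - 1`` per interval."""
        if points_per_interval < 1:
            raise ValueError("points_per_interval must be >= 1")
        nodes, weights = np.polynomial.legendre.leggauss(points_per_interval)
        a = self.breakpoints[:-1]
        b = self.breakpoints[1:]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        t = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
        w = (half[:, None] * weights[None, :]).ravel()
        order = np.argsort(t, kind="stable")
        return t[order], w[order]


@dataclass(frozen=True)
class SplineCoefficients:
    """Per-gene coefficient vectors, stored as a matrix ``C`` of shape
    ``(n_genes, n_basis)``; ``stacked()`` concatenates the gene blocks."""

    C: np.ndarray

    def __init__(self, C) -> None:
        C = np.asarray(C, dtype=float)
        if C.ndim != 2:
            raise ValueError("coefficients must be a (n_genes, n_basis) matrix")
        object.__setattr__(self, "C", C)

    @property
    def n_genes(self) -> int:
        return self.C.shape[0]

    @property
    def n_basis(self) -> int:
        return self.C.shape[1]

    def stacked(self) -> np.ndarray:
        return self.C.ravel()

    @classmethod
    def from_stacked(cls, vec, n_genes: int, n_basis: int) -> "SplineCoefficients":
        vec = np.asarray(vec, dtype=float)
        return cls(vec.reshape(n_genes, n_basis))

    def curves(self, basis: SplineBasis, t) -> np.ndarray:
        """Reconstructed trajectories, shape ``(len(t), n_genes)``."""
        return basis.eval(t) @ self.C.T

    def curve_derivs(self, basis: SplineBasis, t) -> np.ndarray:
        return basis.eval_deriv(t) @ self.C.T


def smoothing_fit(basis: SplineBasis, times, values, ridge: float = 1e-8) -> SplineCoefficients:
    """Penalty-free least-squares spline fit of observed trajectories.

    Used to initialize the profiled inner problem.  ``values`` is a
    ``(n_times, n_genes)`` array; NaN marks a missing observation.  The
    ridge term (default 1e-8) makes the normal equations well-posed when
    the basis is richer than the data; with ``ridge=0`` the minimum-norm
    least-squares solution is returned.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(times):
        raise ValueError("values must have one row per observation time")
    if len(times) < 2:
        raise ValueError("need at least 2 observation times")
    phi = basis.eval(times)
    n_genes = values.shape[1]
    C = np.empty((n_genes, basis.n_basis))
    for i in range(n_genes):
        mask = ~np.isnan(values[:, i])
        if not mask.any():
            raise ValueError(f"gene column {i} has no observations")
        A = phi[mask]
        y = values[mask, i]
        if ridge == 0:
            C[i] = np.linalg.lstsq(A, y, rcond=None)[0]
        else:
            gram = A.T @ A + ridge * np.eye(basis.n_basis)
            C[i] = np.linalg.solve(gram, A.T @ y)
    return SplineCoefficients(C)
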