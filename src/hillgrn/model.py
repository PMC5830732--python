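"""Gene regulatory network structure and Hill-kinetics ODE right-hand side.

A network is a directed signed graph over genes.  Each gene *i* has a
synthesis rate constant ``P[i]`` and a degradation rate constant ``S[i]``;
each regulatory edge carries a threshold ``Q`` and a cooperativity exponent
``R``.  The production of gene *i* is ``P[i]`` times the product of one Hill
factor per incoming edge (inhibiting factors in ``(0, 1]``, activating
factors in ``[1, 2)``), and degradation is linear, ``-S[i]*x[i]``.

All kinetic parameters are strictly positive.  The unconstrained
log-parameterization (``p = ln P`` etc.) removes the positivity constraint:
any real log-vector maps back to valid positive parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ACTIVATING",
    "INHIBITING",
    "GeneNetwork",
    "ParameterSet",
    "LogParameterSet",
    "hill_inhibitor",
    "hill_activator",
    "rhs",
    "rhs_state_jacobian",
    "rhs_log_param_jacobian",
    "to_log",
    "from_log",
    "parameter_count",
]

ACTIVATING = 1
INHIBITING = -1

_SIGN_CHARS = {"+": ACTIVATING, "-": INHIBITING}


@dataclass(frozen=True)
class GeneNetwork:
    """Signed directed graph of regulatory interactions.

    Parameters
    ----------
    gene_names
        Ordered, unique gene identifiers; defines the state ordering.
    edges
        ``(regulator_index, target_index, sign)`` triples with sign
        ``+1`` (activating) or ``-1`` (inhibiting), in parameter order:
        edge ``k`` owns threshold ``Q[k]`` and exponent ``R[k]``.
    """

    gene_names: tuple[str, ...]
    edges: tuple[tuple[int, int, int], ...]

    def __init__(
        self,
        gene_names: Sequence[str],
        edges: Sequence[tuple[int, int, int]],
    ) -> None:
        names = tuple(str(g) for g in gene_names)
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        n = len(names)
        canon = []
        seen_pairs = set()
        for regulator, target, sign in edges:
            regulator, target, sign = int(regulator), int(target), int(sign)
            if not (0 <= regulator < n and 0 <= target < n):
                raise ValueError(
                    f"edge ({regulator}, {target}) references a gene index "
                    f"outside 0..{n - 1}"
                )
            if sign not in (ACTIVATING, INHIBITING):
                raise ValueError(f"edge sign must be +1 or -1, got {sign}")
            if (regulator, target) in seen_pairs:
                raise ValueError(
                    f"duplicate edge: regulator {regulator} -> target {target}"
                )
            seen_pairs.add((regulator, target))
            canon.append((regulator, target, sign))
        object.__setattr__(self, "gene_names", names)
        object.__setattr__(self, "edges", tuple(canon))

    @property
    def N(self) -> int:
        """Number of genes."""
        return len(self.gene_names)

    @property
    def M(self) -> int:
        """Number of regulatory edges."""
        return len(self.edges)

    def gene_index(self, name: str) -> int:
        return self.gene_names.index(name)

    def regulator_indices(self) -> np.ndarray:
        return np.array([e[0] for e in self.edges], dtype=int)

    def target_indices(self) -> np.ndarray:
        return np.array([e[1] for e in self.edges], dtype=int)

    def signs(self) -> np.ndarray:
        return np.array([e[2] for e in self.edges], dtype=int)

    def activators(self, target: int) -> list[int]:
        """Regulator indices of activating edges into ``target``."""
        return [r for r, t, s in self.edges if t == target and s == ACTIVATING]

    def inhibitors(self, target: int) -> list[int]:
        """Regulator indices of inhibiting edges into ``target``."""
        return [r for r, t, s in self.edges if t == target and s == INHIBITING]


def _as_positive_array(values, length: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (length,):
        raise ValueError(f"{what} must have shape ({length},), got {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{what} entries must be finite and strictly positive")
    return arr


@dataclass(frozen=True)
class ParameterSet:
    """Positive-scale kinetic parameters aligned with a :class:`GeneNetwork`.

    ``P`` and ``S`` are per-gene (length ``N``), ``Q`` and ``R`` per-edge
    (length ``M``, in edge order).  Total count is ``2*(M+N)``.
    """

    P: np.ndarray
    S: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __init__(self, P, S, Q, R) -> None:
        P = np.atleast_1d(np.asarray(P, dtype=float))
        Q = np.atleast_1d(np.asarray(Q, dtype=float))
        object.__setattr__(self, "P", _as_positive_array(P, P.shape[0], "P"))
        object.__setattr__(self, "S", _as_positive_array(S, len(self.P), "S"))
        object.__setattr__(self, "Q", _as_positive_array(Q, Q.shape[0], "Q"))
        object.__setattr__(self, "R", _as_positive_array(R, len(self.Q), "R"))

    @property
    def n_genes(self) -> int:
        return len(self.P)

    @property
    def n_edges(self) -> int:
        return len(self.Q)

    def validate_against(self, network: GeneNetwork) -> None:
        if self.n_genes != network.N or self.n_edges != network.M:
            raise ValueError(
                f"parameter shapes (N={self.n_genes}, M={self.n_edges}) do not "
                f"match network (N={network.N}, M={network.M})"
            )


@dataclass(frozen=True)
class LogParameterSet:
    """Unconstrained log-scale parameters ``p=ln P``, ``q=ln Q`` etc.

    The stacked vector ordering is ``[p (N), q (M), s (N), r (M)]`` so that
    the first ``M+2N`` coordinates form the non-exponent block (theta_p)
    and the trailing ``M`` coordinates the cooperativity block (theta_r).
    """

    p: np.ndarray
    q: np.ndarray
    s: np.ndarray
    r: np.ndarray

    def __init__(self, p, q, s, r) -> None:
        for name, v in (("p", p), ("q", q), ("s", s), ("r", r)):
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} entries must be finite")
            object.__setattr__(self, name, arr)
        if len(self.p) != len(self.s) or len(self.q) != len(self.r):
            raise ValueError("p/s and q/r length mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.p)

    @property
    def n_edges(self) -> int:
        return len(self.q)

    def to_vector(self) -> np.ndarray:
        """Stack as ``[p, q, s, r]`` (theta_p block first, theta_r last)."""
        return np.concatenate([self.p, self.q, self.s, self.r])

    @classmethod
    def from_vector(cls, vec, n_genes: int, n_edges: int) -> "LogParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (2 * (n_genes + n_edges),):
            raise ValueError(
                f"expected vector of length {2 * (n_genes + n_edges)}, "
                f"got {vec.shape}"
            )
        n, m = n_genes, n_edges
        return cls(
            p=vec[:n],
            q=vec[n : n + m],
            s=vec[n + m : 2 * n + m],
            r=vec[2 * n + m :],
        )

    def theta_p_mask(self) -> np.ndarray:
        """Boolean mask of the non-exponent block in vector order."""
        n, m = self.n_genes, self.n_edges
        mask = np.zeros(2 * (n + m), dtype=bool)
        mask[: 2 * n + m] = True
        return mask

    def theta_r_mask(self) -> np.ndarray:
        """Boolean mask of the cooperativity block in vector order."""
        return ~self.theta_p_mask()


def _log_ratio(x: np.ndarray, Q, R) -> np.ndarray:
    """R * ln(x/Q) with x == 0 mapped to -inf (no log-of-zero warning)."""
    x = np.asarray(x, dtype=float)
    out = np.full(np.broadcast(x, Q, R).shape, -np.inf)
    pos = np.broadcast_to(x > 0, out.shape)
    xb = np.broadcast_to(x, out.shape)
    Qb = np.broadcast_to(np.asarray(Q, dtype=float), out.shape)
    Rb = np.broadcast_to(np.asarray(R, dtype=float), out.shape)
    out[pos] = Rb[pos] * (np.log(xb[pos]) - np.log(Qb[pos]))
    return out


def _check_hill_args(x, Q, R) -> None:
    if np.any(np.asarray(x, dtype=float) < 0):
        raise ValueError("concentration x must be non-negative")
    if np.any(np.asarray(Q, dtype=float) <= 0):
        raise ValueError("threshold Q must be strictly positive")
    if np.any(np.asarray(R, dtype=float) <= 0):
        raise ValueError("cooperativity R must be strictly positive")


def hill_inhibitor(x, Q, R):
    """Inhibiting Hill factor ``Q^R / (x^R + Q^R)``.

    Equals 1 at ``x = 0``, 1/2 at ``x = Q``, and decays to 0 as ``x``
    grows.  Computed as a logistic in ``R*ln(x/Q)`` so that extreme
    thresholds or exponents cannot overflow.
    """
    _check_hill_args(x, Q, R)
    val = expit(-_log_ratio(x, Q, R))
    return float(val) if np.ndim(val) == 0 else val


def hill_activator(x, Q, R):
    """Activating Hill factor ``1 + x^R / (x^R + Q^R)``.

    Equals 1 at ``x = 0``, 3/2 at ``x = Q``, and saturates at 2.
    """
    _check_hill_args(x, Q, R)
    val = 1.0 + expit(_log_ratio(x, Q, R))
    return float(val) if np.ndim(val) == 0 else val


def _edge_factors(network: GeneNetwork, params: ParameterSet, x: np.ndarray) -> np.ndarray:
    """Hill factor of every edge, for states ``x`` of shape (..., N)."""
    reg = network.regulator_indices()
    sgn = network.signs()
    u = _log_ratio(x[..., reg], params.Q, params.R)
    return np.where(sgn == ACTIVATING, 1.0 + expit(u), expit(-u))


def _production(network: GeneNetwork, params: ParameterSet, x: np.ndarray) -> np.ndarray:
    """P_i times the product of incoming Hill factors; shape (..., N)."""
    h = _edge_factors(network, params, x)
    tgt = network.target_indices()
    prod = np.ones(x.shape)
    if network.M:
        # product over edges grouped by target, batched over leading axes
        flat = prod.reshape(-1, network.N)
        hflat = h.reshape(-1, network.M)
        for k in range(network.M):
            flat[:, tgt[k]] *= hflat[:, k]
    return params.P * prod


def rhs(network: GeneNetwork, params: ParameterSet, x) -> np.ndarray:
    """Time derivative of the concentration vector.

    ``x`` may be a single state of shape ``(N,)`` or a batch ``(T, N)``;
    the result has the same shape.  Genes with no regulators produce at
    the bare rate ``P_i`` (empty product).
    """
    params.validate_against(network)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != network.N:
        raise ValueError(
            f"state has {x.shape[-1]} components, network has {network.N} genes"
        )
    if np.any(x < 0):
        raise ValueError("state concentrations must be non-negative")
    return _production(network, params, x) - params.S * x


def rhs_state_jacobian(network: GeneNetwork, params: ParameterSet, x) -> np.ndarray:
    """Jacobian d(rhs_i)/d(x_j); shape ``(N, N)`` or batched ``(T, N, N)``.

    At ``x_j = 0`` the Hill-factor derivative is taken as 0 (one-sided
    limit for exponents > 1; a measure-zero boundary otherwise).
    """
    params.validate_against(network)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x.reshape(-1, network.N)
    T, N = xb.shape
    jac = np.zeros((T, N, N))
    prodP = _production(network, params, xb)  # (T, N)
    if network.M:
        reg = network.regulator_indices()
        tgt = network.target_indices()
        sgn = network.signs()
        u = _log_ratio(xb[:, reg], params.Q, params.R)  # (T, M)
        sig = expit(u)
        # d ln h / d x in cancellation-free form: for the inhibitor
        # h = 1 - sig, so (dh/dx)/h = -sig*R/x; for the activator
        # h = 1 + sig, so (dh/dx)/h = sig*(1-sig)*R/x/(1+sig)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = params.R / xb[:, reg]
            dlogh = np.where(
                xb[:, reg] > 0,
                np.where(
                    sgn == ACTIVATING,
                    sig * (1.0 - sig) / (1.0 + sig) * rate,
                    -sig * rate,
                ),
                0.0,
            )
        for k in range(network.M):
            jac[:, tgt[k], reg[k]] += prodP[:, tgt[k]] * dlogh[:, k]
    idx = np.arange(N)
    jac[:, idx, idx] -= params.S
    if single:
        return jac[0]
    return jac.reshape(x.shape[:-1] + (N, N))


def rhs_log_param_jacobian(
    network: GeneNetwork, logparams: LogParameterSet, x
) -> np.ndarray:
    """Jacobian of the rhs w.r.t. the stacked log-parameters ``[p, q, s, r]``.

    Shape ``(N, 2*(M+N))`` for a single state or ``(T, N, 2*(M+N))`` for a
    batch.  Derivatives are on the log scale (chain rule through ``exp``),
    which is what the outer optimization differentiates.
    """
    params = from_log(logparams, network)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x.reshape(-1, network.N)
    T, N = xb.shape
    M = network.M
    n_theta = 2 * (N + M)
    jac = np.zeros((T, N, n_theta))
    prodP = _production(network, params, xb)  # (T, N)
    idx = np.arange(N)
    # d f_i / d p_i = production_i ; d f_i / d s_i = -S_i x_i
    jac[:, idx, idx] = prodP
    jac[:, idx, N + M + idx] = -params.S * xb
    if M:
        reg = network.regulator_indices()
        tgt = network.target_indices()
        sgn = network.signs()
        u = _log_ratio(xb[:, reg], params.Q, params.R)  # (T, M)
        sig = expit(u)
        act = sgn == ACTIVATING
        # d ln h / d u: inhibitor h = 1 - sig -> -sig; activator
        # h = 1 + sig -> sig*(1-sig)/(1+sig)
        dlogh_du = np.where(act, sig * (1.0 - sig) / (1.0 + sig), -sig)
        # u = R*(ln x - q): du/dq = -R; du/dr = u (since r = ln R)
        with np.errstate(invalid="ignore"):
            du_dr = np.where(np.isfinite(u), u, 0.0)  # sig=0 kills the -inf
        dq = dlogh_du * (-params.R)
        dr = dlogh_du * du_dr
        for k in range(M):
            jac[:, tgt[k], N + k] = prodP[:, tgt[k]] * dq[:, k]
            jac[:, tgt[k], N + M + N + k] = prodP[:, tgt[k]] * dr[:, k]
    if single:
        return jac[0]
    return jac.reshape(x.shape[:-1] + (N, n_theta))


def to_log(params: ParameterSet) -> LogParameterSet:
    """Elementwise natural logarithm onto the unconstrained scale."""
    return LogParameterSet(
        p=np.log(params.P), q=np.log(params.Q), s=np.log(params.S), r=np.log(params.R)
    )


def from_log(logparams: LogParameterSet, network: GeneNetwork | None = None) -> ParameterSet:
    """Elementwise exponential back to the positive scale.

    Always yields a strictly positive :class:`ParameterSet` for any real
    input.  If ``network`` is given, shapes are validated against it.
    """
    params = ParameterSet(
        P=np.exp(logparams.p),
        S=np.exp(logparams.s),
        Q=np.exp(logparams.q),
        R=np.exp(logparams.r),
    )
    if network is not None:
        params.validate_against(network)
    return params


def parameter_count(network: GeneNetwork) -> tuple[int, int, int]:
    """Return ``(total, non-exponent block size, exponent block size)``,
    i.e. ``(2*(M+N), M+2N, M)``."""
    n, m = network.N, network.M
    return 2 * (m + n), m + 2 * n, m
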