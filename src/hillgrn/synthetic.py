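"""Synthetic networks, ground-truth parameters, and noisy sparse datasets.

Everything is seeded explicitly; the same spec always yields the same
network, truth, and dataset.  Default parameter ranges are calibrated to
the span of the SOS case-study estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory, simulate
from .estimator import TimeSeriesData
from .model import ACTIVATING, INHIBITING, GeneNetwork, ParameterSet

__all__ = [
    "SyntheticSpec",
    "apply_noise",
    "generate_network",
    "generate_truth",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic problem instance.

    ``n_edges`` may not exceed ``n_genes**2`` (one edge per ordered
    regulator/target pair, self-loops allowed).  Parameter ranges are
    log-uniform bounds; ``noise`` is ``'lognormal'`` (multiplicative) or
    ``'gaussian'`` (additive, clamped at zero).
    """

    n_genes: int
    n_edges: int
    seed: int
    activator_fraction: float = 0.5
    p_range: tuple[float, float] = (0.2, 35.0)
    s_range: tuple[float, float] = (0.02, 1.2)
    q_range: tuple[float, float] = (0.5, 400.0)
    r_range: tuple[float, float] = (0.6, 5.0)
    x0_range: tuple[float, float] = (1.0, 20.0)
    n_times: int = 25
    t_span: tuple[float, float] = (0.0, 50.0)
    noise: str = "lognormal"
    sigma: float = 0.0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if not 0 <= self.n_edges <= self.n_genes**2:
            raise ValueError(
                f"n_edges must be in [0, {self.n_genes**2}] for {self.n_genes} genes"
            )
        if not 0.0 <= self.activator_fraction <= 1.0:
            raise ValueError("activator_fraction must be in [0, 1]")
        for name in ("p_range", "s_range", "q_range", "r_range", "x0_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} bounds must be positive and ordered")
        if self.noise not in ("lognormal", "gaussian"):
            raise ValueError("noise must be 'lognormal' or 'gaussian'")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_times < 2:
            raise ValueError("need at least two sample times")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def generate_network(spec: SyntheticSpec) -> GeneNetwork:
    """Random signed edge set, uniform over ordered gene pairs without
    duplicates (self-loops allowed)."""
    rng = _rng(spec, 0)
    n = spec.n_genes
    pair_ids = rng.choice(n * n, size=spec.n_edges, replace=False)
    signs = np.where(
        rng.random(spec.n_edges) < spec.activator_fraction, ACTIVATING, INHIBITING
    )
    names = tuple(f"g{i+1}" for i in range(n))
    edges = tuple(
        (int(pid % n), int(pid // n), int(s)) for pid, s in zip(pair_ids, signs)
    )
    return GeneNetwork(names, edges)


def _log_uniform(rng, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_truth(network: GeneNetwork, spec: SyntheticSpec) -> ParameterSet:
    """Log-uniform ground-truth parameters inside the spec ranges."""
    rng = _rng(spec, 1)
    return ParameterSet(
        P=_log_uniform(rng, *spec.p_range, network.N),
        S=_log_uniform(rng, *spec.s_range, network.N),
        Q=_log_uniform(rng, *spec.q_range, network.M),
        R=_log_uniform(rng, *spec.r_range, network.M),
    )


def apply_noise(
    clean: np.ndarray, sigma: float, model: str, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt noise-free values: multiplicative log-normal
    (``exp(N(0, sigma^2))`` factors) or additive Gaussian clamped at zero."""
    clean = np.asarray(clean, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return clean.copy()
    if model == "lognormal":
        return clean * np.exp(rng.normal(0.0, sigma, size=clean.shape))
    if model == "gaussian":
        return np.clip(clean + rng.normal(0.0, sigma, size=clean.shape), 0.0, None)
    raise ValueError("noise model must be 'lognormal' or 'gaussian'")


def generate_dataset(
    network: GeneNetwork, truth: ParameterSet, spec: SyntheticSpec
) -> tuple[TimeSeriesData, Trajectory]:
    """Simulate from a random positive initial state, sample, add noise.

    Returns the noisy observations together with the noise-free
    trajectory at the sample times.  All emitted values are >= 0.
    """
    rng = _rng(spec, 2)
    x0 = _log_uniform(rng, *spec.x0_range, network.N)
    times = np.linspace(spec.t_span[0], spec.t_span[1], spec.n_times)
    traj = simulate(network, truth, x0, spec.t_span, grid=times)
    noisy = apply_noise(traj.states, spec.sigma, spec.noise, rng)
    data = TimeSeriesData(
        times=times,
        values=noisy,
        t0=spec.t_span[0],
        tf=spec.t_span[1],
        gene_names=network.gene_names,
    )
    return data, traj
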