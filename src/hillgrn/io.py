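"""File formats: network edge lists, time-series tables, parameter files,
and run configuration.

* Network: tab-separated ``regulator  target  sign`` with sign ``+``/``-``;
  ``#`` starts a comment.  A ``# genes:`` directive fixes the state
  ordering; otherwise order of first appearance is used.
* Time series: CSV with header ``time,<gene1>,...``; empty cells are
  missing observations.
* Parameters: JSON with arrays ``P``, ``S`` (per gene) and ``Q``, ``R``
  (per edge, in edge order); the log dialect uses ``log_p`` etc.
* Config: YAML mapping onto :class:`RunConfig`; unknown keys rejected.

All numeric output is written with 12 significant digits so reruns can be
compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimator import GPMConfig, TimeSeriesData
from .model import (
    ACTIVATING,
    INHIBITING,
    GeneNetwork,
    LogParameterSet,
    ParameterSet,
)

__all__ = [
    "read_network",
    "write_network",
    "read_timeseries",
    "write_timeseries",
    "read_params",
    "write_params",
    "RunConfig",
]

_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FMT % x


def read_network(path) -> GeneNetwork:
    path = Path(path)
    declared_order: list[str] | None = None
    raw_edges: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("genes:"):
                declared_order = body[len("genes:"):].replace(",", " ").split()
            continue
        fields = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(fields) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 'regulator<TAB>target<TAB>sign', got {stripped!r}"
            )
        regulator, target, sign = fields
        if sign not in ("+", "-"):
            raise ValueError(
                f"{path}:{lineno}: unknown sign {sign!r} (use '+' or '-')"
            )
        raw_edges.append((regulator, target, sign))
    if not raw_edges:
        raise ValueError(f"{path}: no edges found")
    if declared_order is not None:
        names = declared_order
    else:
        names = []
        for regulator, target, _ in raw_edges:
            for g in (regulator, target):
                if g not in names:
                    names.append(g)
    index = {g: i for i, g in enumerate(names)}
    edges = []
    for regulator, target, sign in raw_edges:
        for g in (regulator, target):
            if g not in index:
                raise ValueError(
                    f"{path}: gene {g!r} not in the declared gene order"
                )
        edges.append(
            (index[regulator], index[target], ACTIVATING if sign == "+" else INHIBITING)
        )
    return GeneNetwork(names, edges)


def write_network(network: GeneNetwork, path) -> None:
    lines = ["# genes: " + " ".join(network.gene_names)]
    for regulator, target, sign in network.edges:
        lines.append(
            f"{network.gene_names[regulator]}\t{network.gene_names[target]}\t"
            f"{'+' if sign == ACTIVATING else '-'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_timeseries(path, t0=None, tf=None) -> TimeSeriesData:
    frame = pd.read_csv(path)
    if frame.columns[0] != "time":
        raise ValueError(f"{path}: first CSV column must be 'time'")
    genes = list(frame.columns[1:])
    if not genes:
        raise ValueError(f"{path}: no gene columns")
    return TimeSeriesData(
        times=frame["time"].to_numpy(dtype=float),
        values=frame[genes].to_numpy(dtype=float),
        t0=t0,
        tf=tf,
        gene_names=genes,
    )


def write_timeseries(data: TimeSeriesData, path) -> None:
    genes = data.gene_names or tuple(f"g{i+1}" for i in range(data.n_genes))
    with open(path, "w") as fh:
        fh.write("time," + ",".join(genes) + "\n")
        for t, row in zip(data.times, data.values):
            cells = ["" if np.isnan(v) else _fmt(v) for v in row]
            fh.write(_fmt(t) + "," + ",".join(cells) + "\n")


def read_params(path) -> ParameterSet | LogParameterSet:
    """Read a parameter file; returns the log dialect if ``log_`` keys are
    present, the positive-scale dialect otherwise."""
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: parameter file must be a JSON object")
    log_keys = {"log_p", "log_q", "log_s", "log_r"}
    lin_keys = {"P", "S", "Q", "R"}
    present = set(payload)
    if log_keys <= present:
        return LogParameterSet(
            p=payload["log_p"], q=payload["log_q"], s=payload["log_s"], r=payload["log_r"]
        )
    if lin_keys <= present:
        return ParameterSet(
            P=payload["P"], S=payload["S"], Q=payload["Q"], R=payload["R"]
        )
    raise ValueError(
        f"{path}: expected keys P/S/Q/R or log_p/log_q/log_s/log_r, found {sorted(present)}"
    )


def write_params(params: ParameterSet | LogParameterSet, path) -> None:
    if isinstance(params, ParameterSet):
        payload = {
            "P": params.P, "S": params.S, "Q": params.Q, "R": params.R,
        }
    else:
        payload = {
            "log_p": params.p, "log_q": params.q,
            "log_s": params.s, "log_r": params.r,
        }
    rendered = {
        key: [float(_fmt(v)) for v in np.asarray(arr)] for key, arr in payload.items()
    }
    Path(path).write_text(json.dumps(rendered, indent=1) + "\n")


@dataclass(frozen=True)
class RunConfig:
    """Serializable run settings for the estimation pipeline."""

    order: int = 4
    n_knots: int = 100
    lam: float = 150.0
    quad_points: int = 5
    ridge: float = 1e-8
    inner_tol: float = 1e-8
    inner_max_iter: int = 200
    outer_tol: float = 1e-8
    outer_max_nfev: int = 400
    r_init: float = 2.0
    r_init_scale: str = "linear"
    loop_tol: float = 1e-3
    max_loops: int = 20
    seed: int | None = None
    out_dir: str = "."
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def gpm_config(self) -> GPMConfig:
        return GPMConfig(
            lam=self.lam,
            order=self.order,
            n_knots=self.n_knots,
            quad_points=self.quad_points,
            ridge=self.ridge,
            inner_tol=self.inner_tol,
            inner_max_iter=self.inner_max_iter,
            outer_tol=self.outer_tol,
            outer_max_nfev=self.outer_max_nfev,
        )
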