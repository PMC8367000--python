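"""Conjugate Beta-Binomial estimation of conditional probability tables.

Each node X of the binary network carries one local probability parameter
θ per configuration of its parents: θ = P(X = 1 | Pa(X) = config). With a
Beta(α, β) prior and k activations out of n observations in a stratum, the
posterior is Beta(α + k, β + n − k) and the point estimate used everywhere
downstream is its mean α′/(α′ + β′). With the default uniform Beta(1, 1)
prior this is the Laplace-smoothed frequency (k + 1)/(n + 2), strictly
inside (0, 1) — likelihood weights can therefore never be exactly zero.

Parent configurations are indexed by a bitmask over the node's parents in
network declaration order, parent 0 in the least-significant bit:
``index = sum(state(parents[i]) << i)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "BetaPrior",
    "CPTEntry",
    "NodeCPT",
    "CPTSet",
    "sufficient_stats",
    "posterior_update",
    "point_estimate",
    "fit_cpts",
]


@dataclass(frozen=True)
class BetaPrior:
    """Shape parameters of the Beta prior on each θ. Default Beta(1, 1),
    the standard uniform on [0, 1] (no prior information)."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"Beta prior requires positive shapes, got {self}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class CPTEntry:
    """One stratum of a node's table: counts, posterior shapes, point estimate."""

    node: str
    parent_config: dict[str, int]
    n: int
    k: int
    alpha_post: float
    beta_post: float
    theta: float


@dataclass(frozen=True)
class NodeCPT:
    """Dense table for one node: arrays of length ``2**len(parents)`` indexed
    by the parent-state bitmask (parents in declaration order, parent 0 in
    the least-significant bit)."""

    node: str
    parents: tuple[str, ...]
    n: np.ndarray
    k: np.ndarray
    theta: np.ndarray
    alpha_post: np.ndarray
    beta_post: np.ndarray

    @property
    def n_configs(self) -> int:
        return 1 << len(self.parents)

    def config_index(self, parent_states: Mapping[str, int]) -> int:
        idx = 0
        for i, p in enumerate(self.parents):
            idx |= (int(parent_states[p]) & 1) << i
        return idx

    def theta_for(self, parent_states: Mapping[str, int]) -> float:
        return float(self.theta[self.config_index(parent_states)])

    def entries(self) -> Iterator[CPTEntry]:
        for idx in range(self.n_configs):
            config = {p: (idx >> i) & 1 for i, p in enumerate(self.parents)}
            yield CPTEntry(
                node=self.node,
                parent_config=config,
                n=int(self.n[idx]),
                k=int(self.k[idx]),
                alpha_post=float(self.alpha_post[idx]),
                beta_post=float(self.beta_post[idx]),
                theta=float(self.theta[idx]),
            )


@dataclass
class CPTSet:
    """All node tables for a network, plus fitting provenance."""

    tables: dict[str, NodeCPT]
    prior: BetaPrior = field(default_factory=BetaPrior)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, node: str) -> NodeCPT:
        return self.tables[node]

    def __contains__(self, node: str) -> bool:
        return node in self.tables

    def nodes(self) -> list[str]:
        return list(self.tables)

    def covers(self, net: Network) -> bool:
        return all(
            n in self.tables and self.tables[n].parents == net.parents(n)
            for n in net.nodes
        )

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "prior": {"alpha": self.prior.alpha, "beta": self.prior.beta},
            "provenance": self.provenance,
            "cpts": {
                node: [
                    {
                        "config": e.parent_config,
                        "n": e.n,
                        "k": e.k,
                        "alpha_post": e.alpha_post,
                        "beta_post": e.beta_post,
                        "theta": e.theta,
                    }
                    for e in tab.entries()
                ]
                for node, tab in self.tables.items()
            },
            "parents": {node: list(tab.parents) for node, tab in self.tables.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CPTSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        prior = BetaPrior(**payload.get("prior", {}))
        tables: dict[str, NodeCPT] = {}
        for node, entries in payload["cpts"].items():
            parents = tuple(payload["parents"][node])
            size = 1 << len(parents)
            n = np.zeros(size, dtype=np.int64)
            k = np.zeros(size, dtype=np.int64)
            a = np.zeros(size)
            b = np.zeros(size)
            th = np.zeros(size)
            for e in entries:
                idx = 0
                for i, par in enumerate(parents):
                    idx |= (int(e["config"][par]) & 1) << i
                n[idx], k[idx] = e["n"], e["k"]
                a[idx], b[idx], th[idx] = e["alpha_post"], e["beta_post"], e["theta"]
            tables[node] = NodeCPT(node, parents, n, k, th, a, b)
        return cls(tables=tables, prior=prior, provenance=payload.get("provenance", {}))


def sufficient_stats(
    data: pd.DataFrame, net: Network, node: str
) -> list[tuple[dict[str, int], int, int]]:
    """Stratified counts for ``node``: for each of the ``2**|parents|``
    parent configurations, ``(config, n, k)`` with n = rows matching the
    configuration and k = those rows with node = 1. Configurations never
    observed return ``(config, 0, 0)``.
    """
    if node not in net.nodes:
        raise KeyError(f"node {node!r} not in network")
    if node not in data.columns:
        raise KeyError(f"node {node!r} not in dataset columns")
    parents = net.parents(node)
    missing = [p for p in parents if p not in data.columns]
    if missing:
        raise KeyError(f"parent column(s) missing from dataset: {missing}")
    n_arr, k_arr = _stratified_counts(data, parents, node)
    out = []
    for idx in range(1 << len(parents)):
        config = {p: (idx >> i) & 1 for i, p in enumerate(parents)}
        out.append((config, int(n_arr[idx]), int(k_arr[idx])))
    return out


def _stratified_counts(
    data: pd.DataFrame, parents: tuple[str, ...], node: str
) -> tuple[np.ndarray, np.ndarray]:
    size = 1 << len(parents)
    x = data[node].to_numpy(dtype=np.int64)
    if parents:
        idx = np.zeros(len(data), dtype=np.int64)
        for i, p in enumerate(parents):
            idx |= data[p].to_numpy(dtype=np.int64) << i
    else:
        idx = np.zeros(len(data), dtype=np.int64)
    n = np.bincount(idx, minlength=size)
    k = np.bincount(idx, weights=x, minlength=size).astype(np.int64)
    return n, k


def posterior_update(prior: BetaPrior, n: int, k: int) -> tuple[float, float]:
    """Conjugate update: ``(α + k, β + n − k)``."""
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"invalid counts n={n}, k={k}")
    return prior.alpha + k, prior.beta + (n - k)


def point_estimate(alpha_post: float, beta_post: float) -> float:
    """Posterior mean ``α′/(α′ + β′)``; strictly inside (0, 1)."""
    if not (alpha_post > 0 and beta_post > 0):
        raise ValueError(f"posterior shapes must be positive, got ({alpha_post}, {beta_post})")
    return alpha_post / (alpha_post + beta_post)


def fit_cpts(
    net: Network, data: pd.DataFrame, prior: BetaPrior | None = None
) -> CPTSet:
    """Fit every node's table from a binary dataset.

    Unobserved parent configurations keep the prior, so their point estimate
    is the prior mean (0.5 under the default uniform prior) — expected with
    ~100 observations against up to ``2**|Pa|`` strata.
    """
    prior = prior or BetaPrior()
    missing = [n for n in net.nodes if n not in data.columns]
    if missing:
        raise KeyError(f"dataset lacks column(s) for node(s): {missing}")
    bad = [
        c for c in net.nodes if not np.isin(data[c].to_numpy(), (0, 1)).all()
    ]
    if bad:
        raise ValueError(f"non-binary values in column(s): {bad}")
    tables: dict[str, NodeCPT] = {}
    for node in net.nodes:
        parents = net.parents(node)
        n_arr, k_arr = _stratified_counts(data, parents, node)
        a = prior.alpha + k_arr
        b = prior.beta + (n_arr - k_arr)
        theta = a / (a + b)
        tables[node] = NodeCPT(node, parents, n_arr, k_arr, theta, a, b)
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(data[list(net.nodes)], index=False).to_numpy().tobytes()
    ).hexdigest()[:16]
    provenance = {
        "prior": {"alpha": prior.alpha, "beta": prior.beta},
        "n_observations": int(len(data)),
        "dataset_hash": digest,
        "fitted_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return CPTSet(tables=tables, prior=prior, provenance=provenance)
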