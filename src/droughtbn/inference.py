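"""Likelihood-weighting inference and an exact enumeration oracle.

Likelihood weighting (LW) estimates Pr(Q = q | E = e) in a discrete
Bayesian network by importance sampling: evidence nodes are clamped to
their observed states, every other node is sampled ancestrally from its
local distribution given its (already assigned) parents, and each joint
sample is weighted by the likelihood of the evidence under its sampled
parents,

    W_i = prod_{X in E} P(X = x_e | Pa(X)^{(i)}).

The estimator is the weight-normalised indicator sum

    Pr(Q = q | E = e)  ~=  sum_i W_i 1[q^{(i)} = q] / sum_i W_i.

Sampling is vectorised: all M draws for one node are generated at once,
nodes visited in the network's deterministic topological order. A single
`numpy` Generator seeded from the run seed drives everything, consumed in
that documented node order, so a (seed, M) pair fully reproduces a run.

`exact_query` is the validation oracle: it prunes the network to the
ancestral closure of query ∪ evidence (barren-node removal, which leaves
the conditional untouched) and sums the factored joint over all remaining
states in chunks. It exists to cross-check LW, not to replace it — the
guard on enumerable size is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import CPTSet
from .network import Network, topological_order

__all__ = [
    "Evidence",
    "Query",
    "WeightedSampleSet",
    "QueryResult",
    "lw_sample",
    "lw_sample_batch",
    "lw_estimate",
    "query_lw",
    "exact_query",
]

Evidence = Mapping[str, int]


@dataclass(frozen=True)
class Query:
    """The node whose conditional probability is being estimated, and the
    state of interest (1 = activation, 0 = inhibition)."""

    node: str
    state: int

    def __post_init__(self) -> None:
        if self.state not in (0, 1):
            raise ValueError(f"query state must be 0 or 1, got {self.state}")


@dataclass
class WeightedSampleSet:
    """M joint samples with their likelihood weights.

    Evidence columns are constant at the clamped values across all rows;
    with θ strictly inside (0, 1) every weight lies in (0, 1].
    """

    samples: pd.DataFrame
    weights: np.ndarray
    evidence: dict[str, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.weights):
            raise ValueError("samples and weights disagree on M")
        if len(self.samples) < 1:
            raise ValueError("need at least one sample")

    @property
    def M(self) -> int:
        return len(self.samples)

    def to_csv(self, path: str | Path) -> None:
        out = self.samples.copy()
        out["weight"] = self.weights
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, evidence: Evidence | None = None
    ) -> "WeightedSampleSet":
        df = pd.read_csv(path)
        if "weight" not in df.columns:
            raise ValueError(f"{path}: no 'weight' column")
        weights = df["weight"].to_numpy(dtype=float)
        samples = df.drop(columns=["weight"]).astype(np.int8)
        if evidence is None:
            # infer: constant columns are candidates, but only trust explicit input
            evidence = {}
        return cls(samples=samples, weights=weights, evidence=dict(evidence))


@dataclass(frozen=True)
class QueryResult:
    query: Query
    evidence: dict[str, int]
    estimate: float
    se: float
    weight_sum: float
    M: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "query": {"node": self.query.node, "state": self.query.state},
            "evidence": self.evidence,
            "estimate": self.estimate,
            "se": self.se,
            "weight_sum": self.weight_sum,
            "M": self.M,
            "seed": self.seed,
        }


def _check_evidence(net: Network, evidence: Evidence) -> dict[str, int]:
    out: dict[str, int] = {}
    for node, state in evidence.items():
        if node not in net.nodes:
            raise KeyError(f"evidence node {node!r} not in network")
        if state not in (0, 1):
            raise ValueError(f"evidence state for {node!r} must be 0 or 1, got {state}")
        out[node] = int(state)
    return out


def lw_sample(
    net: Network,
    cpts: CPTSet,
    evidence: Evidence,
    rng: np.random.Generator,
) -> tuple[dict[str, int], float]:
    """Draw one weighted sample (mainly didactic; bulk runs use the
    vectorised :func:`lw_sample_batch`).

    Nodes are visited in topological order; evidence nodes are clamped and
    contribute their likelihood factor to the weight, all others are drawn
    from θ given the already-assigned parents. With no evidence the weight
    is exactly 1 (empty product).
    """
    ev = _check_evidence(net, evidence)
    state: dict[str, int] = {}
    weight = 1.0
    for node in topological_order(net):
        theta = cpts[node].theta_for(state)
        if node in ev:
            state[node] = ev[node]
            weight *= theta if ev[node] == 1 else 1.0 - theta
        else:
            state[node] = int(rng.random() < theta)
    return state, weight


def lw_sample_batch(
    net: Network,
    cpts: CPTSet,
    evidence: Evidence,
    M: int,
    rng: np.random.Generator | int | None = None,
) -> WeightedSampleSet:
    """Draw M weighted samples, vectorised over the sample axis.

    For each node in topological order, the parent-configuration index of
    every row is assembled as a bitmask and the matching θ looked up; the
    random stream is consumed node-by-node in that order.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    ev = _check_evidence(net, evidence)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cols: dict[str, np.ndarray] = {}
    weights = np.ones(M)
    for node in topological_order(net):
        tab = cpts[node]
        if tab.parents:
            idx = np.zeros(M, dtype=np.int64)
            for i, p in enumerate(tab.parents):
                idx |= cols[p].astype(np.int64) << i
            theta = tab.theta[idx]
        else:
            theta = np.full(M, float(tab.theta[0]))
        if node in ev:
            cols[node] = np.full(M, ev[node], dtype=np.int8)
            weights *= theta if ev[node] == 1 else 1.0 - theta
        else:
            cols[node] = (gen.random(M) < theta).astype(np.int8)
    samples = pd.DataFrame({n: cols[n] for n in net.nodes})
    return WeightedSampleSet(samples=samples, weights=weights, evidence=ev, seed=seed)


def lw_estimate(samples: WeightedSampleSet, query: Query) -> float:
    """The weighted-indicator estimator, as a pure function of an existing
    sample set (re-runnable on externally supplied samples)."""
    if query.node in samples.evidence:
        raise ValueError(f"query node {query.node!r} is an evidence node")
    if query.node not in samples.samples.columns:
        raise KeyError(f"query node {query.node!r} not a sample column")
    total = float(samples.weights.sum())
    if total <= 0:
        raise ZeroDivisionError("total sample weight is zero")
    match = samples.samples[query.node].to_numpy() == query.state
    return float(samples.weights[match].sum() / total)


def _lw_standard_error(samples: WeightedSampleSet, query: Query, estimate: float) -> float:
    # delta-method variance of the ratio estimator r = sum(w z)/sum(w):
    # var(r) ~= sum_i w_i^2 (z_i - r)^2 / (sum_i w_i)^2
    z = (samples.samples[query.node].to_numpy() == query.state).astype(float)
    w = samples.weights
    total = w.sum()
    return float(np.sqrt(np.sum((w * (z - estimate)) ** 2)) / total)


def query_lw(
    net: Network,
    cpts: CPTSet,
    query: Query,
    evidence: Evidence,
    M: int = 600_000,
    seed: int | None = None,
) -> QueryResult:
    """Estimate Pr(query | evidence) with M likelihood-weighted samples.

    Deterministic given (seed, M). The default M follows the study-scale
    convergence choice; a Monte-Carlo standard error (delta method) is
    reported alongside every estimate.
    """
    ev = _check_evidence(net, evidence)
    if query.node in ev:
        raise ValueError(f"query node {query.node!r} is in the evidence")
    ss = lw_sample_batch(net, cpts, ev, M, np.random.default_rng(seed))
    est = lw_estimate(ss, query)
    se = _lw_standard_error(ss, query, est)
    return QueryResult(
        query=query,
        evidence=ev,
        estimate=est,
        se=se,
        weight_sum=float(ss.weights.sum()),
        M=M,
        seed=seed,
    )


_ENUM_GUARD = 25
_CHUNK_BITS = 18


def exact_query(
    net: Network,
    cpts: CPTSet,
    query: Query,
    evidence: Evidence,
    max_nodes: int = _ENUM_GUARD,
) -> float:
    """Pr(query | evidence) by summing the factored joint over all states.

    The network is first pruned to the ancestral closure of
    query ∪ evidence — nodes outside it are barren and marginalise out of
    the conditional exactly — then the remaining joint is enumerated in
    chunks. Guarded at ``max_nodes`` nodes after pruning.
    """
    ev = _check_evidence(net, evidence)
    if query.node in ev:
        raise ValueError(f"query node {query.node!r} is in the evidence")
    keep = net.ancestors(set(ev) | {query.node})
    sub = net.subnetwork(keep)
    if sub.n_nodes > max_nodes:
        raise ValueError(
            f"network too large to enumerate: {sub.n_nodes} nodes after "
            f"ancestral pruning (guard {max_nodes})"
        )
    nodes = list(sub.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n_states = 1 << len(nodes)
    num = 0.0  # P(query state, evidence)
    den = 0.0  # P(evidence)
    q_pos = pos[query.node]
    for start in range(0, n_states, 1 << _CHUNK_BITS):
        stop = min(start + (1 << _CHUNK_BITS), n_states)
        codes = np.arange(start, stop, dtype=np.int64)
        # clamp evidence: skip states inconsistent with it
        mask = np.ones(len(codes), dtype=bool)
        for node, state in ev.items():
            bit = (codes >> pos[node]) & 1
            mask &= bit == state
        if not mask.any():
            continue
        codes = codes[mask]
        prob = np.ones(len(codes))
        for node in nodes:
            tab = cpts[node]
            idx = np.zeros(len(codes), dtype=np.int64)
            for i, p in enumerate(tab.parents):
                idx |= ((codes >> pos[p]) & 1) << i
            theta = tab.theta[idx]
            x = (codes >> pos[node]) & 1
            prob *= np.where(x == 1, theta, 1.0 - theta)
        den += float(prob.sum())
        qmatch = ((codes >> q_pos) & 1) == query.state
        num += float(prob[qmatch].sum())
    if den <= 0.0:
        raise ZeroDivisionError("evidence has zero probability mass")
    return num / den
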