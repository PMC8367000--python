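"""Shared fixtures: small networks, hand-specified CPTs, and an independent
brute-force enumeration oracle (dict-based, no numpy) used to cross-check
the package's exact and sampling inference paths."""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path

import numpy as np
import pytest

from droughtbn import (
    BetaPrior,
    CPTSet,
    Network,
    drought_network,
    example_network,
)
from droughtbn.estimation import NodeCPT


def make_cpts(net: Network, thetas: dict) -> CPTSet:
    """Build a CPTSet from explicit θ values.

    ``thetas[node]`` is either a float (root) or a dict mapping
    parent-state tuples (in declaration-order of the parents) to θ.
    """
    tables = {}
    for node in net.nodes:
        parents = net.parents(node)
        size = 1 << len(parents)
        theta = np.empty(size)
        spec = thetas[node]
        if isinstance(spec, (int, float)):
            theta[:] = float(spec)
        else:
            for idx in range(size):
                key = tuple((idx >> i) & 1 for i in range(len(parents)))
                theta[idx] = spec[key]
        zeros = np.zeros(size, dtype=np.int64)
        tables[node] = NodeCPT(
            node=node, parents=parents, n=zeros, k=zeros.copy(),
            theta=theta, alpha_post=np.ones(size), beta_post=np.ones(size),
        )
    return CPTSet(tables=tables, prior=BetaPrior())


def brute_force_conditional(net: Network, cpts: CPTSet, query_node: str,
                            query_state: int, evidence: dict) -> float:
    """Naive oracle: materialize every joint state as an explicit table of
    (assignment dict, probability) and condition by direct summation.
    Deliberately independent of the package's enumeration code path."""
    joint = []
    for states in itertools.product((0, 1), repeat=net.n_nodes):
        assign = dict(zip(net.nodes, states))
        p = 1.0
        for node in net.nodes:
            tab = cpts[node]
            theta = tab.theta_for(assign)
            p *= theta if assign[node] == 1 else 1.0 - theta
        joint.append((assign, p))
    den = sum(p for a, p in joint if all(a[n] == s for n, s in evidence.items()))
    num = sum(
        p for a, p in joint
        if all(a[n] == s for n, s in evidence.items()) and a[query_node] == query_state
    )
    return num / den


@pytest.fixture(scope="session")
def example_net() -> Network:
    return example_network()


@pytest.fixture(scope="session")
def drought_net() -> Network:
    return drought_network()


@pytest.fixture(scope="session")
def example_cpts(example_net) -> CPTSet:
    """CPTs for the four-gene example consistent with its sign annotations:
    A up-regulates B (0.9 vs 0.3), down-regulates C; D is driven up by B
    and down by C."""
    return make_cpts(example_net, {
        "A": 0.6,
        "B": {(1,): 0.9, (0,): 0.3},
        "C": {(1,): 0.2, (0,): 0.8},
        "D": {(0, 0): 0.5, (1, 0): 0.9, (0, 1): 0.1, (1, 1): 0.5},
    })


def engineered_network_and_cpts() -> tuple[Network, CPTSet]:
    """Synthetic ground truth with a known best intervention.

    DRV pushes ERD1 up and the other three reporters down (the desired
    pattern), ANT does the exact opposite, NEU is disconnected. Reporter θ
    are linear in the parent states with ±0.4 effects, so the optimal
    single-node moves are DRV=1 and ANT=0, and the pair {DRV=1, ANT=0}
    beats both.
    """
    net = Network(
        nodes=("DRV", "ANT", "NEU", "RD29A", "RD22", "RD20", "ERD1"),
        edges=tuple(
            (p, r) for p in ("DRV", "ANT")
            for r in ("RD29A", "RD22", "RD20", "ERD1")
        ),
        reporters=frozenset({"RD29A", "RD22", "RD20", "ERD1"}),
    )
    up = {(0, 0): 0.5, (1, 0): 0.9, (0, 1): 0.1, (1, 1): 0.5}    # ERD1: DRV up, ANT down
    down = {(0, 0): 0.5, (1, 0): 0.1, (0, 1): 0.9, (1, 1): 0.5}  # others: DRV down, ANT up
    cpts = make_cpts(net, {
        "DRV": 0.5, "ANT": 0.5, "NEU": 0.5,
        "RD29A": down, "RD22": down, "RD20": down, "ERD1": up,
    })
    return net, cpts


@pytest.fixture(scope="session")
def engineered() -> tuple[Network, CPTSet]:
    return engineered_network_and_cpts()


@pytest.fixture(scope="session")
def worked_samples_path() -> Path:
    return Path(str(resources.files("droughtbn").joinpath("data", "example_bn_samples.csv")))
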