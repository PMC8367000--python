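"""Directed acyclic graph for a discrete gene-regulatory Bayesian network.

A :class:`Network` is the structural half of a Bayesian network: named nodes
(genes, transcription factors, kinases), directed parent→child edges, a set
of *reporter* nodes whose states define the analysis objective, and optional
regulation-sign annotations. Signs (activating / inhibiting / unknown) are
documentation only — every probability in this package is learned from data
and no computation reads them.

Networks are defined in a small YAML schema::

    name: my-network
    nodes:
      - {name: MYC2, role: regulator}
      - {name: RD22, role: reporter}
    edges:
      - {parent: MYC2, child: RD22, sign: "+"}

``sign`` is one of ``+`` (activating), ``-`` (inhibiting) or ``?`` (unknown)
and may be omitted (treated as ``?``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

__all__ = [
    "Network",
    "NetworkError",
    "load_network",
    "topological_order",
    "drought_network",
    "REPORTER_TARGET_STATES",
]

#: Desired reporter states of the drought objective: the analysis seeks
#: interventions that activate ERD1 while keeping RD29A, RD22 and RD20
#: inhibited (all four confer drought resistance, but jointly activating
#: them carries yield/sterility costs).
REPORTER_TARGET_STATES: dict[str, int] = {
    "RD29A": 0,
    "RD22": 0,
    "RD20": 0,
    "ERD1": 1,
}

_VALID_SIGNS = {"+", "-", "?"}


class NetworkError(ValueError):
    """Raised when a network definition violates a structural invariant."""


@dataclass(frozen=True)
class Network:
    """A validated DAG with reporter flags and inert sign metadata.

    Parameters
    ----------
    nodes
        Node names in declaration order. Declaration order is the
        tie-breaker for the deterministic topological sort and fixes the
        parent ordering used to index conditional probability tables.
    edges
        ``(parent, child)`` pairs.
    reporters
        Subset of ``nodes`` flagged as reporter genes.
    sign
        Optional map ``(parent, child) -> "+" | "-" | "?"``.
    name
        Free-text label carried through serialization.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    reporters: frozenset[str] = frozenset()
    sign: Mapping[tuple[str, str], str] = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self) -> None:
        _validate(self.nodes, self.edges, self.reporters, self.sign)

    # -- structural queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        """Declaration index of ``node``."""
        return self.nodes.index(node)

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in declaration order (stable CPT indexing)."""
        ps = {p for p, c in self.edges if c == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {c for p, c in self.edges if p == node}
        return tuple(n for n in self.nodes if n in cs)

    def non_reporters(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.reporters)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def ancestors(self, nodes: Iterable[str]) -> frozenset[str]:
        """Ancestral closure of ``nodes`` (the nodes themselves included)."""
        g = self.to_networkx()
        out: set[str] = set()
        for n in nodes:
            if n not in g:
                raise NetworkError(f"unknown node {n!r}")
            out.add(n)
            out |= nx.ancestors(g, n)
        return frozenset(out)

    def subnetwork(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph on ``keep``, preserving declaration order."""
        keep = set(keep)
        missing = keep - set(self.nodes)
        if missing:
            raise NetworkError(f"unknown nodes: {sorted(missing)}")
        nodes = tuple(n for n in self.nodes if n in keep)
        edges = tuple((p, c) for p, c in self.edges if p in keep and c in keep)
        return Network(
            nodes=nodes,
            edges=edges,
            reporters=frozenset(self.reporters & keep),
            sign={e: s for e, s in self.sign.items() if e in set(edges)},
            name=self.name,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": [
                {"name": n, "role": "reporter" if n in self.reporters else "regulator"}
                for n in self.nodes
            ],
            "edges": [
                {"parent": p, "child": c, "sign": self.sign.get((p, c), "?")}
                for p, c in self.edges
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_sif(self, path: str | Path) -> None:
        """Export as SIF (``parent <tab> relation <tab> child``) for graph viewers."""
        rel = {"+": "activates", "-": "inhibits", "?": "regulates"}
        lines = [
            f"{p}\t{rel[self.sign.get((p, c), '?')]}\t{c}" for p, c in self.edges
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _validate(nodes, edges, reporters, sign) -> None:
    if len(set(nodes)) != len(nodes):
        dupes = sorted({n for n in nodes if list(nodes).count(n) > 1})
        raise NetworkError(f"duplicate node name(s): {dupes}")
    declared = set(nodes)
    seen: set[tuple[str, str]] = set()
    for p, c in edges:
        if p == c:
            raise NetworkError(f"self-edge on {p!r}")
        for endpoint in (p, c):
            if endpoint not in declared:
                raise NetworkError(f"edge {p!r}->{c!r} references undeclared node {endpoint!r}")
        if (p, c) in seen:
            raise NetworkError(f"duplicate edge {p!r}->{c!r}")
        seen.add((p, c))
    undeclared_rep = set(reporters) - declared
    if undeclared_rep:
        raise NetworkError(f"reporter(s) not declared as nodes: {sorted(undeclared_rep)}")
    for (p, c), s in sign.items():
        if (p, c) not in seen:
            raise NetworkError(f"sign given for non-edge {p!r}->{c!r}")
        if s not in _VALID_SIGNS:
            raise NetworkError(f"invalid sign {s!r} on edge {p!r}->{c!r}")
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise NetworkError(f"cycle detected: {cycle}")


def load_network(path: str | Path) -> Network:
    """Load and validate a network definition from its YAML file.

    Raises
    ------
    NetworkError
        On any structural violation: cycles, self-edges, duplicate nodes or
        edges, edges touching undeclared nodes, invalid signs or roles.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "nodes" not in raw:
        raise NetworkError(f"{path}: not a network definition (missing 'nodes')")
    nodes: list[str] = []
    reporters: set[str] = set()
    for entry in raw["nodes"]:
        if isinstance(entry, str):
            entry = {"name": entry}
        name = entry["name"]
        role = entry.get("role", "regulator")
        if role not in {"regulator", "reporter"}:
            raise NetworkError(f"node {name!r}: invalid role {role!r}")
        nodes.append(str(name))
        if role == "reporter":
            reporters.add(str(name))
    edges: list[tuple[str, str]] = []
    sign: dict[tuple[str, str], str] = {}
    for entry in raw.get("edges", []):
        p, c = str(entry["parent"]), str(entry["child"])
        edges.append((p, c))
        s = str(entry.get("sign", "?"))
        if s in _VALID_SIGNS:
            sign[(p, c)] = s
        else:
            raise NetworkError(f"invalid sign {s!r} on edge {p!r}->{c!r}")
    return Network(
        nodes=tuple(nodes),
        edges=tuple(edges),
        reporters=frozenset(reporters),
        sign=sign,
        name=str(raw.get("name", "network")),
    )


def topological_order(net: Network) -> list[str]:
    """Deterministic topological order: parents precede children, ties broken
    by node declaration order."""
    pos = {n: i for i, n in enumerate(net.nodes)}
    return list(
        nx.lexicographical_topological_sort(net.to_networkx(), key=lambda n: pos[n])
    )


def _bundled(fname: str) -> Path:
    return Path(str(resources.files("droughtbn").joinpath("data", fname)))


def drought_network() -> Network:
    """The curated Arabidopsis drought-signaling network (32 nodes).

    Reporters are the four drought-responsive genes RD29A, RD20, RD22 and
    ERD1. Upstream layers are the ABA-dependent ABRE/AREB bZIP factors, the
    ABA-independent DREB1/DREB2 cold-and-drought module with its ICE1/MYB15/
    HOS1/SIZ1 regulators, the WRKY18/40/60 triad, the JA–ABA crosstalk pair
    MYC2/MYB2 feeding the NAC cluster (ANAC019, ANAC055, ATAF1), ZFHD1 and
    ANAC072 (RD26), and a MAP-kinase cascade converging on DREB2A.
    """
    return load_network(_bundled("drought_network.yaml"))


def example_network() -> Network:
    """The four-gene teaching network A→B, A→C, B→D, C→D (B, D as readouts)."""
    return load_network(_bundled("example_bn.yaml"))
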