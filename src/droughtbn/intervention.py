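"""Intervention scoring: rank regulators by their effect on the reporters.

An intervention clamps one or more non-reporter nodes as likelihood-
weighting *evidence* (conditioning, not a causal do-operation: incoming
edges are kept) and reads off the conditional reporter probabilities. The
composite score multiplies the probability of every reporter attaining its
desired state,

    Score(E) = Pr(RD29A=0|E) · Pr(RD22=0|E) · Pr(RD20=0|E) · Pr(ERD1=1|E)

for the drought objective (ERD1 active, the other three inhibited). A high
score marks a good intervention target.

All reporter terms for one evidence assignment share a single weighted
sample set: evidence alone determines the sampling distribution, so reusing
the samples across the four queries is exact and removes any ambiguity
about per-term seeding. Sweeps derive one seed per candidate node as
``base_seed + node_index`` so adding a candidate never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .estimation import CPTSet
from .inference import Evidence, Query, lw_estimate, lw_sample_batch, _check_evidence
from .network import Network, REPORTER_TARGET_STATES

__all__ = [
    "InterventionScore",
    "composite_score",
    "single_node_sweep",
    "multi_node_score",
]


@dataclass(frozen=True)
class InterventionScore:
    """An evidence assignment, its per-reporter target-state probabilities,
    and their product."""

    evidence: dict[str, int]
    components: dict[str, float]  # "<reporter>=<state>" -> probability
    score: float
    M: int
    seed: int | None

    def to_row(self) -> dict:
        row: dict = {}
        if len(self.evidence) == 1:
            ((node, state),) = self.evidence.items()
            row.update(node=node, state=state)
        else:
            row["evidence"] = ";".join(f"{n}={s}" for n, s in self.evidence.items())
        for key, p in self.components.items():
            reporter, state = key.split("=")
            row[f"p_{reporter}_{state}"] = p
        row["score"] = self.score
        return row


def _target_states(net: Network, targets: Mapping[str, int] | None) -> dict[str, int]:
    if targets is None:
        targets = {r: REPORTER_TARGET_STATES[r] for r in net.reporters
                   if r in REPORTER_TARGET_STATES}
        missing = net.reporters - set(targets)
        if missing:
            raise ValueError(
                f"no default target state for reporter(s) {sorted(missing)}; "
                "pass targets explicitly"
            )
    else:
        targets = {str(k): int(v) for k, v in targets.items()}
        unknown = set(targets) - set(net.reporters)
        if unknown:
            raise ValueError(f"target(s) {sorted(unknown)} are not reporter nodes")
    if not targets:
        raise ValueError("network declares no reporter nodes to score")
    return dict(targets)


def composite_score(
    net: Network,
    cpts: CPTSet,
    evidence: Evidence,
    M: int = 600_000,
    seed: int | None = None,
    targets: Mapping[str, int] | None = None,
) -> InterventionScore:
    """Score one evidence assignment: product over reporters of the
    probability of each reporter's desired state, estimated from one shared
    likelihood-weighted sample set."""
    ev = _check_evidence(net, evidence)
    if not ev:
        raise ValueError("evidence must be non-empty")
    touched = set(ev) & net.reporters
    if touched:
        raise ValueError(f"evidence may not touch reporter node(s): {sorted(touched)}")
    tgt = _target_states(net, targets)
    ss = lw_sample_batch(net, cpts, ev, M, seed)
    components = {
        f"{reporter}={state}": lw_estimate(ss, Query(reporter, state))
        for reporter, state in tgt.items()
    }
    score = 1.0
    for p in components.values():
        score *= p
    return InterventionScore(evidence=ev, components=components, score=score, M=M, seed=seed)


def multi_node_score(
    net: Network,
    cpts: CPTSet,
    evidence: Evidence,
    M: int = 600_000,
    seed: int | None = None,
    targets: Mapping[str, int] | None = None,
) -> InterventionScore:
    """Score a joint intervention on two or more nodes. The LW weight is the
    product of the evidence factors over all clamped nodes; with a single
    node this reduces exactly to :func:`composite_score`."""
    if hasattr(evidence, "items"):
        ev = dict(evidence)
    else:  # sequence of (node, state) pairs — detect contradictions
        ev = {}
        for node, state in evidence:
            if node in ev and ev[node] != int(state):
                raise ValueError(f"conflicting evidence for {node!r}")
            ev[node] = int(state)
    return composite_score(net, cpts, ev, M=M, seed=seed, targets=targets)


def single_node_sweep(
    net: Network,
    cpts: CPTSet,
    state: int,
    M: int = 600_000,
    seed: int = 0,
    targets: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Clamp every non-reporter node, one at a time, to ``state`` and score
    it; return the table sorted by descending score (rank 1 = best).

    Each candidate uses seed ``seed + declaration_index``, so the table is
    reproducible row-by-row and stable under adding candidates.
    """
    if state not in (0, 1):
        raise ValueError("state must be 0 or 1")
    rows = []
    for node in net.non_reporters():
        sc = composite_score(
            net, cpts, {node: state},
            M=M, seed=seed + net.index(node), targets=targets,
        )
        rows.append(sc.to_row())
    table = pd.DataFrame(rows).sort_values("score", ascending=False, kind="mergesort")
    table["rank"] = range(1, len(table) + 1)
    return table.reset_index(drop=True)
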