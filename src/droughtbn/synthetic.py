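"""Synthetic ground truth: CPT generators, forward sampling, and a
continuous expression emulator.

These generators make every pipeline stage testable without external data:

* :func:`random_cpts` draws ground-truth tables, either fully random
  (``uniform``) or sign-consistent with strong effects (``strong``) so that
  interventions are detectable;
* :func:`forward_sample_dataset` draws binary datasets ancestrally from a
  known model — the parameter-recovery oracle for CPT fitting;
* :func:`continuous_emulation` wraps latent binary states in a two-component
  Gaussian observation model, emulating the shape of an n-lines × N-genes
  expression matrix: gene active → Normal(mu1, sigma), inactive →
  Normal(mu0, sigma). Under this model, min-max scaling followed by
  mean-thresholding is a consistent decoder of the latent states when the
  components are well separated.

All generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import BetaPrior, CPTSet, NodeCPT
from .inference import lw_sample_batch
from .network import Network
from .preprocess import BinaryDataset

__all__ = [
    "EmulationParams",
    "ContinuousEmulation",
    "random_cpts",
    "forward_sample_dataset",
    "continuous_emulation",
]


@dataclass(frozen=True)
class EmulationParams:
    """Observation model for the continuous emulator.

    Defaults mirror the study scale: n = 104 lines, and log-intensity-like
    expression units with the active component six within-component
    standard deviations above the inactive one (mu0 = 6, mu1 = 12,
    sigma = 1), a separation at which mean-thresholding recovers nearly all
    latent states.
    """

    n: int = 104
    mu0: float = 6.0
    mu1: float = 12.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if not self.mu1 > self.mu0:
            raise ValueError("active mean mu1 must exceed inactive mean mu0")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class ContinuousEmulation:
    """A continuous matrix plus the latent binary truth that generated it."""

    expression: pd.DataFrame
    latent: BinaryDataset


def random_cpts(net: Network, seed: int = 0, mode: str = "uniform") -> CPTSet:
    """Draw a ground-truth CPT set for ``net``.

    ``uniform`` draws every θ independently from U(0.05, 0.95). ``strong``
    makes regulation effects large and consistent with the network's sign
    annotations: each parent "votes" for activation when its state agrees
    with its sign (an activating parent that is on, or an inhibiting parent
    that is off; unknown signs count as activating), and θ interpolates
    from 0.1 (all votes against) to 0.9 (all votes for). Root θ are drawn
    from U(0.3, 0.7) in strong mode.
    """
    if mode not in {"uniform", "strong"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    tables: dict[str, NodeCPT] = {}
    for node in net.nodes:
        parents = net.parents(node)
        size = 1 << len(parents)
        if mode == "uniform":
            theta = rng.uniform(0.05, 0.95, size=size)
        elif not parents:
            theta = rng.uniform(0.3, 0.7, size=1)
        else:
            signs = [net.sign.get((p, node), "?") for p in parents]
            theta = np.empty(size)
            for idx in range(size):
                votes = 0
                for i, s in enumerate(signs):
                    on = (idx >> i) & 1
                    votes += on if s in {"+", "?"} else 1 - on
                theta[idx] = 0.1 + 0.8 * votes / len(parents)
        zeros = np.zeros(size, dtype=np.int64)
        tables[node] = NodeCPT(
            node=node, parents=parents,
            n=zeros, k=zeros.copy(),
            theta=theta,
            alpha_post=np.ones(size), beta_post=np.ones(size),
        )
    return CPTSet(
        tables=tables,
        prior=BetaPrior(),
        provenance={"generator": "random_cpts", "mode": mode, "seed": int(seed)},
    )


def forward_sample_dataset(
    net: Network,
    cpts: CPTSet,
    n: int,
    seed: int | np.random.Generator | None = 0,
) -> BinaryDataset:
    """Draw ``n`` independent full-network states by ancestral sampling.

    This is likelihood weighting with empty evidence: every weight is 1 and
    the rows are plain forward samples from the joint distribution.
    """
    ss = lw_sample_batch(net, cpts, {}, n, seed)
    return BinaryDataset(data=ss.samples.astype(np.int8))


def continuous_emulation(
    net: Network, cpts: CPTSet, params: EmulationParams | None = None
) -> ContinuousEmulation:
    """Emit an expression-like continuous matrix driven by latent binary
    activation states of the network.

    One random stream (from ``params.seed``) drives first the ancestral
    draw of the latent states, then the per-cell Gaussian observations.
    """
    params = params or EmulationParams()
    rng = np.random.default_rng(params.seed)
    latent = forward_sample_dataset(net, cpts, params.n, rng)
    states = latent.data.to_numpy(dtype=float)
    means = params.mu0 + states * (params.mu1 - params.mu0)
    values = rng.normal(means, params.sigma)
    expression = pd.DataFrame(values, columns=latent.data.columns)
    return ContinuousEmulation(expression=expression, latent=latent)
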