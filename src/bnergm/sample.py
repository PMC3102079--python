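"""Simulation of networks from a specified ERGM.

A Metropolis-Hastings chain over single dyad toggles: propose a uniformly
random dyad and accept the toggle with probability min(1, exp(+-theta' delta)),
where delta is the change-statistic vector of the dyad.  The chain is the
engine behind goodness-of-fit simulation, representative networks and
synthetic cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import _engine
from .network import InvalidInputError, Network, NodeAttributes
from .stats import ModelSpec

__all__ = ["SamplerConfig", "simulate_networks"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Chain settings.

    ``burn_in`` and ``thin`` are dyad-toggle counts; both default to the
    fitting defaults (10*C(n,2) and C(n,2)).  ``init`` is ``"empty"``, a
    ``("bernoulli", p)`` pair, or an observed :class:`Network` to start from.
    """

    burn_in: Optional[int] = None
    thin: Optional[int] = None
    seed: int = 0
    init: Union[str, tuple, Network] = "empty"

    def resolved(self, n_nodes: int) -> tuple[int, int]:
        nd = n_nodes * (n_nodes - 1) // 2
        burn = self.burn_in if self.burn_in is not None else 10 * nd
        thin = self.thin if self.thin is not None else nd
        if burn < 0 or thin < 0:
            raise InvalidInputError("burn_in and thin must be nonnegative")
        return burn, thin


def _initial_network(config: SamplerConfig, n_nodes: int, rng: np.random.Generator) -> Network:
    init = config.init
    if isinstance(init, Network):
        if init.n_nodes != n_nodes:
            raise InvalidInputError("initial network has wrong node count")
        return init
    if init == "empty":
        return Network(n_nodes, ())
    if isinstance(init, tuple) and len(init) == 2 and init[0] == "bernoulli":
        p = float(init[1])
        iu = np.triu_indices(n_nodes, k=1)
        mask = rng.random(len(iu[0])) < p
        edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
        return Network(n_nodes, edges)
    raise InvalidInputError(f"unknown sampler init {init!r}")


def simulate_networks(
    spec: ModelSpec,
    theta: Sequence[float],
    n_nodes: int,
    count: int,
    config: Optional[SamplerConfig] = None,
    attrs: Optional[NodeAttributes] = None,
) -> list[Network]:
    """Draw ``count`` thinned networks from the ERGM (spec, theta).

    Deterministic under a fixed ``config.seed``.  A warning is logged when
    the draws are nearly empty or nearly complete, the signature of a
    degenerate parameter vector.
    """
    config = config or SamplerConfig()
    theta = np.asarray(theta, dtype=float)
    if count < 1:
        raise InvalidInputError("count must be >= 1")
    if len(theta) != len(spec) or not np.all(np.isfinite(theta)):
        raise InvalidInputError("theta must be finite and match the spec length")
    burn, thin = config.resolved(n_nodes)
    seed = int(config.seed) % (2 ** 31)
    rng = np.random.default_rng(seed)
    net0 = _initial_network(config, n_nodes, rng)
    state = _engine.GraphState.from_network(net0, spec, attrs)
    _, stack = _engine.sample_chain(state, theta, burn, thin, count, seed,
                                    collect_adj=True)
    nets = [Network.from_adjacency(stack[s]) for s in range(count)]
    nd = n_nodes * (n_nodes - 1) // 2
    mean_density = float(np.mean([net.n_edges for net in nets])) / nd
    if mean_density < 0.01 or mean_density > 0.99:
        logger.warning(
            "simulated networks are nearly %s (mean density %.4f); "
            "the parameters may be degenerate",
            "empty" if mean_density < 0.01 else "complete", mean_density,
        )
    return nets
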