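"""Loopy belief propagation for cascade activation probabilities.

Computes directed-edge probabilities p_ij = P(s_i = 1 || s_j = 0) — the
probability that i activates when its neighbor j is held inactive (i.e.
before j could have helped) — and node marginals p_i. The fixed-point
equations treat neighbors as independent:

    p_ij = E[ Rc_i(S) ],  S ~ Poisson-binomial({p_ni : n in nb(i) \\ j})
    p_i  = E[ Rc_i(S) ],  S ~ Poisson-binomial({p_ni : n in nb(i)})

Exact on trees after enough sweeps; on loopy graphs the iteration is the
usual loopy-BP approximation, good on locally tree-like networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._pbinom import poisson_binomial_pmf
from .netgraph import Network
from .responses import ResponseFunction

__all__ = ["EdgeBeliefs", "run_loopy_bp", "mean_cascade_size"]


@dataclass
class EdgeBeliefs:
    """Fixed-point (or best-iterate) beliefs for every directed edge."""

    p_edge: dict[tuple[str, str], float]  # (i, j) -> P(s_i=1 || s_j=0)
    p_node: dict[str, float]
    iterations_run: int
    max_last_delta: float


def _expected_rc(r: ResponseFunction, incoming: np.ndarray) -> float:
    """E[Rc(S)] for S the Poisson-binomial of the incoming probabilities."""
    pmf = poisson_binomial_pmf(incoming)
    return float(pmf @ r.Rc[: len(pmf)])


def run_loopy_bp(
    g: Network,
    responses: Mapping[str, ResponseFunction],
    iters: int = 50,
    init: str = "R0",
    schedule: str = "synchronous",
) -> EdgeBeliefs:
    """Iterate the self-consistent equations for a fixed sweep count.

    ``init="R0"`` starts from the seeding probabilities p_ij = R_i(0);
    ``init="zero"`` from 0. The default synchronous (Jacobi) schedule
    updates every directed edge from the previous sweep's values; the
    asynchronous schedule updates in place in directed-edge order.
    Non-convergence is reported via ``max_last_delta``, never raised.
    """
    for n in g.nodes:
        if responses[n].degree != g.degree(n):
            raise ValueError(f"response degree mismatch at node {n!r}")
    directed = [(i, j) for i in g.nodes for j in g.neighbors(i)]
    if init == "R0":
        p = {(i, j): float(responses[i].R[0]) for i, j in directed}
    elif init == "zero":
        p = {(i, j): 0.0 for i, j in directed}
    else:
        raise ValueError(f"unknown init {init!r}")

    delta = 0.0
    for _ in range(iters):
        delta = 0.0
        source = dict(p) if schedule == "synchronous" else p
        for i, j in directed:
            incoming = np.array(
                [source[(n, i)] for n in g.neighbors(i) if n != j]
            )
            new = _expected_rc(responses[i], incoming)
            delta = max(delta, abs(new - p[(i, j)]))
            p[(i, j)] = new

    p_node = {}
    for i in g.nodes:
        incoming = np.array([p[(n, i)] for n in g.neighbors(i)])
        p_node[i] = _expected_rc(responses[i], incoming)
    return EdgeBeliefs(
        p_edge=p, p_node=p_node, iterations_run=iters, max_last_delta=delta
    )


def mean_cascade_size(b: EdgeBeliefs) -> float:
    """BP estimate of E[rho]: the average of the node marginals."""
    if not b.p_node:
        return 0.0
    return float(np.mean(list(b.p_node.values())))
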