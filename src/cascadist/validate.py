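"""Ground-truth machinery: simulation, exhaustive enumeration, percolation.

The generic simulator uses the integer-threshold coupling: node i draws
k_i in 0..d_i+1 with P(k_i = a) = R_i(a) and activates once at least k_i
neighbors are active (k_i = 0 seeds the cascade, k_i = d_i + 1 never
activates). For monotone cumulative responses this reproduces the
framework's activation law exactly and makes the final state independent
of the update schedule. Synchronous updates reach the fixed point in at
most N steps.

The exhaustive oracle enumerates every threshold assignment with its
product probability — exact on any graph, trees or loopy — and is the
independent reference the message-passing algorithms are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .netgraph import Network
from .responses import ModelConfig, build_response
from .sdp import CascadeSizeDistribution

__all__ = [
    "ThresholdAssignment",
    "EmpiricalDistribution",
    "simulate_cascade",
    "sample_assignment",
    "monte_carlo_distribution",
    "brute_force_distribution",
    "enumeration_marginals",
    "icm_bond_percolation_mc",
    "tv_distance",
]

_CHUNK = 1 << 16


@dataclass
class ThresholdAssignment:
    """Integer thresholds k_i in 0..d_i+1 for every node."""

    k: dict[str, int]


@dataclass
class EmpiricalDistribution:
    """Final-size histogram over t = 0..N from independent replicates."""

    counts: np.ndarray
    reps: int
    seed: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.reps:
            raise ValueError("counts must sum to the number of replicates")

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.reps

    def mean_count(self) -> float:
        return float(np.arange(len(self.counts)) @ self.probs)


def tv_distance(p, q) -> float:
    """Total-variation distance between two probability vectors."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    L = max(len(p), len(q))
    pp, qq = np.zeros(L), np.zeros(L)
    pp[: len(p)] = p
    qq[: len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())


# ---------------------------------------------------------------------------
# cascade dynamics

def _final_states(adj, k: np.ndarray) -> np.ndarray:
    """Fixed point of synchronous threshold dynamics, batched.

    ``adj`` is the (N, N) CSR adjacency, ``k`` an (M, N) threshold matrix;
    returns the (M, N) boolean final-state matrix.
    """
    active = k == 0
    while True:
        counts = active.astype(np.int32) @ adj
        new = active | (counts >= k)
        if np.array_equal(new, active):
            return active
        active = new


def simulate_cascade(g: Network, assign: ThresholdAssignment) -> int:
    """Final active count for one threshold assignment."""
    for n in g.nodes:
        ki = assign.k[n]
        if not 0 <= ki <= g.degree(n) + 1:
            raise ValueError(f"threshold {ki} out of range at node {n!r}")
    k = np.array([[assign.k[n] for n in g.nodes]])
    return int(_final_states(g.adjacency_matrix(), k)[0].sum())


def sample_assignment(
    g: Network, config: ModelConfig, rng: np.random.Generator
) -> ThresholdAssignment:
    k = {}
    for n in g.nodes:
        r = build_response(config, n, g.degree(n))
        k[n] = int(rng.choice(g.degree(n) + 2, p=r.R))
    return ThresholdAssignment(k=k)


def _sample_k_matrix(
    g: Network, config: ModelConfig, reps: int, rng: np.random.Generator
) -> np.ndarray:
    k = np.empty((reps, g.n_nodes), dtype=np.int32)
    for col, n in enumerate(g.nodes):
        r = build_response(config, n, g.degree(n))
        k[:, col] = rng.choice(len(r.R), size=reps, p=r.R)
    return k


def monte_carlo_distribution(
    g: Network, config: ModelConfig, reps: int, seed: int
) -> EmpiricalDistribution:
    """Histogram of final sizes over ``reps`` independent threshold draws."""
    if reps < 1:
        raise ValueError("reps >= 1 required")
    rng = np.random.default_rng(seed)
    adj = g.adjacency_matrix()
    N = g.n_nodes
    counts = np.zeros(N + 1, dtype=np.int64)
    for lo in range(0, reps, _CHUNK):
        m = min(_CHUNK, reps - lo)
        k = _sample_k_matrix(g, config, m, rng)
        sizes = _final_states(adj, k).sum(axis=1)
        counts += np.bincount(sizes, minlength=N + 1)
    return EmpiricalDistribution(counts=counts, reps=reps, seed=seed)


# ---------------------------------------------------------------------------
# exhaustive enumeration

def _enumerate(
    g: Network, config: ModelConfig, clamp_inactive: Iterable[str], limit: int
):
    """Yield (k_chunk, prob_chunk) covering every threshold assignment."""
    clamp = {str(n) for n in clamp_inactive}
    radix, masses, fixed = [], [], []
    for n in g.nodes:
        d = g.degree(n)
        if n in clamp:
            radix.append(1)
            masses.append(np.ones(1))
            fixed.append(d + 1)  # never activates
        else:
            r = build_response(config, n, d)
            radix.append(d + 2)
            masses.append(r.R)
            fixed.append(0)
    total = 1
    for rdx in radix:
        total *= rdx
        if total > limit:
            raise ValueError(
                f"state space exceeds limit ({limit}); use Monte Carlo instead"
            )
    radix_arr = np.array(radix, dtype=np.int64)
    strides = np.ones(len(radix), dtype=np.int64)
    for i in range(len(radix) - 2, -1, -1):
        strides[i] = strides[i + 1] * radix_arr[i + 1]
    for lo in range(0, total, _CHUNK):
        idx = np.arange(lo, min(lo + _CHUNK, total), dtype=np.int64)
        k = ((idx[:, None] // strides[None, :]) % radix_arr[None, :]).astype(
            np.int32
        )
        prob = np.ones(len(idx))
        for col, (mass, rdx, fx) in enumerate(zip(masses, radix, fixed)):
            if rdx == 1:
                k[:, col] = fx
            else:
                prob *= mass[k[:, col]]
        yield k, prob


def brute_force_distribution(
    g: Network, config: ModelConfig, limit: int = 10**7
) -> CascadeSizeDistribution:
    """Exact final-size distribution by enumerating all threshold
    assignments; works on any graph. Errors if the state space
    prod_i (d_i + 2) exceeds ``limit``."""
    adj = g.adjacency_matrix()
    N = g.n_nodes
    probs = np.zeros(N + 1)
    for k, prob in _enumerate(g, config, (), limit):
        sizes = _final_states(adj, k).sum(axis=1)
        np.add.at(probs, sizes, prob)
    return CascadeSizeDistribution(N=N, probs=probs / probs.sum())


def enumeration_marginals(
    g: Network,
    config: ModelConfig,
    clamp_inactive: Iterable[str] = (),
    limit: int = 10**7,
) -> dict[str, float]:
    """Exact activation probability per node, optionally with some nodes
    held inactive (used as the oracle for BP's order-conditioned p_ij)."""
    adj = g.adjacency_matrix()
    marg = np.zeros(g.n_nodes)
    total = 0.0
    for k, prob in _enumerate(g, config, clamp_inactive, limit):
        states = _final_states(adj, k)
        marg += prob @ states
        total += prob.sum()
    marg /= total
    return {n: float(marg[g.index(n)]) for n in g.nodes}


# ---------------------------------------------------------------------------
# bond percolation (independent cascade model)

def icm_bond_percolation_mc(
    g: Network, p: float, reps: int, seed: int
) -> EmpiricalDistribution:
    """Final sizes of the bond-percolation process equivalent to the ICM:
    seed each node with probability p, occupy each edge with probability
    p, activate everything reachable from a seed over occupied edges."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    N, E = g.n_nodes, g.n_edges
    edge_idx = [(g.index(u), g.index(v)) for u, v in g.edges]
    counts = np.zeros(N + 1, dtype=np.int64)
    for lo in range(0, reps, _CHUNK):
        m = min(_CHUNK, reps - lo)
        active = rng.random((m, N)) < p
        occ = rng.random((m, E)) < p
        changed = True
        while changed:
            changed = False
            for e, (iu, iv) in enumerate(edge_idx):
                fwd = active[:, iu] & occ[:, e] & ~active[:, iv]
                bwd = active[:, iv] & occ[:, e] & ~active[:, iu]
                if fwd.any():
                    active[:, iv] |= fwd
                    changed = True
                if bwd.any():
                    active[:, iu] |= bwd
                    changed = True
        counts += np.bincount(active.sum(axis=1), minlength=N + 1)
    return EmpiricalDistribution(counts=counts, reps=reps, seed=seed)
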