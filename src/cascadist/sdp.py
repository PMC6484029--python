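"""Subtree distribution propagation: exact cascade-size distributions on trees.

A single upward (post-order) pass computes, at each node n, the joint
distribution of the active count of the subtree rooted at n together with
an indicator of n's own state. Two tables are propagated per node:

* ``pI`` — subtree count and s_n, given the parent stays inactive;
* ``pA`` — subtree count and the trigger indicator r_n (r_n = 1 means n
  activated before its parent and can trigger it; r_n = 0 subsumes every
  other case compatible with an active parent).

Children tables are combined by 2-D convolution (counts add along t, child
indicators add along a); the node's response function then mixes the
convolved tables into its own message. The root combines all child tables
into the final-size distribution P(T_r = t), t = 0..N.

The exact pass costs O(N^2 log N) in the worst case. With ``resolution=C``
set, message supports are capped at C+1 points by mean-preserving two-point
re-binning onto an equidistant grid of [0, N] — an approximate linear-time
mode, off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .netgraph import RootedTree
from .responses import ResponseFunction

__all__ = [
    "SubtreeMessage",
    "ConvolvedChildren",
    "CascadeSizeDistribution",
    "leaf_message",
    "convolve_children",
    "internal_message",
    "root_distribution",
    "run_sdp",
]

# direct convolution below this t-support; FFT above, with round-off control
FFT_THRESHOLD = 256
_CLIP_TOL = 1e-12
_NORM_TOL = 1e-9


@dataclass
class SubtreeMessage:
    """Message from a node to its parent.

    ``pI``/``pA`` are (T+1, 2) tables over (t, s) and (t, r); ``step`` is
    the node-count width of one t index (1.0 exact; N/C in grid mode).
    """

    node: str
    pI: np.ndarray
    pA: np.ndarray
    step: float = 1.0

    def validate(self) -> None:
        for name, tab in (("pI", self.pI), ("pA", self.pA)):
            if np.any(tab < -_CLIP_TOL):
                raise ValueError(f"{name} at node {self.node!r} has negative mass")
            if abs(tab.sum() - 1.0) > _NORM_TOL:
                raise ValueError(
                    f"{name} at node {self.node!r} does not normalize: "
                    f"sum = {tab.sum()!r}"
                )
        if np.max(np.abs(self.pI[:, 1] - self.pA[:, 1])) > _NORM_TOL:
            raise ValueError(f"pI(t,1) != pA(t,1) at node {self.node!r}")


@dataclass
class ConvolvedChildren:
    """2-D convolution of child messages: (t, a) tables, a = active children."""

    pIstar: np.ndarray
    pAstar: np.ndarray
    step: float = 1.0


@dataclass
class CascadeSizeDistribution:
    """Distribution of the final number of active nodes, t = 0..N.

    In grid mode (``grid = C``) probabilities sit on the equidistant
    fractions k/C of [0, 1] instead of the integers 0..N.
    """

    N: int
    probs: np.ndarray
    grid: int | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, float)
        expected = (self.grid if self.grid is not None else self.N) + 1
        if self.probs.shape != (expected,):
            raise ValueError(
                f"expected {expected} probabilities, got {self.probs.shape}"
            )
        if np.any(self.probs < -1e-10):
            raise ValueError("negative probability mass")
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError(f"distribution sum {self.probs.sum()!r} != 1")

    @property
    def counts(self) -> np.ndarray:
        """Node-count value of each support point (non-integer in grid mode)."""
        if self.grid is None:
            return np.arange(self.N + 1, dtype=float)
        return np.arange(self.grid + 1) * (self.N / self.grid)

    @property
    def rho(self) -> np.ndarray:
        return self.counts / self.N if self.N > 0 else self.counts

    def mean_count(self) -> float:
        return float(self.counts @ self.probs)

    def mean_rho(self) -> float:
        return self.mean_count() / self.N if self.N > 0 else 0.0

    def to_tsv(self) -> str:
        lines = ["t\trho\tprobability"]
        for t, r, p in zip(self.counts, self.rho, self.probs):
            lines.append(f"{t:.17g}\t{r:.17g}\t{p:.17g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, N: int | None = None) -> "CascadeSizeDistribution":
        rows = [
            line.split("\t")
            for line in text.strip().splitlines()[1:]
            if line.strip()
        ]
        t = np.array([float(r[0]) for r in rows])
        p = np.array([float(r[2]) for r in rows])
        n_support = len(t) - 1
        if N is None:
            N = int(round(t[-1]))
        grid = None if n_support == N else n_support
        return cls(N=N, probs=p, grid=grid)


# ---------------------------------------------------------------------------
# elementary operations

def leaf_message(r: ResponseFunction, node: str = "") -> SubtreeMessage:
    """Message of a degree-1 node with no children."""
    if r.degree != 1:
        raise ValueError(f"leaf_message requires degree 1, got {r.degree}")
    pA = np.array([[1.0 - r.Rc[1], 0.0], [r.R[1], r.R[0]]])
    pI = np.array([[1.0 - r.R[0], 0.0], [0.0, r.R[0]]])
    return SubtreeMessage(node=node, pI=pI, pA=pA)


def _conv2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full 2-D convolution; FFT above the t-support threshold."""
    if max(a.shape[0], b.shape[0]) <= FFT_THRESHOLD:
        return signal.convolve(a, b, method="direct")
    out = signal.fftconvolve(a, b)
    neg = out.min()
    if neg < -_CLIP_TOL * max(1.0, a.shape[0] + b.shape[0]):
        raise FloatingPointError(
            f"FFT convolution produced negative mass {neg:.3e}; numerical failure"
        )
    target = a.sum() * b.sum()
    out = np.clip(out, 0.0, None)
    s = out.sum()
    if s > 0:
        out *= target / s
    return out


def _identity_cc(step: float = 1.0) -> ConvolvedChildren:
    one = np.ones((1, 1))
    return ConvolvedChildren(pIstar=one.copy(), pAstar=one.copy(), step=step)


def convolve_children(
    messages: Sequence[SubtreeMessage], step: float = 1.0
) -> ConvolvedChildren:
    """Combine child messages by 2-D convolution, smallest t-support first.

    The combination order only affects round-off and speed, not the result.
    An empty sequence yields the convolution identity (unit mass at (0, 0)),
    used for leaves and single-node trees.
    """
    if not messages:
        return _identity_cc(step)
    msgs = sorted(messages, key=lambda m: m.pI.shape[0])
    step = msgs[0].step
    pI = msgs[0].pI
    pA = msgs[0].pA
    for m in msgs[1:]:
        if m.step != step:
            raise ValueError("cannot convolve messages on different grids")
        pI = _conv2(pI, m.pI)
        pA = _conv2(pA, m.pA)
    return ConvolvedChildren(pIstar=pI, pAstar=pA, step=step)


def _shift_one(vec: np.ndarray, step: float) -> np.ndarray:
    """Shift a t-indexed vector by one node (the focal node's own count)."""
    if step == 1.0:
        out = np.zeros(len(vec) + 1)
        out[1:] = vec
        return out
    # fractional shift by 1/step grid indices, split to preserve the mean
    offset = 1.0 / step
    lo = math.floor(offset)
    frac = offset - lo
    out = np.zeros(len(vec) + lo + (1 if frac > 0 else 0))
    out[lo : lo + len(vec)] += (1.0 - frac) * vec
    if frac > 0:
        out[lo + 1 : lo + 1 + len(vec)] += frac * vec
    return out


def internal_message(
    cc: ConvolvedChildren, r: ResponseFunction, node: str = ""
) -> SubtreeMessage:
    """Message of a non-root node from its convolved child tables.

    With a ranging over active-children counts:
      pA(t,0) = sum_a pIstar(t,a)(1-Rc(a+1)) + sum_a pAstar(t-1,a)R(a+1)
      pA(t,1) = sum_a pAstar(t-1,a)Rc(a)
      pI(t,0) = sum_a pIstar(t,a)(1-Rc(a))
      pI(t,1) = pA(t,1)
    """
    n_a = cc.pIstar.shape[1]  # children + 1
    d = r.degree
    if n_a > d:
        raise ValueError(f"{n_a - 1} children exceed degree {d} minus parent")
    w_not_plus = 1.0 - r.Rc[1 : n_a + 1]  # 1 - Rc(a+1)
    w_trig = r.R[1 : n_a + 1]  # R(a+1)
    w_cum = r.Rc[:n_a]  # Rc(a)
    w_not = 1.0 - r.Rc[:n_a]  # 1 - Rc(a)

    pA0 = cc.pIstar @ w_not_plus
    pA0_shift = _shift_one(cc.pAstar @ w_trig, cc.step)
    pA1 = _shift_one(cc.pAstar @ w_cum, cc.step)
    pI0 = cc.pIstar @ w_not

    T = max(len(pA0), len(pA0_shift), len(pA1), len(pI0))
    pA = np.zeros((T, 2))
    pI = np.zeros((T, 2))
    pA[: len(pA0), 0] += pA0
    pA[: len(pA0_shift), 0] += pA0_shift
    pA[: len(pA1), 1] = pA1
    pI[: len(pI0), 0] = pI0
    pI[:, 1] = pA[:, 1]
    msg = SubtreeMessage(node=node, pI=pI, pA=pA, step=cc.step)
    msg.validate()
    return msg


def root_distribution(
    cc: ConvolvedChildren, r: ResponseFunction, N: int | None = None
) -> CascadeSizeDistribution:
    """Final-size distribution at the root from all-children tables:
    P(T_r = t) = sum_a pIstar(t,a)(1-Rc(a)) + sum_a pAstar(t-1,a)Rc(a).
    """
    n_a = cc.pIstar.shape[1]
    if n_a > r.degree + 1:
        raise ValueError(
            f"{n_a - 1} children exceed root degree {r.degree}"
        )
    w_not = 1.0 - r.Rc[:n_a]
    w_cum = r.Rc[:n_a]
    inactive = cc.pIstar @ w_not
    active = _shift_one(cc.pAstar @ w_cum, cc.step)
    T = max(len(inactive), len(active))
    probs = np.zeros(T)
    probs[: len(inactive)] += inactive
    probs[: len(active)] += active
    if abs(probs.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"root distribution sum {probs.sum()!r} != 1")
    if cc.step == 1.0:
        n_nodes = N if N is not None else T - 1
        out = np.zeros(n_nodes + 1)
        out[: len(probs)] = probs[: n_nodes + 1]
        tail = probs[n_nodes + 1 :].sum()
        if tail > _NORM_TOL:
            raise ValueError(f"mass {tail!r} beyond N = {n_nodes}")
        out[-1] += tail
        return CascadeSizeDistribution(N=n_nodes, probs=out / out.sum())
    # grid mode: indices are multiples of step = N/C node counts
    if N is None:
        raise ValueError("grid mode requires N")
    C = int(round(N / cc.step))
    out = _fold_overflow(probs, C)
    return CascadeSizeDistribution(N=N, probs=out / out.sum(), grid=C)


# ---------------------------------------------------------------------------
# grid re-binning

def _fold_overflow(probs: np.ndarray, C: int) -> np.ndarray:
    """Fold rounding spill beyond index C back into 0..C, mean-preserving.

    Two-point splits can stack a sliver of mass past the last grid point
    even though the true support ends there. Folding it flat into bin C
    would lose first moment, so the lost moment is restored by moving an
    equal-moment sliver of interior mass up to bin C.
    """
    out = np.zeros(C + 1)
    L = min(len(probs), C + 1)
    out[:L] = probs[:L]
    if len(probs) <= C + 1:
        return out
    spill = probs[C + 1 :]
    out[C] += spill.sum()
    deficit = float(np.arange(1, len(spill) + 1) @ spill)  # index-units moment
    for k in range(C - 1, -1, -1):
        if deficit <= 0:
            break
        move = min(out[k], deficit / (C - k))
        out[k] -= move
        out[C] += move
        deficit -= move * (C - k)
    return out


def _rebin_axis0(tab: np.ndarray, old_step: float, new_step: float) -> np.ndarray:
    """Move t-indexed masses onto a coarser grid, mean-preserving.

    Each mass at node count x = i*old_step is split between the two
    nearest multiples of new_step so its expectation is unchanged.
    """
    L = tab.shape[0]
    x = np.arange(L) * (old_step / new_step)
    lo = np.floor(x).astype(int)
    frac = x - lo
    out_len = int(lo[-1]) + 2
    out = np.zeros((out_len,) + tab.shape[1:])
    np.add.at(out, lo, tab * (1.0 - frac).reshape(-1, *([1] * (tab.ndim - 1))))
    np.add.at(out, lo + 1, tab * frac.reshape(-1, *([1] * (tab.ndim - 1))))
    while out.shape[0] > 1 and not np.any(out[-1]):
        out = out[:-1]
    return out


def _maybe_rebin(msg: SubtreeMessage, resolution: int | None, N: int) -> SubtreeMessage:
    if resolution is None:
        return msg
    if msg.pI.shape[0] <= resolution + 1:
        return msg
    new_step = N / resolution
    if msg.step >= new_step:
        return msg
    return SubtreeMessage(
        node=msg.node,
        pI=_rebin_axis0(msg.pI, msg.step, new_step),
        pA=_rebin_axis0(msg.pA, msg.step, new_step),
        step=new_step,
    )


def _align_steps(messages: list[SubtreeMessage]) -> list[SubtreeMessage]:
    target = max(m.step for m in messages)
    out = []
    for m in messages:
        if m.step == target:
            out.append(m)
        else:
            out.append(
                SubtreeMessage(
                    node=m.node,
                    pI=_rebin_axis0(m.pI, m.step, target),
                    pA=_rebin_axis0(m.pA, m.step, target),
                    step=target,
                )
            )
    return out


# ---------------------------------------------------------------------------
# driver

def run_sdp(
    tree: RootedTree,
    responses: Mapping[str, ResponseFunction],
    resolution: int | None = None,
) -> CascadeSizeDistribution:
    """Single post-order pass over ``tree`` computing the final-size
    distribution. ``responses[n].degree`` must equal n's tree degree.

    ``resolution=C`` caps every message support at C+1 points by
    mean-preserving re-binning (approximate); with C >= N no re-binning
    triggers and the result is identical to the exact mode.
    """
    net = tree.network
    N = net.n_nodes
    for n in net.nodes:
        r = responses.get(n)
        if r is None:
            raise ValueError(f"no response function for node {n!r}")
        if r.degree != net.degree(n):
            raise ValueError(
                f"response degree {r.degree} != tree degree {net.degree(n)} "
                f"at node {n!r}"
            )
    messages: dict[str, SubtreeMessage] = {}
    for n in tree.postorder:
        kids = [messages.pop(c) for c in tree.children[n]]
        if kids:
            kids = _align_steps(kids)
        cc = convolve_children(kids)
        if n == tree.root:
            return root_distribution(cc, responses[n], N=N)
        msg = internal_message(cc, responses[n], node=n)
        messages[n] = _maybe_rebin(msg, resolution, N)
    raise AssertionError("postorder did not end at the root")  # pragma: no cover
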