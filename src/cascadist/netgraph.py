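"""Graphs, rooted trees and synthetic network generators.

Networks are undirected simple graphs with opaque string node identifiers.
Node order is first-appearance order and is preserved through I/O round
trips; a dense integer index in that order is available for array work.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "RootedTree",
    "SpanningTreeResult",
    "read_edge_list",
    "write_edge_list",
    "minimum_spanning_tree",
    "root_tree",
    "generate",
    "star",
    "path",
    "uniform_tree",
    "hub_tree",
    "power_law_config_model",
]


class Network:
    """Undirected simple graph: no self-loops, no parallel edges.

    Parameters
    ----------
    edges : iterable of (u, v) pairs
        Node identifiers are converted to ``str``. Duplicate edges are
        dropped with a warning; self-loops raise ``ValueError``.
    nodes : optional iterable
        Extra (possibly isolated) nodes; placed before edge endpoints in
        the node order if listed first.
    """

    def __init__(self, edges: Iterable[tuple] = (), nodes: Iterable = ()):
        self._nodes: list[str] = []
        self._index: dict[str, int] = {}
        self._adj: dict[str, list[str]] = {}
        self._edges: list[tuple[str, str]] = []
        self._edge_set: set[frozenset] = set()
        for n in nodes:
            self._add_node(str(n))
        for u, v in edges:
            self.add_edge(str(u), str(v))

    def _add_node(self, n: str) -> None:
        if n not in self._index:
            self._index[n] = len(self._nodes)
            self._nodes.append(n)
            self._adj[n] = []

    def add_edge(self, u: str, v: str) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop at node {u!r}")
        self._add_node(u)
        self._add_node(v)
        key = frozenset((u, v))
        if key in self._edge_set:
            logger.warning("duplicate edge (%s, %s) ignored", u, v)
            return
        self._edge_set.add(key)
        self._edges.append((u, v))
        self._adj[u].append(v)
        self._adj[v].append(u)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def neighbors(self, n: str) -> list[str]:
        return list(self._adj[n])

    def degree(self, n: str) -> int:
        return len(self._adj[n])

    def index(self, n: str) -> int:
        return self._index[n]

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((str(u), str(v))) in self._edge_set

    def __contains__(self, n) -> bool:
        return str(n) in self._index

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Network N={self.n_nodes} E={self.n_edges}>"

    # -- conversions -----------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        return cls(edges=g.edges(), nodes=g.nodes())

    def adjacency_matrix(self):
        """Sparse CSR adjacency in node-index order."""
        from scipy import sparse

        n = self.n_nodes
        rows, cols = [], []
        for u, v in self._edges:
            iu, iv = self._index[u], self._index[v]
            rows += [iu, iv]
            cols += [iv, iu]
        data = np.ones(len(rows), dtype=np.int32)
        return sparse.csr_array((data, (rows, cols)), shape=(n, n))

    def connected_components(self) -> list[list[str]]:
        """Components as node lists, each in node order; components ordered
        by their first node."""
        seen: set[str] = set()
        comps = []
        for start in self._nodes:
            if start in seen:
                continue
            comp = []
            queue = deque([start])
            seen.add(start)
            while queue:
                u = queue.popleft()
                comp.append(u)
                for v in self._adj[u]:
                    if v not in seen:
                        seen.add(v)
                        queue.append(v)
            comps.append(sorted(comp, key=self._index.__getitem__))
        return comps

    def subgraph(self, nodes: Sequence[str]) -> "Network":
        keep = set(nodes)
        order = [n for n in self._nodes if n in keep]
        edges = [(u, v) for u, v in self._edges if u in keep and v in keep]
        return Network(edges=edges, nodes=order)

    def is_tree(self) -> bool:
        return (
            self.n_edges == self.n_nodes - 1
            and len(self.connected_components()) == 1
        )


@dataclass
class RootedTree:
    """A tree with a chosen root and traversal bookkeeping."""

    network: Network
    root: str
    parent: dict[str, str | None]
    children: dict[str, list[str]]
    postorder: list[str]
    height: int
    subtree_size: dict[str, int]


@dataclass
class SpanningTreeResult:
    """Spanning forest plus, per node, the neighbors it lost.

    ``deleted_neighbors[i]`` (dnb(i)) lists original neighbors of *i* no
    longer adjacent in the forest; ``m[i]`` is its length.
    """

    tree: Network
    deleted_neighbors: dict[str, list[str]]
    m: dict[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.m is None:
            self.m = {n: len(v) for n, v in self.deleted_neighbors.items()}


# ---------------------------------------------------------------------------
# edge-list I/O

def read_edge_list(source) -> Network:
    """Read a two-column whitespace-separated edge list.

    ``source`` is a path, a file object, or a string containing the text.
    Lines starting with ``#`` and blank lines are ignored. Duplicate edges
    are dropped with a warning; a self-loop raises ``ValueError`` naming
    the offending line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or (" " in s and "/" not in s and not s.endswith(".edges")):
            text = s
        else:
            try:
                with open(s) as fh:
                    text = fh.read()
            except OSError:
                text = s
    net = Network()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 2:
            raise ValueError(
                f"expected 2 tokens at line {lineno}, got {len(tokens)}: {stripped!r}"
            )
        u, v = tokens
        if u == v:
            raise ValueError(f"self-loop at line {lineno}: {stripped!r}")
        net.add_edge(u, v)
    return net


def write_edge_list(net: Network, target) -> None:
    """Write the edge list; ``target`` is a path or file object."""
    lines = "".join(f"{u} {v}\n" for u, v in net.edges)
    if hasattr(target, "write"):
        target.write(lines)
    else:
        with open(target, "w") as fh:
            fh.write(lines)


# ---------------------------------------------------------------------------
# spanning trees

def minimum_spanning_tree(
    g: Network, seed: int, weights: Mapping[frozenset, float] | None = None
) -> SpanningTreeResult:
    """Minimum spanning forest under i.i.d. uniform random edge weights.

    Each edge receives a pseudo-random weight from a generator seeded with
    ``seed``, so the chosen forest is a uniform-ish random spanning forest,
    deterministic given the seed. ``weights`` overrides the random weights
    (keys are ``frozenset({u, v})``), e.g. to prefer cutting hub-hub edges.
    """
    rng = np.random.default_rng(seed)
    w = rng.random(g.n_edges)
    gx = nx.Graph()
    gx.add_nodes_from(g.nodes)
    for k, (u, v) in enumerate(g.edges):
        wt = w[k] if weights is None else weights[frozenset((u, v))]
        gx.add_edge(u, v, weight=wt)
    forest_edges = {
        frozenset((u, v))
        for u, v, _ in nx.minimum_spanning_edges(gx, algorithm="kruskal")
    }
    tree = Network(
        edges=[(u, v) for u, v in g.edges if frozenset((u, v)) in forest_edges],
        nodes=g.nodes,
    )
    dnb: dict[str, list[str]] = {n: [] for n in g.nodes}
    for u, v in g.edges:
        if frozenset((u, v)) not in forest_edges:
            dnb[u].append(v)
            dnb[v].append(u)
    return SpanningTreeResult(tree=tree, deleted_neighbors=dnb)


# ---------------------------------------------------------------------------
# rooting

def _bfs_farthest(t: Network, start: str):
    """(farthest node, parents, depth) by BFS; farthest ties broken by node
    order so the result is deterministic."""
    parent = {start: None}
    depth = {start: 0}
    queue = deque([start])
    far, far_d = start, 0
    while queue:
        u = queue.popleft()
        if depth[u] > far_d:
            far, far_d = u, depth[u]
        for v in t.neighbors(u):
            if v not in parent:
                parent[v] = u
                depth[v] = depth[u] + 1
                queue.append(v)
    return far, parent, depth


def _tree_center(t: Network) -> str:
    """Node of minimum eccentricity via the double-BFS diameter trick;
    of the (at most two) centers, the earlier in node order wins."""
    u, _, _ = _bfs_farthest(t, t.nodes[0])
    v, parent, depth = _bfs_farthest(t, u)
    path_uv = [v]
    while parent[path_uv[-1]] is not None:
        path_uv.append(parent[path_uv[-1]])
    diam = len(path_uv) - 1
    mid = path_uv[diam // 2], path_uv[(diam + 1) // 2]
    centers = {mid[0], mid[1]}
    return next(n for n in t.nodes if n in centers)


def root_tree(t: Network, root: str | None = "auto") -> RootedTree:
    """Root a tree, choosing a center when ``root`` is ``"auto"``/None.

    The center (node of minimum eccentricity, ties broken by node order)
    minimizes the maximum path length from the root, which keeps message
    supports balanced. An explicit root is always honored.
    """
    if not t.is_tree():
        raise ValueError("input is not a connected tree")
    if root in (None, "auto"):
        root = _tree_center(t)
    else:
        root = str(root)
        if root not in t:
            raise ValueError(f"root {root!r} not in network")

    parent: dict[str, str | None] = {root: None}
    children: dict[str, list[str]] = {n: [] for n in t.nodes}
    depth = {root: 0}
    order = [root]
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in t.neighbors(u):
            if v not in parent:
                parent[v] = u
                children[u].append(v)
                depth[v] = depth[u] + 1
                order.append(v)
                queue.append(v)
    postorder = order[::-1]
    subtree_size = {n: 1 for n in t.nodes}
    for n in postorder:
        p = parent[n]
        if p is not None:
            subtree_size[p] += subtree_size[n]
    return RootedTree(
        network=t,
        root=root,
        parent=parent,
        children=children,
        postorder=postorder,
        height=max(depth.values()),
        subtree_size=subtree_size,
    )


# ---------------------------------------------------------------------------
# generators

def star(n: int) -> Network:
    """Star on ``n`` nodes: hub ``0`` plus ``n-1`` leaves."""
    if n < 1:
        raise ValueError("n >= 1 required")
    return Network(edges=[(0, k) for k in range(1, n)], nodes=range(n))


def path(n: int) -> Network:
    if n < 1:
        raise ValueError("n >= 1 required")
    return Network(edges=[(k, k + 1) for k in range(n - 1)], nodes=range(n))


def uniform_tree(n: int, seed: int) -> Network:
    """Uniformly random labeled tree via a random Prüfer sequence."""
    if n < 1:
        raise ValueError("n >= 1 required")
    if n == 1:
        return Network(nodes=[0])
    if n == 2:
        return Network(edges=[(0, 1)])
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, n, size=n - 2).tolist()
    g = nx.from_prufer_sequence(seq)
    return Network(edges=sorted(g.edges()), nodes=range(n))


def hub_tree(hub_degrees: Sequence[int], n: int) -> Network:
    """Tree with prescribed hub degrees, hubs joined along a path.

    Each hub gets leaf neighbors until it reaches its requested degree.
    If ``n`` exceeds the minimal construction, surplus nodes are chained
    onto the leaf branches round-robin (leaves become paths), which keeps
    the hub degrees exact while lengthening branches.
    """
    k = len(hub_degrees)
    if k == 0:
        raise ValueError("at least one hub required")
    for i, d in enumerate(hub_degrees):
        internal = (1 if i > 0 else 0) + (1 if i < k - 1 else 0)
        if d < internal:
            raise ValueError(f"hub {i} degree {d} below its path degree {internal}")
    n_leaves = sum(
        d - ((1 if i > 0 else 0) + (1 if i < k - 1 else 0))
        for i, d in enumerate(hub_degrees)
    )
    n_min = k + n_leaves
    if n < n_min:
        raise ValueError(f"need at least {n_min} nodes for these hub degrees")
    hubs = [f"h{i}" for i in range(k)]
    edges = [(hubs[i], hubs[i + 1]) for i in range(k - 1)]
    branches: list[str] = []  # current tip of each branch
    leaf_id = 0
    for i, d in enumerate(hub_degrees):
        internal = (1 if i > 0 else 0) + (1 if i < k - 1 else 0)
        for _ in range(d - internal):
            leaf = f"v{leaf_id}"
            leaf_id += 1
            edges.append((hubs[i], leaf))
            branches.append(leaf)
    surplus = n - n_min
    b = 0
    for _ in range(surplus):
        tip = branches[b % len(branches)]
        new = f"v{leaf_id}"
        leaf_id += 1
        edges.append((tip, new))
        branches[b % len(branches)] = new
        b += 1
    return Network(edges=edges, nodes=hubs)


def truncated_power_law_pmf(gamma: float, d_min: int, d_max: int) -> np.ndarray:
    """pmf over degrees d_min..d_max with p(d) ∝ d^-gamma."""
    d = np.arange(d_min, d_max + 1, dtype=float)
    w = d ** (-gamma)
    return w / w.sum()


def power_law_config_model(
    n: int, gamma: float, d_min: int, d_max: int, seed: int
) -> Network:
    """Configuration-model graph with truncated power-law degrees.

    Degrees are i.i.d. from p(d) ∝ d^-gamma on [d_min, d_max]; an odd
    degree sum is fixed by resampling one uniformly chosen degree; stubs
    are matched uniformly; self-loops are erased and parallel edges
    collapsed (the resulting degree distortion is logged).
    """
    if not (1 <= d_min <= d_max < n):
        raise ValueError("need 1 <= d_min <= d_max < n")
    if gamma <= 1:
        raise ValueError("gamma > 1 required")
    rng = np.random.default_rng(seed)
    pmf = truncated_power_law_pmf(gamma, d_min, d_max)
    support = np.arange(d_min, d_max + 1)
    degrees = rng.choice(support, size=n, p=pmf)
    while degrees.sum() % 2 == 1:
        k = rng.integers(0, n)
        degrees[k] = rng.choice(support, p=pmf)
    stubs = np.repeat(np.arange(n), degrees)
    rng.shuffle(stubs)
    net = Network(nodes=range(n))
    dropped = 0
    for a, b in zip(stubs[0::2], stubs[1::2]):
        u, v = str(a), str(b)
        if a == b or net.has_edge(u, v):
            dropped += 1
            continue
        net.add_edge(u, v)
    if dropped:
        logger.info(
            "config model: dropped %d stub pairs (self-loops/multi-edges); "
            "realized mean degree %.3f vs drawn %.3f",
            dropped,
            2 * net.n_edges / n,
            degrees.mean(),
        )
    return net


_GENERATORS = {
    "star": lambda params, seed: star(int(params["N"])),
    "path": lambda params, seed: path(int(params["N"])),
    "uniform_tree": lambda params, seed: uniform_tree(int(params["N"]), seed),
    "hub_tree": lambda params, seed: hub_tree(
        [int(d) for d in params["hub_degrees"]], int(params["N"])
    ),
    "power_law_config_model": lambda params, seed: power_law_config_model(
        int(params["N"]),
        float(params["gamma"]),
        int(params.get("d_min", 1)),
        int(params["d_max"]),
        seed,
    ),
}


def generate(kind: str, params: Mapping, seed: int = 0) -> Network:
    """Dispatch to a named generator; deterministic given ``seed``."""
    try:
        gen = _GENERATORS[kind]
    except KeyError:
        raise ValueError(
            f"unknown generator {kind!r}; choices: {sorted(_GENERATORS)}"
        ) from None
    return gen(params, seed)
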