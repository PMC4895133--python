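"""Simple undirected graphs with connectome-style edge-list I/O.

Voxel-level connectome files store each undirected edge once (one triangle of
the adjacency matrix), as two whitespace-separated node labels per line.  The
reader symmetrizes, collapses duplicates and (by default) drops self-loops.
Internally nodes are contiguous 0-based indices over an :class:`igraph.Graph`
backend, with the original labels kept in a side table; all reports use the
original labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import igraph as ig
import numpy as np

logger = logging.getLogger("connectopo")

__all__ = [
    "Graph",
    "DegreeHistogram",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "degree_histogram",
    "remove_random_edges",
]


class EdgeListParseError(ValueError):
    """Malformed edge-list line (reported with its 1-based line number)."""


@dataclass
class Graph:
    """Simple undirected graph: an igraph backend plus original node labels.

    Invariants: no self-loops, no multi-edges; adjacency is symmetric;
    ``n_edges`` counts each undirected edge once.
    """

    _ig: ig.Graph
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(range(self._ig.vcount()))
        if len(self.labels) != self._ig.vcount():
            raise ValueError("label count does not match node count")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]],
                   labels: Sequence | None = None) -> "Graph":
        """Build from 0-based index pairs; duplicates/reverses collapse."""
        g = ig.Graph(n=n, edges=list(edges), directed=False)
        g.simplify(multiple=True, loops=True)
        return cls(g, list(labels) if labels is not None else list(range(n)))

    @classmethod
    def from_igraph(cls, g: ig.Graph, labels: Sequence | None = None) -> "Graph":
        g = g.copy()
        g.to_undirected()
        g.simplify(multiple=True, loops=True)
        return cls(g, list(labels) if labels is not None else None)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._ig.vcount()

    @property
    def n_edges(self) -> int:
        return self._ig.ecount()

    @property
    def mean_degree(self) -> float:
        if self.n_nodes == 0:
            raise ValueError("empty graph has no mean degree")
        return 2.0 * self.n_edges / self.n_nodes

    def degrees(self) -> np.ndarray:
        return np.asarray(self._ig.degree(), dtype=np.int64)

    def neighbors(self, i: int) -> list[int]:
        return self._ig.neighbors(i)

    def edges(self) -> list[tuple[int, int]]:
        """Each undirected edge once, as sorted index pairs."""
        return [tuple(sorted(e.tuple)) for e in self._ig.es]

    def adjacency_sets(self) -> list[set[int]]:
        return [set(self._ig.neighbors(i)) for i in range(self.n_nodes)]

    def to_igraph(self) -> ig.Graph:
        return self._ig

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and self._ig.is_connected()

    def check_invariants(self) -> None:
        """Raise if the simple/symmetric/edge-count invariants are violated."""
        if not self._ig.is_simple():
            raise AssertionError("graph has self-loops or multi-edges")
        if int(sum(self._ig.degree())) != 2 * self.n_edges:
            raise AssertionError("degree sum != 2 * n_edges")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class DegreeHistogram:
    """Degree counts ``n_k`` with the Shannon entropy of the frequencies.

    ``H = -sum_k (n_k/N) ln(n_k/N)`` in nats; the saturated (fully empirical)
    degree model attains log-likelihood exactly ``-N*H``.
    """

    counts: dict[int, int]
    N: int
    k_min: int
    k_max: int
    H: float

    @classmethod
    def from_degrees(cls, degrees: Sequence[int] | np.ndarray) -> "DegreeHistogram":
        degrees = np.asarray(degrees, dtype=np.int64)
        if degrees.size == 0:
            raise ValueError("no degrees to histogram")
        ks, ns = np.unique(degrees, return_counts=True)
        N = int(degrees.size)
        p = ns / N
        H = float(-(p * np.log(p)).sum())
        return cls(counts={int(k): int(n) for k, n in zip(ks, ns)},
                   N=N, k_min=int(ks[0]), k_max=int(ks[-1]), H=H)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ks = np.fromiter(self.counts.keys(), dtype=np.int64)
        ns = np.fromiter(self.counts.values(), dtype=np.int64)
        order = np.argsort(ks)
        return ks[order], ns[order]

    def to_tsv(self, path) -> None:
        ks, ns = self.arrays()
        with open(path, "w") as fh:
            fh.write("degree\tcount\n")
            for k, n in zip(ks, ns):
                fh.write(f"{k}\t{n}\n")

    @classmethod
    def from_tsv(cls, path) -> "DegreeHistogram":
        ks: list[int] = []
        ns: list[int] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("degree"):
                    continue
                k, n = line.split()
                ks.append(int(k))
                ns.append(int(n))
        degrees = np.repeat(ks, ns)
        return cls.from_degrees(degrees)


# ---------------------------------------------------------------------------
# Edge-list I/O


def read_edge_list(path, symmetrize: bool = True,
                   drop_self_loops: bool = True) -> Graph:
    """Read a whitespace-separated edge list into a simple undirected Graph.

    Each non-comment line holds two node labels.  Files that store only one
    direction of each edge (upper triangle) are handled by ``symmetrize``:
    the pair (u, v), its reverse and any duplicates all collapse to the
    single undirected edge {u, v}.  Self-loops are dropped (and counted in
    the log) when ``drop_self_loops`` is on, otherwise they raise.
    """
    label_index: dict = {}
    labels: list = []
    edges: list[tuple[int, int]] = []
    n_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two tokens, got {len(tokens)}")
            u_lab, v_lab = tokens
            if u_lab == v_lab:
                if drop_self_loops:
                    n_loops += 1
                    # still register the node
                    if u_lab not in label_index:
                        label_index[u_lab] = len(labels)
                        labels.append(u_lab)
                    continue
                raise ValueError(f"{path}:{lineno}: self-loop on node {u_lab}")
            for lab in (u_lab, v_lab):
                if lab not in label_index:
                    label_index[lab] = len(labels)
                    labels.append(lab)
            edges.append((label_index[u_lab], label_index[v_lab]))
    if n_loops:
        logger.info("read_edge_list: dropped %d self-loop line(s) from %s",
                    n_loops, path)
    if not symmetrize:
        # without symmetrization the stored direction is still the only
        # information we have; the graph is undirected either way, but
        # duplicate detection is skipped (kept for dialect compatibility).
        g = ig.Graph(n=len(labels), edges=edges, directed=False)
        g.simplify(multiple=True, loops=True)
        return Graph(g, labels)
    return Graph.from_edges(len(labels), edges, labels)


def write_edge_list(g: Graph, path) -> None:
    """Write each undirected edge once, smaller label first, sorted."""
    lines = []
    for i, j in g.edges():
        a, b = str(g.labels[i]), str(g.labels[j])
        if b < a:
            a, b = b, a
        lines.append((a, b))
    lines.sort()
    with open(path, "w") as fh:
        fh.write(f"# nodes={g.n_nodes} edges={g.n_edges}\n")
        for a, b in lines:
            fh.write(f"{a} {b}\n")


def read_graphml(path) -> Graph:
    """GraphML import; every edge element is treated as undirected."""
    g = ig.Graph.Read_GraphML(str(path))
    labels = g.vs["id"] if "id" in g.vs.attributes() else None
    g.to_undirected()
    g.simplify(multiple=True, loops=True)
    return Graph(g, list(labels) if labels is not None else None)


# ---------------------------------------------------------------------------
# Components, histograms, perturbations


def largest_connected_component(g: Graph) -> Graph:
    """Induced subgraph on the largest component.

    Ties on size are broken toward the component containing the smallest
    minimum original node label (string order for string labels), so the
    result is deterministic.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph has no components")
    comps = g.to_igraph().connected_components()
    sizes = [len(c) for c in comps]
    best = None
    best_key = None
    for c, size in zip(comps, sizes):
        key = (-size, min(str(g.labels[i]) for i in c))
        if best_key is None or key < best_key:
            best_key = key
            best = c
    sub = g.to_igraph().induced_subgraph(best)
    return Graph(sub, [g.labels[i] for i in best])


def degree_histogram(g: Graph) -> DegreeHistogram:
    if g.n_nodes == 0:
        raise ValueError("empty graph has no degree histogram")
    return DegreeHistogram.from_degrees(g.degrees())


def remove_random_edges(g: Graph, fraction: float, mode: str = "undirected",
                        seed: int | None = None) -> Graph:
    """Random edge-removal perturbation.

    ``undirected`` removes exactly ``round(fraction * n_edges)`` undirected
    edges uniformly without replacement.  ``directed_views`` treats each
    undirected edge as two directed arcs, removes arcs independently with
    probability ``fraction``, and keeps the undirected edge if at least one
    arc survives (the graph is then re-symmetrized), matching a pipeline
    that perturbs one stored triangle of the adjacency matrix but measures
    undirected invariants afterwards.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    m = g.n_edges
    edges = g.edges()
    if mode == "undirected":
        n_remove = int(round(fraction * m))
        removed = set(map(int, rng.choice(m, size=n_remove, replace=False)))
        kept = [e for i, e in enumerate(edges) if i not in removed]
    elif mode == "directed_views":
        # an undirected edge dies only if both of its arcs are removed
        both_dead = rng.random((m, 2)) < fraction
        kept = [e for e, dead in zip(edges, both_dead.all(axis=1)) if not dead]
    else:
        raise ValueError(f"unknown removal mode: {mode!r}")
    return Graph.from_edges(g.n_nodes, kept, g.labels)
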