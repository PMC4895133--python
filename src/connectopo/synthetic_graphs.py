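"""Synthetic graphs emulating the statistical structure of voxel connectomes.

Provides every input the analysis stages need without downloading data:
degree sequences drawn from the six hybrid tail families, configuration-model
graphs realizing a prescribed degree sequence, spatially embedded graphs of
known low dimension (periodic lattices, 3D random geometric graphs), and
Erdős–Rényi graphs as nulls.  All randomness flows from a single seeded
generator per call.
"""

from __future__ import annotations

import igraph as ig
import numpy as np
from scipy.spatial import cKDTree

from .degree_models import DegreeModelSpec, build_pmf
from .graph_core import Graph

__all__ = [
    "sample_degree_sequence",
    "configuration_graph",
    "lattice_graph",
    "random_geometric_graph",
    "radius_for_mean_degree",
    "erdos_renyi_graph",
]


def sample_degree_sequence(spec: DegreeModelSpec, n: int,
                           seed: int | None = None) -> np.ndarray:
    """``n`` i.i.d. degrees from the hybrid pmf (inverse-CDF sampling).

    The discrete support is truncated where the remaining mass drops below
    the pmf builder's tolerance (or at ``spec.support_max``), and the
    truncated vector is renormalized for sampling.
    """
    if n < 1:
        raise ValueError("n must be positive")
    pmf = build_pmf(spec)
    total = pmf.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate pmf (non-summable tail?)")
    cdf = np.cumsum(pmf / total)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right").astype(np.int64) + 1


def configuration_graph(degrees, seed: int | None = None,
                        simplify: bool = True) -> Graph:
    """Uniform stub matching for a prescribed degree sequence.

    With ``simplify`` on, self-loops and multi-edges produced by the
    matching are discarded, so realized degrees fall slightly below the
    targets (expected loss is O(1/N) per node for bounded degrees).
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    if degrees.size == 0 or degrees.min() < 1:
        raise ValueError("degrees must be positive")
    if degrees.sum() % 2 != 0:
        raise ValueError("degree sum must be even")
    rng = np.random.default_rng(seed)
    stubs = np.repeat(np.arange(degrees.size), degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    if simplify:
        keep = pairs[:, 0] != pairs[:, 1]
        pairs = pairs[keep]
    elif np.any(pairs[:, 0] == pairs[:, 1]):
        raise ValueError("stub matching produced self-loops; "
                         "pass simplify=True to discard them")
    return Graph.from_edges(int(degrees.size),
                            [(int(a), int(b)) for a, b in pairs])


def lattice_graph(side: int, dims: int = 3, periodic: bool = True) -> Graph:
    """Nearest-neighbor hypercubic lattice with ``side**dims`` nodes."""
    if side < 2:
        raise ValueError("side must be at least 2")
    if dims not in (1, 2, 3):
        raise ValueError("dims must be 1, 2 or 3")
    g = ig.Graph.Lattice([side] * dims, circular=periodic)
    g.simplify(multiple=True, loops=True)
    return Graph(g)


def random_geometric_graph(n: int, radius: float, periodic: bool = True,
                           seed: int | None = None) -> Graph:
    """3D random geometric graph on the unit cube.

    ``n`` uniform points; pairs within Euclidean distance ``radius`` are
    linked.  Periodic boundaries (the default) suppress surface effects, so
    the dense-limit Watts–Strogatz clustering 15/32 is approached without
    boundary corrections.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    if periodic:
        if radius >= 0.5:
            raise ValueError("periodic boundaries require radius < 0.5")
        tree = cKDTree(pts, boxsize=1.0)
    else:
        tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    return Graph.from_edges(n, [(int(a), int(b)) for a, b in pairs])


def radius_for_mean_degree(n: int, mean_k: float) -> float:
    """Radius giving expected degree ``mean_k`` in a periodic 3D RGG:
    ``<k> = n * (4/3) pi r^3``."""
    return float((3.0 * mean_k / (4.0 * np.pi * n)) ** (1.0 / 3.0))


def erdos_renyi_graph(n: int, m: int, seed: int | None = None) -> Graph:
    """G(n, m): exactly ``m`` distinct undirected edges, uniform."""
    max_m = n * (n - 1) // 2
    if m > max_m:
        raise ValueError(f"m={m} exceeds the {max_m} possible edges")
    if m < 0:
        raise ValueError("m must be nonnegative")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    # rejection sampling of unordered pairs; each distinct pair is uniform
    while len(chosen) < m:
        need = m - len(chosen)
        us = rng.integers(0, n, size=2 * need + 8)
        vs = rng.integers(0, n, size=2 * need + 8)
        for u, v in zip(us, vs):
            if u == v:
                continue
            e = (int(u), int(v)) if u < v else (int(v), int(u))
            if e not in chosen:
                chosen.add(e)
                if len(chosen) == m:
                    break
    return Graph.from_edges(n, sorted(chosen))
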