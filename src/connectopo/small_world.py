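"""Small-world coefficients against an Erdős–Rényi null.

The small-world coefficient of Humphries and Gurney,

    sigma = (C / C_r) / (L / L_r),

compares a graph's clustering C and average shortest path length L with the
expectation for an ER random graph of the same size and density:
``C_r = <k>/N`` and ``L_r = (ln N - gamma_E)/ln<k> + 1/2`` with gamma_E the
Euler–Mascheroni constant.  Both common clustering definitions are
reported: the Watts–Strogatz node average C^W (which weights low-degree
nodes heavily) and the global transitivity C^Delta = 3*triangles/triples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_core import Graph

__all__ = [
    "SmallWorldReport",
    "clustering_watts_strogatz",
    "clustering_global",
    "average_path_length",
    "er_null_values",
    "small_world_sigma",
    "small_world_report",
]

EULER_MASCHERONI = float(np.euler_gamma)

#: above this many nodes, L is estimated from a uniform source sample
EXACT_L_LIMIT = 20_000
DEFAULT_L_SOURCES = 1000
_CHUNK = 64


def clustering_watts_strogatz(g: Graph) -> float:
    """Node-averaged clustering; degree < 2 nodes contribute 0.

    ``C^W = (1/N) sum_i 2 n_i / (k_i (k_i - 1))`` where ``n_i`` counts edges
    among the neighbors of i.  All N nodes enter the average.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    local = g.to_igraph().transitivity_local_undirected(mode="zero")
    return float(np.mean(local))


def clustering_global(g: Graph) -> float:
    """Global transitivity: 3 * triangles / connected triples."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    c = g.to_igraph().transitivity_undirected(mode="nan")
    if math.isnan(c):
        raise ValueError("graph has no connected triples")
    return float(c)


def average_path_length(g: Graph, mode: str = "exact",
                        n_sources: int = DEFAULT_L_SOURCES,
                        seed: int | None = None) -> tuple[float, float | None]:
    """Mean graph distance over unordered node pairs.

    ``exact`` runs BFS from every node.  ``sampled`` averages distances from
    a uniform source sample to all other nodes and reports the standard
    error of the per-source means.  Requires a connected graph.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not g.is_connected():
        raise ValueError("L is undefined on disconnected graphs")
    igg = g.to_igraph()
    if mode == "exact":
        return float(igg.average_path_length(directed=False, unconn=False)), None
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    k = min(int(n_sources), n)
    sources = rng.choice(n, size=k, replace=False)
    means = np.empty(k)
    for lo in range(0, k, _CHUNK):
        chunk = [int(i) for i in sources[lo:lo + _CHUNK]]
        d = np.asarray(igg.distances(source=chunk), dtype=float)
        means[lo:lo + len(chunk)] = d.sum(axis=1) / (n - 1)
    L = float(means.mean())
    se = float(means.std(ddof=1) / math.sqrt(k)) if k > 1 else None
    return L, se


def er_null_values(N_l: int, mean_k: float) -> tuple[float, float]:
    """ER-null clustering and path length for a graph of ``N_l`` nodes and
    mean degree ``<k>``: ``C_r = <k>/N_l`` and
    ``L_r = (ln N_l - gamma_E)/ln<k> + 1/2``."""
    if N_l < 2:
        raise ValueError("need at least 2 nodes")
    if mean_k <= 1:
        raise ValueError("ER path-length formula requires <k> > 1")
    C_r = mean_k / N_l
    L_r = (math.log(N_l) - EULER_MASCHERONI) / math.log(mean_k) + 0.5
    return C_r, L_r


def small_world_sigma(C: float, C_r: float, L: float, L_r: float) -> float:
    """sigma = (C/C_r) / (L/L_r); all inputs must be positive."""
    for name, v in (("C", C), ("C_r", C_r), ("L", L), ("L_r", L_r)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (C / C_r) / (L / L_r)


@dataclass
class SmallWorldReport:
    """All small-world quantities for one connected graph."""

    N: int
    n_edges: int
    mean_k: float
    L: float
    L_r: float
    C_W: float
    C_D: float
    C_r: float
    sigma_W: float
    sigma_D: float
    L_mode: str
    L_stderr: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("N", "n_edges", "mean_k", "L", "L_r", "C_W", "C_D", "C_r",
                 "sigma_W", "sigma_D", "L_mode", "L_stderr")}

    TSV_COLUMNS = ("N", "n_edges", "mean_k", "L", "L_r", "C_W", "C_D",
                   "C_r", "sigma_W", "sigma_D")

    def to_tsv_row(self) -> str:
        return "\t".join(f"{getattr(self, c):.6g}" for c in self.TSV_COLUMNS)


def small_world_report(g: Graph, L_mode: str = "auto",
                       n_sources: int = DEFAULT_L_SOURCES,
                       seed: int | None = None) -> SmallWorldReport:
    """Assemble clustering, path length, ER nulls and sigma for one graph.

    ``L_mode="auto"`` computes L exactly up to ``EXACT_L_LIMIT`` nodes and
    samples sources above.  Null values use the graph's own N and mean
    degree.  Triangle-free graphs get sigma = 0 (zero clustering).
    """
    if not g.is_connected():
        raise ValueError("run on the largest connected component")
    n = g.n_nodes
    mean_k = g.mean_degree
    if L_mode == "auto":
        L_mode = "exact" if n <= EXACT_L_LIMIT else "sampled"
    L, L_se = average_path_length(g, mode=L_mode, n_sources=n_sources,
                                  seed=seed)
    C_W = clustering_watts_strogatz(g)
    try:
        C_D = clustering_global(g)
    except ValueError:
        C_D = 0.0
    C_r, L_r = er_null_values(n, mean_k)
    sigma_W = small_world_sigma(C_W, C_r, L, L_r) if C_W > 0 else 0.0
    sigma_D = small_world_sigma(C_D, C_r, L, L_r) if C_D > 0 else 0.0
    return SmallWorldReport(N=n, n_edges=g.n_edges, mean_k=mean_k, L=L,
                            L_r=L_r, C_W=C_W, C_D=C_D, C_r=C_r,
                            sigma_W=sigma_W, sigma_D=sigma_D,
                            L_mode=L_mode, L_stderr=L_se)
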