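"""Graph-theoretic summary statistics of a connection matrix.

Conventions follow the common binary directed definitions: the
characteristic path length is the mean shortest-path distance over
ordered reachable pairs, global efficiency the mean inverse distance
over all ordered pairs (1/inf = 0), clustering the directed
transitivity (an undirected-projection variant is also reported),
modularity the mean +/- sd over repeated stochastic Louvain runs, and
small-worldness sigma = (C/C_null)/(L/L_null) against an ensemble of
degree-preserving edge-swap randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity

from .connectome import ConnectionMatrix


@dataclass(frozen=True)
class MetricReport:
    characteristic_path_length: float
    global_efficiency: float
    clustering_coefficient: float
    clustering_coefficient_undirected: float
    modularity_mean: float
    modularity_sd: float
    small_worldness_mean: float
    small_worldness_sd: float
    null_ensemble_size: int
    modularity_runs: int
    seed: int

    def as_dict(self) -> dict[str, float]:
        return {
            "characteristic_path_length": self.characteristic_path_length,
            "global_efficiency": self.global_efficiency,
            "clustering_coefficient": self.clustering_coefficient,
            "clustering_coefficient_undirected": self.clustering_coefficient_undirected,
            "modularity_mean": self.modularity_mean,
            "modularity_sd": self.modularity_sd,
            "small_worldness_mean": self.small_worldness_mean,
            "small_worldness_sd": self.small_worldness_sd,
        }


def _digraph(C: ConnectionMatrix) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(range(C.n))
    rows, cols = np.nonzero(C.A)
    G.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return G


def path_length_and_efficiency(G: nx.DiGraph) -> tuple[float, float]:
    """Mean distance over reachable ordered pairs, and mean inverse
    distance over all ordered pairs."""
    n = G.number_of_nodes()
    total_d = 0
    reachable_pairs = 0
    total_inv = 0.0
    for src, dists in nx.all_pairs_shortest_path_length(G):
        for dst, d in dists.items():
            if dst == src:
                continue
            total_d += d
            reachable_pairs += 1
            total_inv += 1.0 / d
    if reachable_pairs == 0:
        raise ValueError("graph has no finite directed path")
    L = total_d / reachable_pairs
    E = total_inv / (n * (n - 1))
    return L, E


def directed_clustering(G: nx.DiGraph) -> float:
    return float(nx.average_clustering(G))


def undirected_clustering(G: nx.DiGraph) -> float:
    return float(nx.average_clustering(G.to_undirected(as_view=False)))


def rewire_null(C: ConnectionMatrix, n_swaps: int, seed: int) -> ConnectionMatrix:
    """Degree-preserving randomization by directed edge swaps.

    In- and out-degree sequences are preserved exactly.  Graphs too
    small to swap are returned unchanged with a warning.
    """
    import warnings

    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    G = _digraph(C)
    if G.number_of_nodes() < 4 or G.number_of_edges() < 4:
        warnings.warn("graph too small for degree-preserving swaps; returning input")
        return C
    try:
        nx.directed_edge_swap(G, nswap=n_swaps, max_tries=max(100, 100 * n_swaps), seed=seed)
    except nx.NetworkXAlgorithmError:
        warnings.warn("edge swapping stalled before reaching the requested swap count")
    A = np.zeros_like(C.A)
    for u, v in G.edges:
        A[u, v] = 1
    return ConnectionMatrix(names=list(C.names), classes=list(C.classes), A=A, weighted=False)


def compute_metrics(
    C: ConnectionMatrix,
    modularity_runs: int = 100,
    null_ensemble: int = 100,
    null_swap_factor: int = 10,
    seed: int = 0,
) -> MetricReport:
    """Full metric report with stochastic parts under one seed."""
    if not np.any(C.A):
        raise ValueError("connection matrix has no edges")
    G = _digraph(C)
    L, E = path_length_and_efficiency(G)
    Cdir = directed_clustering(G)
    Cund = undirected_clustering(G)

    rng = np.random.default_rng(seed)
    mods = []
    for _ in range(modularity_runs):
        parts = louvain_communities(G, seed=int(rng.integers(2**31 - 1)))
        mods.append(modularity(G, parts))
    mod_mean = float(np.mean(mods))
    mod_sd = float(np.std(mods, ddof=1)) if len(mods) > 1 else 0.0

    n_swaps = max(1, null_swap_factor * G.number_of_edges())
    sigmas = []
    for _ in range(null_ensemble):
        null = rewire_null(C, n_swaps, seed=int(rng.integers(2**31 - 1)))
        Gn = _digraph(null)
        try:
            Ln, _ = path_length_and_efficiency(Gn)
        except ValueError:
            continue
        Cn = directed_clustering(Gn)
        if Cn > 0 and Ln > 0:
            sigmas.append((Cdir / Cn) / (L / Ln))
    sw_mean = float(np.mean(sigmas)) if sigmas else float("nan")
    sw_sd = float(np.std(sigmas, ddof=1)) if len(sigmas) > 1 else 0.0

    return MetricReport(
        characteristic_path_length=L,
        global_efficiency=E,
        clustering_coefficient=Cdir,
        clustering_coefficient_undirected=Cund,
        modularity_mean=mod_mean,
        modularity_sd=mod_sd,
        small_worldness_mean=sw_mean,
        small_worldness_sd=sw_sd,
        null_ensemble_size=null_ensemble,
        modularity_runs=modularity_runs,
        seed=seed,
    )
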