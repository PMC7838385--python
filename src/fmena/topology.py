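"""Topological indices, fast-greedy modules, and random-network nulls.

All indices treat the network as unweighted and unsigned.  Harmonic
geodesic distance (HD) is the harmonic mean of shortest-path lengths
over all node pairs, with disconnected pairs contributing reciprocal 0,
so sparse disconnected networks still get a finite value.  Nulls are
degree-preserving (repeated double-edge swaps, the molecular-ecological-
network convention) or size-and-links-preserving uniform random graphs;
an index's departure from its null ensemble is summarized by a Z test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy.stats import norm

from .rmt import GeneNetwork, powerlaw_r2


@dataclass
class ModulePartition:
    node_to_module: dict[str, int]
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.node_to_module.values()))

    def members(self, module: int) -> list[str]:
        return [n for n, m in self.node_to_module.items() if m == module]

    def modules_by_size(self) -> list[int]:
        """Module ids sorted by descending member count (stable)."""
        sizes = pd.Series(list(self.node_to_module.values())).value_counts()
        return [int(m) for m in sizes.index]


def fast_greedy_modules(network: GeneNetwork | nx.Graph) -> ModulePartition:
    """Clauset-Newman-Moore greedy modularity maximization.

    Edgeless graphs get one singleton module per node with Q = 0.
    """
    g = network.graph if isinstance(network, GeneNetwork) else network
    if g.number_of_edges() == 0:
        return ModulePartition({n: i + 1 for i, n in enumerate(sorted(g.nodes))}, 0.0)
    communities = nx_community.greedy_modularity_communities(g, weight=None)
    node_to_module = {}
    for m, nodes in enumerate(communities, start=1):
        for n in nodes:
            node_to_module[n] = m
    q = nx_community.modularity(g, communities, weight=None)
    return ModulePartition(node_to_module, float(q))


def modularity_of_partition(g: nx.Graph, node_to_module: dict[str, int]) -> float:
    """Newman-Girvan Q = sum_m (e_mm - a_m^2), from first principles."""
    L = g.number_of_edges()
    if L == 0:
        return 0.0
    modules = set(node_to_module.values())
    q = 0.0
    for m in modules:
        members = {n for n, mm in node_to_module.items() if mm == m}
        e_mm = sum(1 for u, v in g.edges if u in members and v in members) / L
        deg_sum = sum(d for n, d in g.degree if n in members)
        a_m = deg_sum / (2 * L)
        q += e_mm - a_m**2
    return q


def harmonic_geodesic_distance(g: nx.Graph) -> float:
    """Harmonic mean geodesic distance; disconnected pairs count as 1/d = 0."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need >= 2 nodes")
    recip_sum = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                recip_sum += 1.0 / d
    mean_recip = recip_sum / (n * (n - 1))  # ordered pairs; symmetric
    if mean_recip == 0:
        return float("inf")
    return 1.0 / mean_recip


@dataclass
class TopologySummary:
    n: int
    L: int
    avgK: float
    HD: float
    avgCC: float
    transitivity: float
    modularity: float
    n_modules: int
    powerlaw_r2: float | None

    def as_row(self) -> dict:
        return {
            "n": self.n,
            "links": self.L,
            "R2_power_law": self.powerlaw_r2,
            "avgK": self.avgK,
            "HD": self.HD,
            "avgCC": self.avgCC,
            "modularity": self.modularity,
            "n_modules": self.n_modules,
            "transitivity": self.transitivity,
        }


def topology_summary(
    network: GeneNetwork, partition: ModulePartition | None = None
) -> TopologySummary:
    """Unweighted, unsigned topological indices of the network."""
    g = network.graph
    n, L = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("network too small to summarize")
    if partition is None:
        partition = fast_greedy_modules(network)
    return TopologySummary(
        n=n,
        L=L,
        avgK=2.0 * L / n,
        HD=harmonic_geodesic_distance(g),
        avgCC=nx.average_clustering(g),
        transitivity=nx.transitivity(g),
        modularity=partition.modularity,
        n_modules=partition.n_modules,
        powerlaw_r2=powerlaw_r2(network),
    )


def z_test(empirical: float, ensemble_mean: float, ensemble_sd: float) -> tuple[float, float]:
    """Z = (empirical - mean) / sd with a two-sided normal p value."""
    if ensemble_sd < 0:
        raise ValueError("ensemble sd must be >= 0")
    if ensemble_sd == 0:
        if empirical == ensemble_mean:
            return 0.0, 1.0
        return float("inf") if empirical > ensemble_mean else float("-inf"), 0.0
    z = (empirical - ensemble_mean) / ensemble_sd
    return z, 2.0 * norm.sf(abs(z))


NULL_METHODS = ("degree_preserving", "size_links")
NULL_INDICES = ("HD", "avgCC", "modularity")


@dataclass
class RandomEnsemble:
    method: str
    n_networks: int
    index_values: pd.DataFrame  # one row per random network
    empirical: dict[str, float]

    def mean(self, index: str) -> float:
        return float(self.index_values[index].mean())

    def sd(self, index: str) -> float:
        return float(self.index_values[index].std(ddof=1))

    def z(self, index: str) -> tuple[float, float]:
        return z_test(self.empirical[index], self.mean(index), self.sd(index))

    def summary(self) -> pd.DataFrame:
        rows = []
        for index in self.index_values.columns:
            z, p = self.z(index)
            rows.append(
                {
                    "index": index,
                    "empirical": self.empirical[index],
                    "random_mean": self.mean(index),
                    "random_sd": self.sd(index),
                    "Z": z,
                    "p": p,
                }
            )
        return pd.DataFrame(rows)


def _randomize_degree_preserving(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    h = g.copy()
    L = h.number_of_edges()
    nswap = 10 * L
    try:
        nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap,
                            seed=int(rng.integers(2**31 - 1)))
    except nx.NetworkXAlgorithmError:
        pass  # ran out of tries; the partial shuffle still preserves degrees
    return h


def _randomize_size_links(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    n, L = g.number_of_nodes(), g.number_of_edges()
    h = nx.gnm_random_graph(n, L, seed=int(rng.integers(2**31 - 1)))
    return nx.relabel_nodes(h, dict(enumerate(g.nodes)))


def random_ensemble(
    network: GeneNetwork,
    n_networks: int = 100,
    method: str = "degree_preserving",
    seed: int | None = None,
) -> RandomEnsemble:
    """Null-model ensemble with per-index mean, sd, and Z tests.

    ``degree_preserving`` rewires by repeated double-edge swaps (>= 10 L
    successful swaps per network, no self-loops or multi-edges);
    ``size_links`` draws uniform random graphs with the same n and L.
    """
    if method not in NULL_METHODS:
        raise ValueError(f"method must be one of {NULL_METHODS}, got {method!r}")
    g = network.graph
    if g.number_of_edges() < 2:
        raise ValueError("need >= 2 links to randomize")
    rng = np.random.default_rng(seed)
    randomize = (
        _randomize_degree_preserving if method == "degree_preserving" else _randomize_size_links
    )
    rows = []
    for _ in range(n_networks):
        h = randomize(g, rng)
        part = fast_greedy_modules(h)
        rows.append(
            {
                "HD": harmonic_geodesic_distance(h),
                "avgCC": nx.average_clustering(h),
                "modularity": part.modularity,
            }
        )
    emp_part = fast_greedy_modules(network)
    empirical = {
        "HD": harmonic_geodesic_distance(g),
        "avgCC": nx.average_clustering(g),
        "modularity": emp_part.modularity,
    }
    return RandomEnsemble(method, n_networks, pd.DataFrame(rows), empirical)


def summary_table(
    label: str,
    n_original_genes: int,
    network: GeneNetwork,
    summary: TopologySummary,
    ensemble: RandomEnsemble | None = None,
) -> pd.DataFrame:
    """One row in the conventional network-properties table layout."""
    row = {
        "network": label,
        "original_genes": n_original_genes,
        "st": network.st,
        **summary.as_row(),
        "pct_positive_links": network.pct_positive,
        "pct_negative_links": network.pct_negative,
    }
    if ensemble is not None:
        for index in ensemble.index_values.columns:
            z, p = ensemble.z(index)
            row[f"random_{index}_mean"] = ensemble.mean(index)
            row[f"random_{index}_sd"] = ensemble.sd(index)
            row[f"{index}_Z"] = z
            row[f"{index}_p"] = p
    return pd.DataFrame([row])
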