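"""Weighted graph statistics on functional networks.

Three global metrics (global efficiency, synchronizability, transitivity)
and five nodal metrics (node strength, eigenvector centrality, betweenness
centrality, control centrality, clustering coefficient), plus regional
control centrality for contiguous electrode regions.

Conventions
-----------
* Shortest paths use edge length 1 / weight (strong edges are short);
  zero-weight entries mean "no edge".
* Weighted transitivity and clustering follow the Brain Connectivity
  Toolbox convention: weights are divided by the network maximum before
  the cube-root geometric mean over triplets.
* Betweenness is reported as raw per-pair path counts (set
  ``normalized=True`` for the (N-1)(N-2)/2 normalization).
* Synchronizability is the Laplacian eigenratio lambda_2 / lambda_max,
  defined as 0 for disconnected or edgeless networks; consequently a
  node whose removal disconnects the network has control centrality -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .core import ElectrodeLayout, FunctionalNetwork

__all__ = [
    "global_efficiency",
    "synchronizability",
    "transitivity",
    "node_strength",
    "eigenvector_centrality",
    "betweenness_centrality",
    "control_centrality",
    "clustering_coefficient",
    "regional_control_centrality",
    "RegionalCCResult",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "NODAL_OPTIMUM_SENSE",
]

_EIG_TOL = 1e-12


def _length_graph(adj: np.ndarray) -> csr_matrix:
    """Sparse graph with edge length 1/weight; zero weights are non-edges."""
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / adj, 0.0)
    return csr_matrix(lengths)


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adj > 0), directed=False)
    return n_comp == 1


def global_efficiency(net: FunctionalNetwork) -> float:
    """Mean inverse shortest-path length over all ordered node pairs.

    E = (1 / (N(N-1))) * sum_{i != j} 1 / sigma_ij, with sigma_ij the
    Dijkstra shortest path under length 1/weight. Pairs with no connecting
    path contribute 0, so E of an edgeless network is 0.
    """
    n = net.n_contacts
    if n < 2:
        raise ValueError("global efficiency requires >= 2 contacts")
    dist = dijkstra(_length_graph(net.adjacency), directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def laplacian_spectrum(net: FunctionalNetwork) -> np.ndarray:
    """Ascending eigenvalues of the weighted Laplacian L = D - A."""
    a = net.adjacency
    lap = np.diag(a.sum(axis=1)) - a
    return np.linalg.eigvalsh(lap)


def synchronizability(net: FunctionalNetwork) -> float:
    """Laplacian eigenratio lambda_2 / lambda_max.

    Quantifies the stability of the fully synchronous network state: values
    near 1 (a compressed Laplacian spectrum) indicate a network that
    synchronizes easily. Defined as 0 when the network is disconnected
    (lambda_2 = 0) or edgeless (lambda_max = 0).
    """
    if net.n_contacts < 2:
        raise ValueError("synchronizability requires >= 2 contacts")
    ev = laplacian_spectrum(net)
    lam2, lam_max = ev[1], ev[-1]
    if lam_max <= _EIG_TOL or lam2 <= _EIG_TOL * max(1.0, lam_max):
        return 0.0
    return float(min(lam2 / lam_max, 1.0))


def _normalized_cycles(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node weighted closed-triplet mass and binary degree.

    cyc3_i counts ordered neighbor pairs, i.e. twice the geometric-mean
    weight of the triangles at i, computed on weights scaled by the network
    maximum.
    """
    w_max = adj.max()
    w = adj / w_max if w_max > 0 else adj
    w13 = np.cbrt(w)
    cyc3 = np.diagonal(w13 @ w13 @ w13).copy()
    degree = (adj > 0).sum(axis=1)
    return cyc3, degree


def transitivity(net: FunctionalNetwork) -> float:
    """Weighted triplet ratio: closed-triplet mass over all triplets.

    T = sum_i cyc3_i / sum_i k_i (k_i - 1); 0 when the network has no
    connected triplets.
    """
    if net.n_contacts < 3:
        raise ValueError("transitivity requires >= 3 contacts")
    cyc3, degree = _normalized_cycles(net.adjacency)
    denom = float((degree * (degree - 1)).sum())
    if denom == 0.0:
        return 0.0
    return float(cyc3.sum() / denom)


def clustering_coefficient(net: FunctionalNetwork) -> np.ndarray:
    """Per-node weighted clustering (nodal counterpart of transitivity).

    cl_i = cyc3_i / (v_i (v_i - 1)) with v_i the number of neighbors;
    0 for nodes with fewer than two neighbors.
    """
    if net.n_contacts < 3:
        raise ValueError("clustering coefficient requires >= 3 contacts")
    cyc3, degree = _normalized_cycles(net.adjacency)
    denom = degree * (degree - 1)
    out = np.zeros(net.n_contacts)
    mask = denom > 0
    out[mask] = cyc3[mask] / denom[mask]
    return out


def node_strength(net: FunctionalNetwork) -> np.ndarray:
    """Row sums of the adjacency: total connection weight per contact."""
    if net.n_contacts < 2:
        raise ValueError("node strength requires >= 2 contacts")
    return net.adjacency.sum(axis=1)


def eigenvector_centrality(net: FunctionalNetwork) -> np.ndarray:
    """Leading eigenvector of the adjacency, nonnegative, unit 2-norm.

    By Perron-Frobenius the leading eigenvector of a connected nonnegative
    matrix can be taken entrywise nonnegative. On a disconnected network the
    vector concentrates on the component with the largest eigenvalue; this
    is computed with a warning rather than rejected, because subsampling can
    disconnect otherwise dense networks.
    """
    a = net.adjacency
    if not _is_connected(a):
        warnings.warn(
            "eigenvector centrality on a disconnected network: values "
            "concentrate on the dominant component",
            stacklevel=2,
        )
    _, vecs = np.linalg.eigh(a)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def betweenness_centrality(
    net: FunctionalNetwork, *, normalized: bool = False
) -> np.ndarray:
    """Shortest-path betweenness under edge length 1/weight.

    Counts, for each node, the fraction of shortest paths between other
    node pairs passing through it, summed over unordered pairs (raw counts
    by default).
    """
    if net.n_contacts < 2:
        raise ValueError("betweenness centrality requires >= 2 contacts")
    a = net.adjacency
    g = nx.Graph()
    g.add_nodes_from(range(net.n_contacts))
    ii, jj = np.nonzero(np.triu(a, k=1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / a[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=normalized)
    return np.array([bc[i] for i in range(net.n_contacts)])


def control_centrality(net: FunctionalNetwork) -> np.ndarray:
    """Relative change in synchronizability from deleting each contact.

    c_i = (Sync_new - Sync_old) / Sync_old, where Sync_new is the
    synchronizability of the network with contact i's row and column
    removed. Negative values mark synchronizing nodes (their removal lowers
    synchronizability); c_i = -1 exactly when removal disconnects the
    network. Undefined (raises) when the original synchronizability is 0.
    """
    n = net.n_contacts
    if n < 3:
        raise ValueError("control centrality requires >= 3 contacts")
    sync_old = synchronizability(net)
    if sync_old == 0.0:
        raise ValueError("control centrality undefined: original synchronizability is 0")
    out = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        sub = net.subnetwork(all_idx[all_idx != i])
        out[i] = (synchronizability(sub) - sync_old) / sync_old
    return out


@dataclass(frozen=True)
class RegionalCCResult:
    """Control centrality of contiguous regions, one per seed contact.

    ``per_seed_values[i]`` is the relative synchronizability change when the
    region grown from seed contact i (the seed plus its nearest neighbors)
    is removed; ``argmin_region`` is the most synchronizing region.
    """

    per_seed_values: np.ndarray
    regions: tuple[tuple[int, ...], ...]
    argmin_seed: int
    region_size: int

    @property
    def argmin_region(self) -> tuple[int, ...]:
        return self.regions[self.argmin_seed]


def regional_control_centrality(
    net: FunctionalNetwork, layout: ElectrodeLayout, region_size: int
) -> RegionalCCResult:
    """Control centrality of each contact's spatial neighborhood.

    For every seed contact, form the region of the seed plus its
    ``region_size - 1`` nearest neighbors (Euclidean distance in the
    layout; ties to the lowest contact index), delete the region, and
    record the relative synchronizability change. The minimizing region --
    the one whose removal most desynchronizes the network -- is a candidate
    surgical target.
    """
    n = net.n_contacts
    if len(layout) != n:
        raise ValueError(f"layout has {len(layout)} contacts, network has {n}")
    if not 1 <= region_size <= n - 2:
        raise ValueError(
            f"region_size must be in [1, {n - 2}] for {n} contacts, got {region_size}"
        )
    sync_old = synchronizability(net)
    if sync_old == 0.0:
        raise ValueError(
            "regional control centrality undefined: original synchronizability is 0"
        )
    values = np.empty(n)
    regions = []
    all_idx = np.arange(n)
    for seed in range(n):
        region = layout.nearest_neighbors(seed, region_size)
        regions.append(tuple(int(i) for i in region))
        keep = all_idx[~np.isin(all_idx, region)]
        values[seed] = (synchronizability(net.subnetwork(keep)) - sync_old) / sync_old
    argmin_seed = int(np.argmin(values))  # ties -> lowest seed index
    return RegionalCCResult(
        per_seed_values=values,
        regions=tuple(regions),
        argmin_seed=argmin_seed,
        region_size=region_size,
    )


#: Dispatch tables used by the subsampling, reliability, and jackknife stages.
GLOBAL_METRICS = {
    "global_efficiency": global_efficiency,
    "synchronizability": synchronizability,
    "transitivity": transitivity,
}

NODAL_METRICS = {
    "node_strength": node_strength,
    "eigenvector_centrality": eigenvector_centrality,
    "betweenness_centrality": betweenness_centrality,
    "control_centrality": control_centrality,
    "clustering_coefficient": clustering_coefficient,
}

#: Whether the "optimal" contact for a nodal metric is its max or min.
NODAL_OPTIMUM_SENSE = {name: "max" for name in NODAL_METRICS}
NODAL_OPTIMUM_SENSE["control_centrality"] = "min"
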