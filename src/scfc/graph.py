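"""Binary graph construction and global efficiency.

Structural networks are binarized at one or more fibers; functional networks
keep edges whose Fisher-z value is positive and Benjamini-Hochberg
significant at the chosen false-discovery rate.  Global efficiency is the
mean inverse shortest-path length (hop counts, breadth-first search) over
ordered node pairs, with disconnected pairs contributing zero:

    E_glob = 1 / (N (N - 1)) * sum_{i != j} 1 / d(i, j)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from scfc.matrices import ConnectivityMatrix, DataError
from scfc.subnetworks import SubnetworkDefinition


@dataclass
class BinaryGraph:
    """An undirected, unweighted graph as a 0/1 adjacency matrix."""

    adjacency: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise DataError(f"adjacency must be square, got {adj.shape}")
        if not np.array_equal(adj, adj.T):
            raise DataError("adjacency must be symmetric")
        if not np.all(np.isin(adj, (0, 1))):
            raise DataError("adjacency entries must be 0 or 1")
        self.adjacency = adj.astype(np.int8)
        np.fill_diagonal(self.adjacency, 0)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def threshold_structural(sc: ConnectivityMatrix) -> BinaryGraph:
    """Binarize a fiber-count matrix: an edge exists at >= 1 fiber."""
    if sc.modality != "SC":
        raise DataError(f"expected SC modality, got {sc.modality}")
    if np.any(sc.values < 0):
        raise DataError("negative fiber count")
    return BinaryGraph(
        adjacency=(sc.values >= 1).astype(np.int8), node_labels=list(sc.node_labels)
    )


def fisher_z_edge_pvalues(z: np.ndarray, t_points: int) -> np.ndarray:
    """Two-sided p-values for Fisher-z correlations from n time points.

    Under the null, z * sqrt(n - 3) is standard normal; p = 2 (1 - Phi(|z| sqrt(n-3))).
    """
    if t_points <= 3:
        raise ValueError(f"t_points must exceed 3 for a defined SE, got {t_points}")
    se = 1.0 / np.sqrt(t_points - 3)
    return 2.0 * stats.norm.sf(np.abs(z) / se)


def bh_reject(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


def threshold_functional(
    fc: ConnectivityMatrix, t_points: int, q: float = 0.05
) -> BinaryGraph:
    """Keep positive FC edges that survive BH FDR at level ``q``.

    Each strict upper-triangle Fisher-z edge gets a two-sided normal p-value;
    BH runs over all upper-triangle edges of this matrix; surviving edges with
    z > 0 become graph edges.
    """
    if fc.modality != "FC":
        raise DataError(f"expected FC modality, got {fc.modality}")
    n = fc.n_nodes
    iu = np.triu_indices(n, k=1)
    z = fc.values[iu]
    pvals = fisher_z_edge_pvalues(z, t_points)
    keep = bh_reject(pvals, q) & (z > 0)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu] = keep
    adj += adj.T
    return BinaryGraph(adjacency=adj, node_labels=list(fc.node_labels))


def extract_subnetwork(obj, subnet: SubnetworkDefinition):
    """Principal submatrix restricted to a subnetwork's regions.

    Works on either a :class:`ConnectivityMatrix` or a :class:`BinaryGraph`;
    returns the same type with rows/columns in subnetwork region order.
    """
    idx = subnet.indices(obj.node_labels)
    sub_labels = [obj.node_labels[i] for i in idx]
    if isinstance(obj, BinaryGraph):
        return BinaryGraph(
            adjacency=obj.adjacency[np.ix_(idx, idx)], node_labels=sub_labels
        )
    return ConnectivityMatrix(
        values=obj.values[np.ix_(idx, idx)],
        node_labels=sub_labels,
        modality=obj.modality,
    )


def bfs_hop_distances(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by breadth-first search.

    Frontier expansion is vectorized over sources with boolean matrix
    products.  Unreachable pairs are returned as ``inf``.
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    hops = 0
    while frontier.any():
        hops += 1
        frontier = (frontier @ adj) & ~reached
        dist[frontier] = hops
        reached |= frontier
    return dist


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs, in [0, 1].

    Equals 1 for a complete graph; disconnected pairs contribute 0.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError(f"global efficiency needs >= 2 nodes, got {n}")
    dist = bfs_hop_distances(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    return float(inv.sum() / (n * (n - 1)))
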