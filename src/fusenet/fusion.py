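"""Similarity network fusion, disparity-filter backbone and IC genes.

The two condition networks are fused by cross-diffusion: each condition's
similarity matrix is propagated through the other's K-nearest-neighbor
kernel,

    W_{t+1}^(n) = S^(n) W_t^(c) S^(n)^T
    W_{t+1}^(c) = S^(c) W_t^(n) S^(c)^T

until the relative Frobenius change of the running average drops below the
tolerance; the fused network is the average of the two converged iterates.
The fused (dense) network is then pruned with the disparity filter
(per-node significance alpha = (1 - p)^(k - 1) of each edge's normalized
weight under a uniform null), communities are extracted by modularity
maximization on the backbone, and the genes of the sufficiently large
communities form the Integrated Community (IC) gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import WeightedGeneNetwork

logger = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_TOLERANCE = 1e-5
DEFAULT_MAX_ITER = 50
#: weight of the identity source term mixed into each diffusion step.  The
#: literal alternating recursion is generically non-convergent (its even
#: and odd fused iterates approach two different limits), so by default a
#: fraction of the identity is re-injected every step, which turns the
#: update into an affine contraction with a unique fixed point; 0 recovers
#: the literal recursion.
DEFAULT_IDENTITY_MIXING = 0.3
DEFAULT_DISPARITY_PERCENTILE = 99.0
DEFAULT_MIN_SIZE_FRACTION = 0.01


class ConvergenceError(RuntimeError):
    """Raised when the diffusion does not converge within max_iter."""

    def __init__(self, max_iter: int, last_rel_diff: float):
        super().__init__(
            f"SNF did not converge in {max_iter} iterations "
            f"(last relative difference {last_rel_diff:.3e})"
        )
        self.last_rel_diff = last_rel_diff


@dataclass
class FusedNetwork:
    """Fused adjacency plus its disparity-filtered backbone."""

    genes: list[str]
    weights: np.ndarray  # dense fused adjacency, symmetric, zero diagonal
    t_star: int
    backbone: pd.DataFrame | None = None  # gene_a, gene_b, weight, alpha
    alpha_cutoff: float | None = None
    final_rel_diff: float | None = None  # relative difference at termination

    def backbone_genes(self) -> list[str]:
        if self.backbone is None or self.backbone.empty:
            return []
        return sorted(set(self.backbone["gene_a"]) | set(self.backbone["gene_b"]))

    def backbone_graph(self) -> nx.Graph:
        g = nx.Graph()
        if self.backbone is not None:
            for row in self.backbone.itertuples(index=False):
                g.add_edge(row.gene_a, row.gene_b, weight=row.weight, alpha=row.alpha)
        return g


@dataclass
class CommunityPartition:
    """Gene -> community assignment with modularity and the IC selection."""

    assignment: dict[str, int]
    modularity: float
    ic_genes: set[str] = field(default_factory=set)
    selected_communities: list[int] = field(default_factory=list)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignment.values():
            out[c] = out.get(c, 0) + 1
        return out


def knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized similarity restricted to each node's top-K neighbors.

    N_i is the set of (at most) K neighbors with the largest positive
    weight; ties are broken by node index for determinism.  A node with no
    positive off-diagonal weight gets an all-zero row (logged, not an
    error).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    n = W.shape[0]
    S = np.zeros_like(W, dtype=float)
    isolated = 0
    for i in range(n):
        row = W[i].copy()
        row[i] = 0.0
        nonzero = np.nonzero(row)[0]
        if nonzero.size == 0:
            isolated += 1
            continue
        # stable descending sort by weight, index as tie-break
        order = nonzero[np.lexsort((nonzero, -row[nonzero]))]
        neighbors = order[:K]
        total = row[neighbors].sum()
        S[i, neighbors] = row[neighbors] / total
    if isolated:
        logger.info("knn_kernel: %d isolated nodes with all-zero kernel rows", isolated)
    return S


def diffusion_step(
    S_n: np.ndarray, S_c: np.ndarray, W_n: np.ndarray, W_c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One literal cross-diffusion update of the two similarity iterates."""
    return S_n @ W_c @ S_n.T, S_c @ W_n @ S_c.T


def snf_fuse(
    W_n: WeightedGeneNetwork | np.ndarray,
    W_c: WeightedGeneNetwork | np.ndarray,
    K: int = DEFAULT_K,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    genes: list[str] | None = None,
    identity_mixing: float = DEFAULT_IDENTITY_MIXING,
) -> FusedNetwork:
    """Cross-diffusion fusion of the normal and cancer networks.

    With ``identity_mixing = eps > 0`` each step computes
    ``(1 - eps) * S W S^T + eps * I`` (both sides), which stabilizes the
    recursion into an affine contraction; ``identity_mixing = 0`` runs the
    literal recursion.  Convergence is declared when the relative Frobenius
    change of the running fused average drops below ``tolerance``.
    """
    if isinstance(W_n, WeightedGeneNetwork):
        if not isinstance(W_c, WeightedGeneNetwork) or W_n.genes != W_c.genes:
            raise ValueError("networks must share the same gene universe in the same order")
        genes = W_n.genes
        W_n, W_c = W_n.weights, W_c.weights
    elif genes is None:
        genes = [f"g{i}" for i in range(np.asarray(W_n).shape[0])]
    Wn = np.asarray(W_n, dtype=float)
    Wc = np.asarray(W_c, dtype=float)
    if Wn.shape != Wc.shape:
        raise ValueError("adjacency matrices must have the same shape")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not 0.0 <= identity_mixing < 1.0:
        raise ValueError("identity_mixing must be in [0, 1)")

    Sn = knn_kernel(Wn, K)
    Sc = knn_kernel(Wc, K)
    eye = np.eye(Wn.shape[0])
    fused_prev = (Wn + Wc) / 2.0
    rel_diff = np.inf
    for t in range(1, max_iter + 1):
        Wn_next, Wc_next = diffusion_step(Sn, Sc, Wn, Wc)
        if identity_mixing > 0:
            Wn_next = (1.0 - identity_mixing) * Wn_next + identity_mixing * eye
            Wc_next = (1.0 - identity_mixing) * Wc_next + identity_mixing * eye
        # floating-point symmetrization after each diffusion step
        Wn = (Wn_next + Wn_next.T) / 2.0
        Wc = (Wc_next + Wc_next.T) / 2.0
        fused = (Wn + Wc) / 2.0
        denom = np.linalg.norm(fused_prev)
        if denom == 0:
            raise ValueError("fused matrix vanished during diffusion")
        rel_diff = np.linalg.norm(fused - fused_prev) / denom
        fused_prev = fused
        if rel_diff < tolerance:
            out = (fused + fused.T) / 2.0
            np.fill_diagonal(out, 0.0)
            return FusedNetwork(
                genes=list(genes), weights=out, t_star=t, final_rel_diff=float(rel_diff)
            )
    raise ConvergenceError(max_iter, rel_diff)


def disparity_alpha(W: np.ndarray) -> np.ndarray:
    """Directed disparity significance alpha_ij = (1 - w_ij / s_i)^(k_i - 1).

    Nodes of degree 1 get alpha = 1 on their side (a single edge is never
    significant from that endpoint); zero-strength nodes contribute alpha =
    1 as well.  Entries without an edge are set to 1.
    """
    n = W.shape[0]
    alpha = np.ones_like(W, dtype=float)
    degree = (W > 0).sum(axis=1)
    strength = W.sum(axis=1)
    for i in range(n):
        if degree[i] <= 1 or strength[i] <= 0:
            continue
        js = np.nonzero(W[i])[0]
        p = W[i, js] / strength[i]
        alpha[i, js] = (1.0 - p) ** (degree[i] - 1)
    return alpha


def disparity_filter(
    fused: FusedNetwork,
    percentile: float = DEFAULT_DISPARITY_PERCENTILE,
    keep_below: bool = True,
) -> FusedNetwork:
    """Backbone extraction at a percentile cutoff of the alpha distribution.

    An undirected edge's alpha is the minimum of its two directed values
    (kept if significant from either endpoint).  With ``keep_below`` (the
    default) the cutoff is the (100 - percentile)-th percentile of the
    per-edge alpha distribution and edges at or below it are retained, so
    ``percentile = 99`` keeps the most significant ~1% of edges.
    """
    W = fused.weights
    alpha_dir = disparity_alpha(W)
    iu, ju = np.triu_indices(W.shape[0], k=1)
    mask = W[iu, ju] > 0
    ii, jj = iu[mask], ju[mask]
    alpha = np.minimum(alpha_dir[ii, jj], alpha_dir[jj, ii])
    if alpha.size == 0:
        raise ValueError("fused network has no edges")
    if keep_below:
        cutoff = float(np.percentile(alpha, 100.0 - percentile))
        keep = alpha <= cutoff
    else:
        cutoff = float(np.percentile(alpha, percentile))
        keep = alpha >= cutoff
    rows = []
    for i, j, a in zip(ii[keep], jj[keep], alpha[keep]):
        a_id, b_id = sorted((fused.genes[i], fused.genes[j]))
        rows.append((a_id, b_id, W[i, j], a))
    backbone = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "alpha"])
    backbone = backbone.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return FusedNetwork(
        genes=fused.genes,
        weights=fused.weights,
        t_star=fused.t_star,
        backbone=backbone,
        alpha_cutoff=cutoff,
        final_rel_diff=fused.final_rel_diff,
    )


def detect_communities(
    backbone: nx.Graph | FusedNetwork,
    resolution: float = 1.0,
    seed: int = 0,
) -> CommunityPartition:
    """Louvain modularity communities on the weighted backbone."""
    g = backbone.backbone_graph() if isinstance(backbone, FusedNetwork) else backbone
    if g.number_of_edges() == 0:
        raise ValueError("backbone is empty")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    q = nx.community.modularity(g, communities, weight="weight", resolution=resolution)
    assignment = {}
    for cid, members in enumerate(communities):
        for node in members:
            assignment[node] = cid
    return CommunityPartition(assignment=assignment, modularity=float(q))


def select_ic_genes(
    partition: CommunityPartition,
    min_size_fraction: float = DEFAULT_MIN_SIZE_FRACTION,
) -> CommunityPartition:
    """IC genes = union of communities holding >= fraction of backbone nodes."""
    n_nodes = len(partition.assignment)
    cutoff = min_size_fraction * n_nodes
    sizes = partition.sizes()
    selected = sorted(c for c, s in sizes.items() if s >= cutoff)
    ic = {g for g, c in partition.assignment.items() if c in set(selected)}
    partition.ic_genes = ic
    partition.selected_communities = selected
    return partition


def partition_table(partition: CommunityPartition) -> pd.DataFrame:
    rows = [
        (g, c, int(g in partition.ic_genes))
        for g, c in sorted(partition.assignment.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "community_id", "is_ic"])
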