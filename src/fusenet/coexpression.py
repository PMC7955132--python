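"""Dual-metric gene co-expression networks.

For each condition two similarity networks are built over the filtered
gene universe:

* a Euclidean-distance network, thresholded at the 99th percentile of the
  off-diagonal weight distribution (keeping the gene pairs with the
  largest expression difference), and
* a Pearson-correlation network, pruned by a permutation null (10
  independent shuffles of each gene's profile) and then balanced to the
  Euclidean edge count by keeping the smallest-p edges.

The two are merged per condition by summing the max-normalized
log-distance weights with the absolute correlations, yielding weights in
[0, 2] over the union of the two edge sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class WeightedGeneNetwork:
    """Symmetric gene-gene adjacency with measure/condition provenance.

    Weights are stored dense; 0 means "no edge".  For ``measure ==
    "pearson"`` weights are signed correlations in [-1, 1] (with the
    per-edge p-value matrix alongside); for all other measures weights are
    non-negative.
    """

    genes: list[str]
    weights: np.ndarray
    measure: str = "euclidean"  # euclidean | pearson | combined
    condition: str = "normal"
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape does not match the gene list")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be zero")
        if self.measure != "pearson" and (w < 0).any():
            raise ValueError("negative weights are only allowed for the pearson measure")

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(len(self.genes), k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> pd.DataFrame:
        """3-column edge list (gene_a < gene_b lexicographically)."""
        iu, ju = np.triu_indices(len(self.genes), k=1)
        mask = self.weights[iu, ju] != 0
        rows = []
        for i, j in zip(iu[mask], ju[mask]):
            a, b = sorted((self.genes[i], self.genes[j]))
            rows.append((a, b, self.weights[i, j]))
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])

    def to_tsv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)


@dataclass
class PermutationBounds:
    """Significance limits of the permuted-null correlation distribution."""

    lower: float
    upper: float
    n_shuffles: int = 10
    mode: str = "pooled"  # pooled | averaged

    def __post_init__(self) -> None:
        if not (self.lower <= 0.0 <= self.upper):
            raise ValueError("bounds must bracket zero")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


def euclidean_network(expr: ExpressionMatrix) -> WeightedGeneNetwork:
    """Pairwise Euclidean distances between gene expression profiles."""
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(expr.values.to_numpy(), metric="euclidean"))
    return WeightedGeneNetwork(
        genes=expr.genes, weights=d, measure="euclidean", condition=expr.condition
    )


def threshold_euclidean(
    net: WeightedGeneNetwork, percentile: float = 99.0
) -> WeightedGeneNetwork:
    """Keep edges strictly above the given percentile of the edge weights.

    The percentile (linear interpolation) is taken over the nonzero
    off-diagonal weights; ``percentile <= 0`` is a no-op so that "0th
    percentile" means "keep every edge".
    """
    n = len(net.genes)
    iu = np.triu_indices(n, k=1)
    values = net.weights[iu]
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("network has no edges")
    if percentile <= 0:
        return WeightedGeneNetwork(
            genes=net.genes, weights=net.weights.copy(),
            measure=net.measure, condition=net.condition,
        )
    cut = np.percentile(values, percentile)
    w = np.where(net.weights > cut, net.weights, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedGeneNetwork(
        genes=net.genes, weights=w, measure=net.measure, condition=net.condition
    )


def _pearson_with_pvalues(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = x.shape[1]
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    # exact t-transform: t = r * sqrt((m - 2) / (1 - r^2)), two-sided
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((m - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * t_dist.sf(np.abs(t), df=m - 2)
    np.fill_diagonal(p, 1.0)
    p = (p + p.T) / 2.0
    return r, p


def pearson_network(
    expr: ExpressionMatrix, drop_constant: bool = False
) -> WeightedGeneNetwork:
    """Pairwise Pearson correlations with per-edge two-sided p-values.

    Constant-expression genes either raise (default) or are dropped with a
    warning when ``drop_constant`` is set (full-pipeline mode).
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = expr.values.to_numpy()
    variances = x.var(axis=1)
    constant = [g for g, v in zip(expr.genes, variances) if v == 0]
    if constant:
        if not drop_constant:
            raise ValueError(f"zero-variance genes: {constant}")
        logger.warning("dropping %d constant-expression genes: %s", len(constant), constant[:5])
        expr = expr.subset_genes([g for g in expr.genes if g not in set(constant)])
        x = expr.values.to_numpy()
    r, p = _pearson_with_pvalues(x)
    return WeightedGeneNetwork(
        genes=expr.genes, weights=r, measure="pearson", condition=expr.condition, pvalues=p
    )


def permutation_bounds(
    expr: ExpressionMatrix,
    n_shuffles: int = 10,
    seed: int = 0,
    mode: str = "pooled",
) -> PermutationBounds:
    """Null correlation limits from independent per-gene profile shuffles.

    Each shuffle permutes every gene's values across samples independently,
    destroying gene-gene association while preserving marginals.  In
    ``pooled`` mode (default) the bounds are the min and max over all
    shuffles' correlations; in ``averaged`` mode the per-pair correlations
    are first averaged across shuffles.
    """
    if mode not in {"pooled", "averaged"}:
        raise ValueError(f"bad mode: {mode!r}")
    rng = np.random.default_rng(seed)
    x = expr.values.to_numpy()
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    null_r = []
    for _ in range(n_shuffles):
        shuffled = rng.permuted(x, axis=1)
        r = np.corrcoef(shuffled)
        null_r.append(r[iu])
    stacked = np.vstack(null_r)
    values = stacked.mean(axis=0) if mode == "averaged" else stacked.ravel()
    return PermutationBounds(
        lower=float(values.min()),
        upper=float(values.max()),
        n_shuffles=n_shuffles,
        mode=mode,
    )


def threshold_pearson(
    net: WeightedGeneNetwork,
    bounds: PermutationBounds,
    target_edge_count: int,
) -> WeightedGeneNetwork:
    """Null-band filter followed by p-value balancing to the target count.

    Edges with correlation inside [lower, upper] are removed; survivors are
    sorted by (p-value, gene-pair id) and the ``target_edge_count``
    smallest-p edges are kept.  If fewer survive, all survivors are kept
    with a warning.
    """
    if net.pvalues is None:
        raise ValueError("network carries no p-values; build it with pearson_network")
    n = len(net.genes)
    iu, ju = np.triu_indices(n, k=1)
    r = net.weights[iu, ju]
    surviving = (r < bounds.lower) | (r > bounds.upper)
    idx = np.nonzero(surviving)[0]
    if idx.size < target_edge_count:
        warnings.warn(
            f"only {idx.size} edges survive the null band "
            f"(target {target_edge_count}); keeping all survivors",
            stacklevel=2,
        )
        keep = idx
    else:
        pairs = [
            (net.pvalues[iu[k], ju[k]], net.genes[iu[k]], net.genes[ju[k]], k)
            for k in idx
        ]
        pairs.sort()
        keep = np.array([k for *_, k in pairs[:target_edge_count]], dtype=int)
    w = np.zeros_like(net.weights)
    w[iu[keep], ju[keep]] = net.weights[iu[keep], ju[keep]]
    w = w + w.T
    return WeightedGeneNetwork(
        genes=net.genes,
        weights=w,
        measure="pearson",
        condition=net.condition,
        pvalues=net.pvalues,
    )


def combine_measures(
    eucl: WeightedGeneNetwork, pears: WeightedGeneNetwork
) -> WeightedGeneNetwork:
    """Sum of max-normalized log-distances and absolute correlations.

    Distances d are mapped through log1p before max-normalization so that
    distances <= 1 (whose plain log would be <= 0) still yield positive
    weights; log1p is monotone, so the normalization fixed point (the
    maximum-distance edge mapping to exactly 1) is preserved.
    """
    if eucl.genes != pears.genes:
        raise ValueError("networks must share the same gene universe in the same order")
    log_d = np.where(eucl.weights > 0, np.log1p(eucl.weights), 0.0)
    max_log = log_d.max()
    if eucl.n_edges > 0 and max_log <= 0:
        raise ValueError("maximum log-distance is zero; cannot normalize")
    eucl_part = log_d / max_log if max_log > 0 else log_d
    pears_part = np.abs(pears.weights)
    w = eucl_part + pears_part
    np.fill_diagonal(w, 0.0)
    return WeightedGeneNetwork(
        genes=eucl.genes, weights=w, measure="combined", condition=eucl.condition
    )


def build_condition_network(
    expr: ExpressionMatrix,
    euclidean_percentile: float = 99.0,
    n_shuffles: int = 10,
    seed: int = 0,
    null_mode: str = "pooled",
) -> dict:
    """Full per-condition network construction; returns all intermediates."""
    eucl = threshold_euclidean(euclidean_network(expr), percentile=euclidean_percentile)
    pears_full = pearson_network(expr, drop_constant=True)
    if pears_full.genes != expr.genes:
        # constant genes were dropped from the pearson side; drop them from
        # the euclidean side too so that the union is over one universe
        expr = expr.subset_genes(pears_full.genes)
        eucl = threshold_euclidean(euclidean_network(expr), percentile=euclidean_percentile)
    bounds = permutation_bounds(expr, n_shuffles=n_shuffles, seed=seed, mode=null_mode)
    pears = threshold_pearson(pears_full, bounds, target_edge_count=eucl.n_edges)
    combined = combine_measures(eucl, pears)
    return {
        "euclidean": eucl,
        "pearson": pears,
        "bounds": bounds,
        "combined": combined,
    }
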