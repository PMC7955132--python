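"""Active-gene filtering via the zFPKM transform and biotype selection.

zFPKM re-expresses log2 FPKM as a z-score against the active-gene
distribution of each sample: the mode mu of the log2 density is located by
a Gaussian kernel density estimate, and the spread is estimated from the
right half of the distribution as sigma = (U - mu) * sqrt(pi / 2), where U
is the mean of the log2 values above the mode.  Genes whose mean zFPKM
exceeds -3.0 in both conditions are considered biologically active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .matrix import ExpressionMatrix

#: zFPKM assigned to zero-FPKM entries (log2 undefined); large negative
#: sentinel keeps per-gene means finite and conservative.
ZERO_FPKM_SENTINEL = -30.0

DEFAULT_THRESHOLD = -3.0

KDE_GRID_POINTS = 512

RNA_BIOTYPES = frozenset({"protein_coding", "lncRNA"})


@dataclass
class ZfpkmMatrix:
    """zFPKM values plus the per-sample (mu, sigma) fit parameters."""

    values: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    condition: str

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def filter_biotypes(matrix: ExpressionMatrix, annotation: pd.Series) -> ExpressionMatrix:
    """Keep protein-coding and lncRNA genes; pass miRNAs through.

    Raises if any gene id lacks an annotation entry.
    """
    missing = [g for g in matrix.genes if g not in annotation.index]
    if missing:
        raise ValueError(f"genes with unknown biotype: {missing}")
    keep_labels = RNA_BIOTYPES | {"miRNA"}
    keep = [g for g in matrix.genes if annotation.loc[g] in keep_labels]
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        biotypes=annotation.loc[keep],
        condition=matrix.condition,
    )


def _fit_sample(log2_fpkm: np.ndarray) -> tuple[float, float]:
    """Fit (mu, sigma) for one sample from positive log2 FPKMs.

    mu is the grid argmax of a Silverman-bandwidth Gaussian KDE evaluated on
    512 points spanning the data range plus 3 bandwidths on each side.
    """
    kde = gaussian_kde(log2_fpkm, bw_method="silverman")
    bw = kde.factor * log2_fpkm.std(ddof=1)
    lo, hi = log2_fpkm.min() - 3 * bw, log2_fpkm.max() + 3 * bw
    grid = np.linspace(lo, hi, KDE_GRID_POINTS)
    density = kde(grid)
    mu = float(grid[np.argmax(density)])
    upper = log2_fpkm[log2_fpkm > mu]
    if upper.size == 0:
        raise ValueError("no log2 FPKM values above the fitted mode")
    sigma = float((upper.mean() - mu) * np.sqrt(np.pi / 2.0))
    if sigma <= 0:
        raise ValueError(f"non-positive sigma estimate ({sigma})")
    return mu, sigma


def compute_zfpkm(matrix: ExpressionMatrix) -> ZfpkmMatrix:
    """Per-sample zFPKM transform of an expression matrix.

    Zero FPKMs are excluded from the density fit and mapped to a -30
    sentinel in the output.
    """
    z = np.empty(matrix.values.shape)
    mus, sigmas = {}, {}
    x = matrix.values.to_numpy()
    for j, sample in enumerate(matrix.samples):
        col = x[:, j]
        positive = col > 0
        if positive.sum() < 2:
            raise ValueError(f"sample {sample}: fewer than 2 genes with positive FPKM")
        log2_fpkm = np.log2(col[positive])
        mu, sigma = _fit_sample(log2_fpkm)
        mus[sample] = mu
        sigmas[sample] = sigma
        z[:, j] = ZERO_FPKM_SENTINEL
        z[positive, j] = (log2_fpkm - mu) / sigma
    return ZfpkmMatrix(
        values=pd.DataFrame(z, index=matrix.genes, columns=matrix.samples),
        mu=pd.Series(mus),
        sigma=pd.Series(sigmas),
        condition=matrix.condition,
    )


def active_gene_filter(
    normal: ZfpkmMatrix,
    cancer: ZfpkmMatrix,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[str]:
    """Genes whose mean zFPKM exceeds ``threshold`` in both conditions."""
    shared = [g for g in normal.genes if g in set(cancer.genes)]
    if not shared:
        raise ValueError("normal and cancer matrices share no genes")
    mean_n = normal.values.loc[shared].mean(axis=1)
    mean_c = cancer.values.loc[shared].mean(axis=1)
    mask = (mean_n > threshold) & (mean_c > threshold)
    return [g for g in shared if mask.loc[g]]


def preprocess_pair(
    normal: ExpressionMatrix,
    cancer: ExpressionMatrix,
    annotation: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Biotype filter + zFPKM activity filter over both conditions."""
    normal_f = filter_biotypes(normal, annotation)
    cancer_f = filter_biotypes(cancer, annotation)
    active = active_gene_filter(
        compute_zfpkm(normal_f), compute_zfpkm(cancer_f), threshold=threshold
    )
    return normal_f.subset_genes(active), cancer_f.subset_genes(active)
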