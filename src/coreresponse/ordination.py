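"""PCA of the expression matrix and extraction of top-loading genes.

PCA runs on replicate-level samples of log2(normalized CPM + prior), with
per-gene centering and no gene scaling, via singular value decomposition. A
deterministic sign convention (largest-magnitude element of each loading
column is positive) makes outputs reproducible across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import CountMatrix
from .normalization import NormFactors, cpm

__all__ = ["PCAResult", "expression_matrix", "run_pca", "top_loading_genes"]


@dataclass
class PCAResult:
    gene_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # genes x components, orthonormal columns
    variance_explained: np.ndarray  # fractions, sum <= 1
    transform: str


def expression_matrix(
    counts: CountMatrix, factors: NormFactors | None = None, prior: float = 1.0
) -> np.ndarray:
    """log2(normalized CPM + prior), genes x samples."""
    return np.log2(cpm(counts, factors) + prior)


def run_pca(matrix: np.ndarray, gene_ids=None, sample_ids=None) -> PCAResult:
    """SVD-based PCA of a genes x samples matrix (per-gene centering)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("PCA requires a 2-D matrix with at least 2 samples")
    centered = X - X.mean(axis=1, keepdims=True)
    total_var = np.sum(centered**2)
    if total_var == 0:
        raise ValueError("matrix is constant across samples; no variance for PCA")
    # samples x genes orientation for SVD
    U, S, Vt = np.linalg.svd(centered.T, full_matrices=False)
    scores = U * S[None, :]
    loadings = Vt.T
    var_explained = S**2 / np.sum(S**2)
    # deterministic sign: largest-|.| element of each loading column positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    n_genes, n_samples = X.shape
    return PCAResult(
        gene_ids=list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n_genes)],
        sample_ids=list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n_samples)],
        scores=scores,
        loadings=loadings,
        variance_explained=var_explained,
        transform="log2(cpm + prior), gene-centered, unscaled",
    )


def top_loading_genes(pca: PCAResult, component: int = 1, n: int = 100):
    """Genes ranked by |loading| on a component (1-based), descending; ties
    break by canonical gene order. Returns a list of (gene, loading)."""
    if not 1 <= component <= pca.loadings.shape[1]:
        raise ValueError(
            f"component {component} out of range 1..{pca.loadings.shape[1]}"
        )
    col = pca.loadings[:, component - 1]
    if n > len(col):
        warnings.warn(
            f"requested top {n} genes but only {len(col)} available; returning all"
        )
        n = len(col)
    order = np.argsort(-np.abs(col), kind="stable")[:n]
    return [(pca.gene_ids[i], float(col[i])) for i in order]
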