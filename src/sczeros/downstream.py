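"""Downstream analyses run on observed, binarized, or imputed counts.

Desk-scale versions of the standard scRNA-seq pipeline stages: binarization,
library-size log-normalization, PCA + 2-D neighbor-graph embedding, seeded
modularity clustering on a shared-nearest-neighbor graph, and two per-gene
differential-expression tests (a count-model likelihood-ratio test that
reuses the model-selection machinery, and a two-sample detection-proportion
test for binarized data) with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from . import models
from .containers import CountMatrix
from .models import N_PARAMS

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "NormalizedMatrix",
    "binarize",
    "normalize_log",
    "reduce_embed",
    "cluster_cells",
    "de_test_count_lrt",
    "de_test_proportion",
    "bh_adjust",
]


@dataclass
class DEResult:
    """Per-gene p-values, BH-adjusted values, and 5%-FDR discoveries."""

    pvalues: np.ndarray
    adjusted: np.ndarray
    discovered: np.ndarray
    fdr_level: float


@dataclass
class NormalizedMatrix:
    """Log-normalized expression (genes x cells) over the retained cells."""

    values: np.ndarray
    cell_ids: list[str]
    cell_types: list[str] | None
    kept_cells: np.ndarray  # column indices into the source matrix


def binarize(matrix: CountMatrix) -> CountMatrix:
    """Truncate all non-zero counts to one, keeping only detection patterns."""
    out = matrix.copy()
    out.values = (out.values > 0).astype(np.int64)
    return out


def normalize_log(matrix: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """log(1 + scale * count / cell_total); zero-total cells are dropped."""
    totals = matrix.values.sum(axis=0)
    keep = np.flatnonzero(totals > 0)
    dropped = matrix.n_cells - keep.size
    if dropped:
        ids = [matrix.cell_ids[j] for j in np.flatnonzero(totals == 0)]
        logger.warning("dropping %d zero-total cells: %s", dropped, ids[:10])
    vals = matrix.values[:, keep].astype(float)
    vals = np.log1p(scale * vals / totals[keep])
    return NormalizedMatrix(
        values=vals,
        cell_ids=[matrix.cell_ids[j] for j in keep],
        cell_types=None
        if matrix.cell_types is None
        else [matrix.cell_types[j] for j in keep],
        kept_cells=keep,
    )


def top_variable_genes(norm: NormalizedMatrix, n_top: int = 2000) -> np.ndarray:
    """Indices of the most variable genes of a log-normalized matrix."""
    var = norm.values.var(axis=1)
    n_top = min(n_top, var.size)
    return np.sort(np.argsort(-var, kind="stable")[:n_top])


def reduce_embed(
    logmatrix, n_pcs: int = 50, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores plus a 2-D neighbor-graph (UMAP) embedding of the scores.

    ``logmatrix`` is genes x cells (a :class:`NormalizedMatrix` or plain
    array). Returns (pc_scores cells x n_pcs, coords_2d cells x 2);
    deterministic given ``seed``.
    """
    vals = logmatrix.values if isinstance(logmatrix, NormalizedMatrix) else np.asarray(logmatrix)
    x = vals.T  # cells as samples
    n_cells, n_genes = x.shape
    if n_pcs > min(n_cells, n_genes) - 1:
        raise ValueError("n_pcs exceeds min(n_cells, n_genes) - 1")
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("matrix is constant; nothing to embed")
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    import umap  # deferred: import compiles numba kernels

    emb = umap.UMAP(
        n_components=2,
        n_neighbors=min(15, n_cells - 1),
        random_state=seed,
        transform_seed=seed,
    )
    coords = emb.fit_transform(scores)
    return scores, np.asarray(coords, dtype=float)


def _snn_graph(pc_scores: np.ndarray, k_neighbors: int, prune: float = 1 / 15):
    """Shared-nearest-neighbor graph over all cell pairs.

    Edge weight is the Jaccard overlap of the two cells' k-NN sets (self
    included); weights below ``prune`` are dropped, the toolkit-standard
    sparsification.
    """
    import igraph as ig
    from scipy import sparse

    n = pc_scores.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(pc_scores)
    _, knn = nn.kneighbors(pc_scores)
    rows = np.repeat(np.arange(n), k_neighbors)
    a = sparse.csr_matrix(
        (np.ones(rows.size), (rows, knn.ravel())), shape=(n, n)
    )
    shared = (a @ a.T).tocoo()  # pairwise shared-neighbor counts
    jaccard = shared.data / (2 * k_neighbors - shared.data)
    keep = (shared.row < shared.col) & (jaccard >= prune)
    g = ig.Graph(
        n=n, edges=list(zip(shared.row[keep], shared.col[keep]))
    )
    g.es["weight"] = jaccard[keep]
    return g


def cluster_cells(
    pc_scores: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Seeded modularity (Leiden) community detection on the SNN graph."""
    import leidenalg

    pc_scores = np.asarray(pc_scores, dtype=float)
    n = pc_scores.shape[0]
    if n < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 cells")
    # canonical cell order: the partition is invariant to input permutation
    order = np.lexsort(pc_scores.T[::-1])
    g = _snn_graph(pc_scores[order], k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.empty(n, dtype=int)
    labels[order] = np.asarray(part.membership, dtype=int)
    return labels


def _group_columns(matrix: CountMatrix, group_a: str, group_b: str):
    cols_a = matrix.cells_of_type(group_a)
    cols_b = matrix.cells_of_type(group_b)
    if cols_a.size < 2 or cols_b.size < 2:
        raise ValueError("both groups need at least 2 cells")
    return cols_a, cols_b


def de_test_count_lrt(
    matrix: CountMatrix, group_a: str, group_b: str, alpha_select: float = 0.05
) -> np.ndarray:
    """Per-gene likelihood-ratio DE test using the selected count family.

    For each gene the family is chosen on the pooled counts of both groups;
    the null fits that family once (pooled), the alternative fits it per
    group, and the statistic is referred to chi-square with df equal to the
    family's free-parameter count (the selection step is treated as fixed).
    Genes with all-zero pooled counts are untestable (NaN).
    """
    cols_a, cols_b = _group_columns(matrix, group_a, group_b)
    pvals = np.full(matrix.n_genes, np.nan)
    for g in range(matrix.n_genes):
        xa = matrix.values[g, cols_a]
        xb = matrix.values[g, cols_b]
        pooled = np.concatenate([xa, xb])
        if not pooled.any():
            continue
        sel = models.select_model(pooled, alpha=alpha_select)
        fam = sel.chosen
        ll0 = sel.chosen_fit.loglik
        ll1 = models.fit_model(xa, fam).loglik + models.fit_model(xb, fam).loglik
        stat = max(0.0, 2.0 * (ll1 - ll0))
        pvals[g] = stats.chi2.sf(stat, df=N_PARAMS[fam])
    return pvals


def de_test_proportion(
    binary_matrix: CountMatrix, group_a: str, group_b: str
) -> np.ndarray:
    """Two-sample test of detection proportions on binarized counts.

    Pooled-variance z-test per gene; when any expected cell of the 2x2
    detection table is below 5 the exact (hypergeometric / Fisher) test is
    used instead. Genes detected in no cell of either group are NaN.
    """
    cols_a, cols_b = _group_columns(binary_matrix, group_a, group_b)
    xa = (binary_matrix.values[:, cols_a] > 0).sum(axis=1)
    xb = (binary_matrix.values[:, cols_b] > 0).sum(axis=1)
    na, nb = cols_a.size, cols_b.size
    pvals = np.full(binary_matrix.n_genes, np.nan)
    for g in range(binary_matrix.n_genes):
        ka, kb = int(xa[g]), int(xb[g])
        if ka + kb == 0:
            continue
        p1, p2 = ka / na, kb / nb
        if p1 == p2:
            pvals[g] = 1.0
            continue
        pool = (ka + kb) / (na + nb)
        expected = min(na * pool, nb * pool, na * (1 - pool), nb * (1 - pool))
        if expected < 5:
            table = [[ka, na - ka], [kb, nb - kb]]
            pvals[g] = stats.fisher_exact(table, alternative="two-sided")[1]
        else:
            z = (p1 - p2) / math.sqrt(pool * (1 - pool) * (1 / na + 1 / nb))
            pvals[g] = 2 * stats.norm.sf(abs(z))
    return pvals


def bh_adjust(pvalues, fdr_level: float = 0.05) -> DEResult:
    """Benjamini-Hochberg step-up over the testable (non-NaN) genes."""
    pvals = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(pvals)
    if np.any((pvals[ok] < 0) | (pvals[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.full(pvals.shape, np.nan)
    discovered = np.zeros(pvals.shape, dtype=bool)
    if ok.any():
        rej, adj, _, _ = multipletests(pvals[ok], alpha=fdr_level, method="fdr_bh")
        adjusted[ok] = adj
        discovered[ok] = adj <= fdr_level
    return DEResult(pvals, adjusted, discovered, fdr_level)
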