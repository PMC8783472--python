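"""Synthetic gene-by-cell count data with known cell types and DE truth.

The generator mirrors how marginal-model-based scRNA-seq simulators work:
each gene in each cell type carries a fitted count distribution (Poisson,
ZIP, NB, or ZINB; see :mod:`sczeros.models`), and synthetic cells are drawn
from those marginals, optionally coupled through a Gaussian copula over a
designated top-expressed gene subset to preserve gene-gene correlations.

For benchmarking, zero-inflation components are stripped before generation
(counts come from the Poisson/NB component only), and differential-expression
ground truth is defined as the ``n_de`` genes with the largest absolute
mean-parameter difference between two cell types; every other gene has its
mean parameter replaced by the two types' average in both types so that it is
exactly non-DE, while NB dispersions stay as fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .containers import CountMatrix
from .models import CountModelParams, Family
from ._seeds import derive_seed

__all__ = [
    "CellTypePopulationModel",
    "ReferencePanel",
    "DEGroundTruth",
    "sample_reference_panel",
    "fit_reference_panel",
    "strip_zero_inflation",
    "construct_de_truth",
    "generate_counts",
    "fit_copula",
]

PRESETS = ("umi-like", "smartseq2-like")


@dataclass
class CellTypePopulationModel:
    """One cell type: its size and one count model per gene."""

    cell_type: str
    n_cells: int
    gene_models: list[CountModelParams]

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def means(self) -> np.ndarray:
        return np.array([g.mean for g in self.gene_models])


@dataclass
class ReferencePanel:
    """A set of cell-type population models over a shared gene list.

    ``copula`` optionally holds, per cell type, a (gene-index array,
    correlation matrix) pair coupling a designated top-K gene subset.
    """

    gene_ids: list[str]
    populations: list[CellTypePopulationModel]
    copula: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    loglik: pd.DataFrame | None = None  # per-gene fit log-likelihoods, if fitted

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("panel needs at least one population")
        n = len(self.gene_ids)
        for pop in self.populations:
            if len(pop.gene_models) != n:
                raise ValueError(
                    f"population {pop.cell_type!r} has {len(pop.gene_models)} gene "
                    f"models for {n} genes"
                )
        names = [p.cell_type for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def population(self, cell_type: str) -> CellTypePopulationModel:
        for pop in self.populations:
            if pop.cell_type == cell_type:
                return pop
        raise KeyError(f"no population named {cell_type!r}")


@dataclass
class DEGroundTruth:
    """Per-gene DE labels with the generating mean parameters."""

    is_de: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    n_de: int

    def __post_init__(self) -> None:
        self.is_de = np.asarray(self.is_de, dtype=bool)
        if int(self.is_de.sum()) != self.n_de:
            raise ValueError("sum(is_de) must equal n_de")


def sample_reference_panel(
    n_genes: int,
    cell_type_specs,
    seed: int,
    preset: str = "umi-like",
    log_mean: float = 0.0,
    log_sd: float = 1.5,
    disp_log_mean: float = 0.0,
    disp_log_sd: float = 1.0,
    nb_fraction: float = 0.7,
) -> ReferencePanel:
    """Draw a synthetic reference panel emulating fitted real-data models.

    Per gene and cell type the mean is lognormal(``log_mean``, ``log_sd``)
    (a heavy-tailed gene-mean law, drawn independently per type so that
    genes differ between types). The family (NB with probability
    ``nb_fraction`` else Poisson) and the NB dispersion psi (lognormal with
    median exp(``disp_log_mean``)) are gene properties shared across types,
    as in real data where dispersion is largely technical. The
    ``"smartseq2-like"`` preset additionally gives about half of the genes a
    zero-inflation component with p ~ Uniform(0.05, 0.5); the default
    ``"umi-like"`` preset has none.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    specs = [(str(name), int(n)) for name, n in cell_type_specs]
    if not specs or any(n < 1 for _, n in specs):
        raise ValueError("cell_type_specs must be non-empty (name, n_cells>=1) pairs")
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    gene_rng = np.random.default_rng(derive_seed(seed, "panel", "genes"))
    psis = gene_rng.lognormal(disp_log_mean, disp_log_sd, n_genes)
    is_nb = gene_rng.random(n_genes) < nb_fraction
    if preset == "smartseq2-like":
        zi = np.where(
            gene_rng.random(n_genes) < 0.5, gene_rng.uniform(0.05, 0.5, n_genes), 0.0
        )
    else:
        zi = np.zeros(n_genes)
    populations = []
    for t, (name, n_cells) in enumerate(specs):
        rng = np.random.default_rng(derive_seed(seed, "panel", t))
        mus = rng.lognormal(log_mean, log_sd, n_genes)
        gene_models = []
        for g in range(n_genes):
            if is_nb[g]:
                fam = Family.ZINB if zi[g] > 0 else Family.NB
                gene_models.append(
                    CountModelParams(fam, mus[g], dispersion=psis[g], zero_inflation=zi[g])
                )
            else:
                fam = Family.ZIP if zi[g] > 0 else Family.POISSON
                gene_models.append(
                    CountModelParams(fam, mus[g], zero_inflation=zi[g])
                )
        populations.append(CellTypePopulationModel(name, n_cells, gene_models))
    return ReferencePanel(gene_ids, populations)


def fit_reference_panel(matrix: CountMatrix, alpha: float = 0.05) -> ReferencePanel:
    """Fit a per-gene, per-cell-type count model panel to labeled data.

    For every gene in every cell type the family is chosen by the two-stage
    likelihood-ratio chain (:func:`sczeros.models.select_model`) and the
    chosen family's maximum-likelihood fit is stored; the number of real
    cells per type is recorded as the population size.
    """
    if matrix.cell_types is None:
        raise ValueError("fit_reference_panel requires cell_types labels")
    populations = []
    ll_rows = {}
    for name in dict.fromkeys(matrix.cell_types):  # stable order of appearance
        cols = matrix.cells_of_type(name)
        if cols.size < 2:
            raise ValueError(f"cell type {name!r} has fewer than 2 cells")
        sub = matrix.values[:, cols]
        gene_models, lls = [], []
        for g in range(matrix.n_genes):
            sel = models.select_model(sub[g], alpha=alpha)
            fit = sel.chosen_fit
            gene_models.append(fit.params)
            lls.append(fit.loglik)
        populations.append(CellTypePopulationModel(name, cols.size, gene_models))
        ll_rows[name] = lls
    loglik = pd.DataFrame(ll_rows, index=matrix.gene_ids)
    return ReferencePanel(list(matrix.gene_ids), populations, loglik=loglik)


def strip_zero_inflation(panel: ReferencePanel) -> ReferencePanel:
    """Drop zero-inflation components: ZIP -> Poisson, ZINB -> NB.

    The non-inflated component's parameters are kept unchanged; idempotent.
    """
    populations = []
    for pop in panel.populations:
        stripped = []
        for m in pop.gene_models:
            if m.family == Family.ZIP:
                stripped.append(CountModelParams(Family.POISSON, m.mean))
            elif m.family == Family.ZINB:
                stripped.append(
                    CountModelParams(Family.NB, m.mean, dispersion=m.dispersion)
                )
            else:
                stripped.append(m)
        populations.append(CellTypePopulationModel(pop.cell_type, pop.n_cells, stripped))
    return ReferencePanel(
        list(panel.gene_ids), populations, copula=panel.copula, loglik=panel.loglik
    )


def construct_de_truth(
    panel: ReferencePanel, type_a: str, type_b: str, n_de: int = 1500
) -> tuple[ReferencePanel, DEGroundTruth]:
    """Label the top mean-difference genes DE; equalize the rest.

    Genes are ranked by |mean_a - mean_b| of their model mean parameters
    (ties broken by gene id, ascending); the top ``n_de`` keep their fitted
    models and are labeled DE. Every other gene gets the average of its two
    mean parameters in both cell types (families and NB dispersions kept),
    making it exactly non-DE.
    """
    pop_a = panel.population(type_a)
    pop_b = panel.population(type_b)
    n_genes = panel.n_genes
    if not 0 <= n_de <= n_genes:
        raise ValueError("n_de must lie in [0, n_genes]")
    mean_a = pop_a.means()
    mean_b = pop_b.means()
    diff = np.abs(mean_a - mean_b)
    order = sorted(range(n_genes), key=lambda g: (-diff[g], panel.gene_ids[g]))
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[order[:n_de]] = True

    avg = 0.5 * (mean_a + mean_b)
    new_pops = []
    for pop in panel.populations:
        if pop.cell_type not in (type_a, type_b):
            new_pops.append(pop)
            continue
        new_models = []
        for g, m in enumerate(pop.gene_models):
            if is_de[g]:
                new_models.append(m)
            else:
                new_models.append(replace(m, mean=float(avg[g])))
        new_pops.append(CellTypePopulationModel(pop.cell_type, pop.n_cells, new_models))
    new_panel = ReferencePanel(
        list(panel.gene_ids), new_pops, copula=panel.copula, loglik=panel.loglik
    )
    out_a = np.where(is_de, mean_a, avg)
    out_b = np.where(is_de, mean_b, avg)
    truth = DEGroundTruth(is_de, out_a, out_b, n_de=int(n_de))
    return new_panel, truth


def generate_counts(
    panel: ReferencePanel, seed: int, use_copula: bool = False
) -> CountMatrix:
    """Draw a gene-by-cell count matrix from a reference panel.

    Genes are sampled independently from their per-type marginals; with
    ``use_copula=True`` the designated top-K subset of each population is
    coupled through its latent Gaussian correlation (counts obtained by
    inverting each marginal CDF at the Gaussian uniforms).
    """
    blocks, cell_ids, cell_types = [], [], []
    for t, pop in enumerate(panel.populations):
        rng = np.random.default_rng(derive_seed(seed, "counts", t))
        block = np.empty((panel.n_genes, pop.n_cells), dtype=np.int64)
        for g, m in enumerate(pop.gene_models):
            block[g] = models.sample(m, pop.n_cells, rng)
        if use_copula:
            if panel.copula is None or pop.cell_type not in panel.copula:
                raise ValueError(
                    f"use_copula=True but no copula fitted for {pop.cell_type!r}"
                )
            idx, corr = panel.copula[pop.cell_type]
            z = rng.multivariate_normal(
                np.zeros(len(idx)), corr, size=pop.n_cells, method="cholesky"
            ).T
            u = stats.norm.cdf(z)
            for j, g in enumerate(idx):
                block[g] = ppf_counts(pop.gene_models[g], u[j])
        blocks.append(block)
        cell_ids.extend(f"{pop.cell_type}_{j}" for j in range(pop.n_cells))
        cell_types.extend([pop.cell_type] * pop.n_cells)
    return CountMatrix(
        np.concatenate(blocks, axis=1),
        gene_ids=list(panel.gene_ids),
        cell_ids=cell_ids,
        cell_types=cell_types,
    )


def ppf_counts(m: CountModelParams, u: np.ndarray) -> np.ndarray:
    return np.asarray(models.ppf(m, u), dtype=np.int64)


def _nearest_correlation(r: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix
    (eigenvalue clipping followed by diagonal rescaling)."""
    r = 0.5 * (r + r.T)
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, 1e-8, None)
    r = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def fit_copula(
    matrix: CountMatrix, panel: ReferencePanel, top_k: int = 100, seed: int = 0
) -> ReferencePanel:
    """Estimate a latent Gaussian correlation over the top-K mean genes.

    Uses the distributional transform: each count x is mapped to
    u = F(x-1) + V * (F(x) - F(x-1)) with V uniform (jitter over the CDF
    gap), then z = Phi^-1(u); the empirical correlation of z is projected to
    the nearest correlation matrix. Fitted per population on the labeled
    cells of that type.
    """
    if top_k < 1 or top_k > panel.n_genes:
        raise ValueError("top_k must lie in [1, n_genes]")
    if matrix.cell_types is None:
        raise ValueError("fit_copula requires cell_types labels")
    copula: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t, pop in enumerate(panel.populations):
        cols = matrix.cells_of_type(pop.cell_type)
        if cols.size < 3:
            raise ValueError(f"cell type {pop.cell_type!r} has fewer than 3 cells")
        rng = np.random.default_rng(derive_seed(seed, "copula", t))
        means = pop.means()
        idx = np.sort(np.argsort(-means, kind="stable")[:top_k])
        z = np.empty((top_k, cols.size))
        for j, g in enumerate(idx):
            m = pop.gene_models[g]
            x = matrix.values[g, cols]
            hi = np.asarray(models.cdf(m, x), dtype=float)
            lo = np.asarray(models.cdf(m, x - 1), dtype=float)
            u = lo + rng.random(cols.size) * (hi - lo)
            z[j] = stats.norm.ppf(np.clip(u, 1e-9, 1 - 1e-9))
        corr = _nearest_correlation(np.corrcoef(z)) if top_k > 1 else np.array([[1.0]])
        copula[pop.cell_type] = (idx, corr)
    return ReferencePanel(
        list(panel.gene_ids), list(panel.populations), copula=copula, loglik=panel.loglik
    )
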