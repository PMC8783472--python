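"""End-to-end benchmark: simulate, mask, analyze, score.

Drives the full pipeline over a grid of masking schemes x proportions x
input data types x analyses, producing a tidy table of metric records.
The unmasked baseline (proportion 0, scheme "none") is always included,
and every record is reproducible from the configuration plus the master
seed (per-condition streams are derived by hashing the condition tuple).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import downstream, masking, metrics, simulate
from .containers import CountMatrix
from .masking import MaskingSpec, Scheme
from ._seeds import derive_seed

__all__ = ["BenchmarkConfig", "run_benchmark", "summarize_ranks"]

RECORD_COLUMNS = [
    "preset",
    "scheme",
    "proportion",
    "input_type",
    "analysis",
    "metric",
    "value",
    "seed",
]

_ANALYSES = ("clustering", "dimension_reduction", "de")
_INPUT_TYPES = ("observed", "binarized")


@dataclass
class BenchmarkConfig:
    """Desk-scale benchmark configuration.

    The two-cell-type preset, masking grid, input data types, analyses,
    and replicate count; ``n_de`` defaults to one fifth of the genes.
    """

    preset: str = "umi-like"
    n_genes: int = 300
    cells_per_type: int = 150
    n_de: int | None = None
    schemes: tuple = tuple(Scheme)
    proportions: tuple = masking.DEFAULT_PROPORTIONS
    input_types: tuple = _INPUT_TYPES
    analyses: tuple = ("clustering", "de")
    n_seeds: int = 1
    master_seed: int = 0
    fdr_level: float = 0.05
    alpha_select: float = 0.05
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 0.8
    type_names: tuple = ("typeA", "typeB")

    def __post_init__(self) -> None:
        if self.n_de is None:
            self.n_de = max(1, self.n_genes // 5)
        for a in self.analyses:
            if a not in _ANALYSES:
                raise ValueError(f"unknown analysis {a!r}; expected one of {_ANALYSES}")
        for t in self.input_types:
            if t not in _INPUT_TYPES:
                raise ValueError(
                    f"unknown input type {t!r}; expected one of {_INPUT_TYPES}"
                )
        self.schemes = tuple(Scheme(s) for s in self.schemes)
        for p in self.proportions:
            if not 0 <= p < 1:
                raise ValueError("masking proportions must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        valid = set(cls.__dataclass_fields__)
        for key in d:
            if key not in valid:
                raise ValueError(f"unknown benchmark config key {key!r}")
        return cls(**d)


def _simulate_dataset(config: BenchmarkConfig, replicate: int):
    """One seeded two-type dataset with DE ground truth."""
    seed = derive_seed(config.master_seed, "data", replicate)
    panel = simulate.sample_reference_panel(
        config.n_genes,
        [(config.type_names[0], config.cells_per_type),
         (config.type_names[1], config.cells_per_type)],
        seed=seed,
        preset=config.preset,
    )
    panel = simulate.strip_zero_inflation(panel)
    panel, truth = simulate.construct_de_truth(
        panel, config.type_names[0], config.type_names[1], n_de=config.n_de
    )
    counts = simulate.generate_counts(panel, seed=derive_seed(seed, "gen"))
    return counts, truth


def _cluster_and_embed(config, counts: CountMatrix, seed: int, want_embedding: bool):
    norm = downstream.normalize_log(counts)
    hvg = downstream.top_variable_genes(norm, n_top=2000)
    vals = norm.values[hvg]
    n_pcs = min(config.n_pcs, min(vals.shape[0], len(norm.cell_ids)) - 1)
    scores, coords = None, None
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(vals.T)
    if want_embedding:
        _, coords = downstream.reduce_embed(vals, n_pcs=n_pcs, seed=seed)
    return norm, scores, coords


def _analyze(config: BenchmarkConfig, counts: CountMatrix, truth, input_type: str,
             analyses, seed: int):
    """Metric records for one (masked) dataset and one input type."""
    data = downstream.binarize(counts) if input_type == "binarized" else counts
    records = []
    need_cluster = "clustering" in analyses
    need_dr = "dimension_reduction" in analyses
    if need_cluster or need_dr:
        norm, scores, coords = _cluster_and_embed(config, data, seed, need_dr)
        true_labels = np.asarray(norm.cell_types)
        if need_cluster:
            labels = downstream.cluster_cells(
                scores,
                k_neighbors=min(config.k_neighbors, scores.shape[0] - 1),
                resolution=config.resolution,
                seed=seed,
            )
            ari = metrics.adjusted_rand_index(true_labels, labels)
            records.append(("clustering", "ARI", ari))
        if need_dr:
            sil = metrics.average_silhouette(coords, true_labels)
            records.append(("dimension_reduction", "silhouette", sil))
    if "de" in analyses:
        if input_type == "binarized":
            pvals = downstream.de_test_proportion(data, *config.type_names)
        else:
            pvals = downstream.de_test_count_lrt(
                data, *config.type_names, alpha_select=config.alpha_select
            )
        res = downstream.bh_adjust(pvals, fdr_level=config.fdr_level)
        precision, recall, f1 = metrics.precision_recall_f1(res.discovered, truth.is_de)
        records.extend(
            [("de", "precision", precision), ("de", "recall", recall), ("de", "F1", f1)]
        )
    return records


def run_benchmark(config: BenchmarkConfig | dict) -> pd.DataFrame:
    """Run the full grid and return a tidy metric table.

    Rows: one per (scheme, proportion, input type, analysis, metric,
    replicate). The unmasked baseline appears as scheme "none" at
    proportion 0.
    """
    if isinstance(config, dict):
        config = BenchmarkConfig.from_dict(config)
    rows = []
    for rep in range(config.n_seeds):
        counts, truth = _simulate_dataset(config, rep)
        conditions = [("none", 0.0, counts)]
        for scheme in config.schemes:
            for prop in config.proportions:
                if prop == 0:
                    continue
                spec = MaskingSpec(
                    scheme,
                    prop,
                    derive_seed(config.master_seed, "mask", rep, scheme.value, prop),
                )
                conditions.append(
                    (scheme.value, prop, masking.mask_counts(counts, spec).masked)
                )
        for scheme_name, prop, data in conditions:
            for input_type in config.input_types:
                seed = derive_seed(
                    config.master_seed, "analyze", rep, scheme_name, prop, input_type
                )
                for analysis, metric_name, value in _analyze(
                    config, data, truth, input_type, config.analyses, seed
                ):
                    rows.append(
                        {
                            "preset": config.preset,
                            "scheme": scheme_name,
                            "proportion": prop,
                            "input_type": input_type,
                            "analysis": analysis,
                            "metric": metric_name,
                            "value": value,
                            "seed": rep,
                        }
                    )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize_ranks(
    table: pd.DataFrame,
    metric: str,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Rank input types per condition and aggregate with condition weights.

    For each (preset, scheme, proportion, seed) condition the input types
    are ranked on ``metric`` (rank 1 = best, ties averaged), then ranks are
    averaged across conditions with the given per-preset weights (default:
    equal).
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows with metric {metric!r}")
    pivot = sub.pivot_table(
        index=["preset", "scheme", "proportion", "seed"],
        columns="input_type",
        values="value",
    )
    ranks = pivot.apply(lambda row: metrics.rank_with_ties(row.values), axis=1,
                        result_type="expand")
    ranks.columns = pivot.columns
    presets = ranks.index.get_level_values("preset")
    w = np.array([1.0 if weights is None else weights.get(p, 1.0) for p in presets])
    agg = metrics.weighted_rank_average(ranks.values, w)
    return pd.DataFrame({"input_type": list(pivot.columns), "mean_rank": agg})
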