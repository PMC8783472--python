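"""Readers and writers for count matrices, panels, and configuration.

Matrix Market (coordinate, 1-based, genes as rows) with TSV sidecars
(``genes.tsv``, ``barcodes.tsv``, optional ``cell_types.tsv``) under one
directory, or dense CSV (gene rows, cell columns, ids in the header/index).
All internal indexing is 0-based; the 1-based convention is confined here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy import sparse

from .containers import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_panel_csv",
    "write_panel_csv",
    "load_config",
]

MTX_NAME = "matrix.mtx"
GENES_NAME = "genes.tsv"
CELLS_NAME = "barcodes.tsv"
TYPES_NAME = "cell_types.tsv"


def _read_ids(path: Path) -> list[str]:
    return [line.rstrip("\n") for line in path.read_text().splitlines() if line.strip()]


def read_count_matrix(
    path, format: str = "auto", allow_real: bool = False
) -> CountMatrix:
    """Read a count matrix from an MTX-triplet directory or a dense CSV.

    ``allow_real=True`` accepts real-valued (e.g., externally imputed)
    matrices; values are then rounded to the nearest integer for the
    integer container after validation is relaxed.
    """
    path = Path(path)
    if format == "auto":
        format = "mtx" if path.is_dir() else "csv"
    if format == "mtx":
        mtx_path = path / MTX_NAME
        for p in (mtx_path, path / GENES_NAME, path / CELLS_NAME):
            if not p.exists():
                raise FileNotFoundError(f"missing {p}")
        mat = sio.mmread(mtx_path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        gene_ids = _read_ids(path / GENES_NAME)
        cell_ids = _read_ids(path / CELLS_NAME)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecars "
                f"{path / GENES_NAME} ({len(gene_ids)} genes) and "
                f"{path / CELLS_NAME} ({len(cell_ids)} cells)"
            )
        types_path = path / TYPES_NAME
        cell_types = _read_ids(types_path) if types_path.exists() else None
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        cell_types = None
    else:
        raise ValueError(f"unknown format {format!r}")
    if allow_real:
        values = np.rint(np.clip(values, 0, None))
    elif not np.all(values == np.floor(values)) or np.any(values < 0):
        raise ValueError(f"{path}: observed counts must be non-negative integers")
    matrix = CountMatrix(values.astype(np.int64), gene_ids, cell_ids, cell_types)
    logger.info("read %d genes x %d cells from %s", matrix.n_genes, matrix.n_cells, path)
    return matrix


def write_count_matrix(matrix: CountMatrix, path, format: str = "mtx") -> None:
    """Write to an MTX-triplet directory or a dense CSV file."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        coo = sparse.coo_matrix(matrix.values)
        sio.mmwrite(path / MTX_NAME, coo, field="integer")
        (path / GENES_NAME).write_text("\n".join(matrix.gene_ids) + "\n")
        (path / CELLS_NAME).write_text("\n".join(matrix.cell_ids) + "\n")
        if matrix.cell_types is not None:
            (path / TYPES_NAME).write_text("\n".join(matrix.cell_types) + "\n")
    elif format == "csv":
        df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids)
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_panel_csv(panel, path) -> None:
    """Serialize a reference panel as one row per gene per cell type."""
    rows = []
    for pop in panel.populations:
        for gid, m in zip(panel.gene_ids, pop.gene_models):
            rows.append(
                {
                    "cell_type": pop.cell_type,
                    "n_cells": pop.n_cells,
                    "gene_id": gid,
                    "family": m.family.value,
                    "mean": m.mean,
                    "dispersion": m.dispersion,
                    "zero_inflation": m.zero_inflation,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_panel_csv(path):
    """Load a reference panel written by :func:`write_panel_csv`."""
    from .models import CountModelParams, Family
    from .simulate import CellTypePopulationModel, ReferencePanel

    df = pd.read_csv(path, float_precision="round_trip")
    gene_ids = list(dict.fromkeys(df["gene_id"].astype(str)))
    populations = []
    for name, sub in df.groupby("cell_type", sort=False):
        sub = sub.assign(gene_id=sub["gene_id"].astype(str)).set_index("gene_id")
        sub = sub.loc[gene_ids]
        gene_models = [
            CountModelParams(
                Family(row["family"]),
                float(row["mean"]),
                dispersion=float(row["dispersion"]),
                zero_inflation=float(row["zero_inflation"]),
            )
            for _, row in sub.iterrows()
        ]
        populations.append(
            CellTypePopulationModel(str(name), int(sub["n_cells"].iloc[0]), gene_models)
        )
    return ReferencePanel(gene_ids, populations)


def load_config(path) -> dict:
    """Load a YAML benchmark/pipeline config; unknown keys raise later at
    construction, missing file raises here with the path named."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
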