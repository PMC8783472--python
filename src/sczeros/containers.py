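"""Gene-by-cell count matrix container, the currency of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CountMatrix:
    """A genes x cells matrix of non-negative integer counts.

    Parameters
    ----------
    values
        2-D integer array, genes in rows, cells in columns.
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Cell identifiers (barcodes), one per column.
    cell_types
        Optional cell-type label per cell.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    cell_types: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.floor(self.values)):
                raise ValueError("count matrix entries must be integers")
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            raise ValueError("count matrix entries must be non-negative")
        n_genes, n_cells = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene{i}" for i in range(n_genes)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{j}" for j in range(n_cells)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match number of columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if self.cell_types is not None:
            self.cell_types = [str(t) for t in self.cell_types]
            if len(self.cell_types) != n_cells:
                raise ValueError("cell_types length does not match number of cells")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def nnz(self) -> int:
        """Number of non-zero entries."""
        return int(np.count_nonzero(self.values))

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            cell_types=None if self.cell_types is None else list(self.cell_types),
        )

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        """Column indices of cells with the given type label."""
        if self.cell_types is None:
            raise ValueError("count matrix has no cell_types labels")
        return np.flatnonzero(np.asarray(self.cell_types) == cell_type)
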