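"""Masking schemes that inject non-biological zeros into a count matrix.

A masking scheme converts a target proportion ``q`` of the non-zero entries
of a gene-by-cell count matrix to zeros, emulating technical/sampling zeros
on top of data whose remaining zeros are biological. Five schemes are
provided, crossing two axes:

* random vs quantile: random schemes pick entries uniformly (masking is
  independent of the count value); quantile schemes mask the smallest
  non-zero counts first (low expression is lost first, the empirically more
  realistic mechanism).
* matrix-wide vs per-gene: matrix-wide schemes apply one rule to all
  entries; per-gene schemes control each gene's masked fraction, either the
  same ``q`` for every gene or gene-specific proportions that decrease with
  mean expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import product

import numpy as np

from .containers import CountMatrix

__all__ = [
    "Scheme",
    "MaskingSpec",
    "MaskingResult",
    "mask_counts",
    "per_gene_specific_proportions",
    "masking_grid",
    "DEFAULT_PROPORTIONS",
]

DEFAULT_PROPORTIONS = tuple(round(0.1 * i, 1) for i in range(1, 10))


class Scheme(str, Enum):
    RANDOM_ALL = "random_all"
    QUANTILE_ALL = "quantile_all"
    RANDOM_PER_GENE_SPECIFIC = "random_per_gene_specific"
    QUANTILE_PER_GENE_SAME = "quantile_per_gene_same"
    QUANTILE_PER_GENE_SPECIFIC = "quantile_per_gene_specific"


@dataclass(frozen=True)
class MaskingSpec:
    scheme: Scheme
    proportion: float
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        if not 0 <= self.proportion < 1:
            raise ValueError("masking proportion must lie in [0, 1)")


@dataclass
class MaskingResult:
    masked: CountMatrix
    mask: np.ndarray  # boolean, True where an entry was set to zero
    achieved_overall: float
    achieved_per_gene: np.ndarray


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _apportion(raw: np.ndarray, total: int, capacity: np.ndarray) -> np.ndarray:
    """Integer per-gene masked counts summing exactly to ``total``.

    Largest-remainder apportionment of the real-valued targets ``raw``
    (bounded above by ``capacity``): each gene receives floor(raw_g) plus at
    most one extra unit, extras going to the largest fractional parts.
    """
    base = np.minimum(np.floor(raw).astype(int), capacity)
    frac = raw - np.floor(raw)
    deficit = total - int(base.sum())
    if deficit > 0:
        room = capacity - base
        # deterministic tie-break: larger fraction first, then gene order
        order = np.lexsort((np.arange(raw.size), -frac))
        for g in order:
            if deficit == 0:
                break
            if room[g] > 0:
                base[g] += 1
                deficit -= 1
    elif deficit < 0:
        order = np.lexsort((np.arange(raw.size), frac))
        for g in order:
            if deficit == 0:
                break
            if base[g] > 0:
                base[g] -= 1
                deficit += 1
    return base


def _smallest_positions(values: np.ndarray, positions: np.ndarray, m: int, rng) -> np.ndarray:
    """Positions of the m smallest values; ties at the cut broken at random."""
    jitter = rng.random(values.size)
    order = np.lexsort((jitter, values))
    return positions[order[:m]]


def mask_counts(matrix: CountMatrix, spec: MaskingSpec) -> MaskingResult:
    """Apply one masking scheme at one proportion; the input is untouched.

    The total number of masked entries is exactly round-half-up(q * nnz)
    (at least 1 when q > 0); per-gene schemes apportion that total across
    genes by largest remainder, so each gene's masked count is floor or ceil
    of its real-valued target.
    """
    values = matrix.values
    nnz = matrix.nnz
    if nnz == 0:
        raise ValueError("matrix has no non-zero entries to mask")
    q = spec.proportion
    rng = np.random.default_rng(spec.seed)
    total = _round_half_up(q * nnz)
    if total == 0 and q > 0:
        total = 1

    mask = np.zeros(values.shape, dtype=bool)
    flat = values.ravel()
    if spec.scheme in (Scheme.RANDOM_ALL, Scheme.QUANTILE_ALL):
        pos = np.flatnonzero(flat)
        if spec.scheme == Scheme.RANDOM_ALL:
            chosen = rng.choice(pos, size=total, replace=False)
        else:
            chosen = _smallest_positions(flat[pos], pos, total, rng)
        mask.ravel()[chosen] = True
    else:
        nnz_g = np.count_nonzero(values, axis=1)
        if spec.scheme == Scheme.QUANTILE_PER_GENE_SAME:
            q_g = np.full(matrix.n_genes, q)
        else:
            q_g = per_gene_specific_proportions(matrix, q, spec.seed)
        per_gene = _apportion(q_g * nnz_g, total, nnz_g)
        random_within = spec.scheme == Scheme.RANDOM_PER_GENE_SPECIFIC
        for g in range(matrix.n_genes):
            m = per_gene[g]
            if m == 0:
                continue
            cols = np.flatnonzero(values[g])
            if random_within:
                chosen = rng.choice(cols, size=m, replace=False)
            else:
                chosen = _smallest_positions(values[g, cols], cols, m, rng)
            mask[g, chosen] = True

    masked = matrix.copy()
    masked.values[mask] = 0
    nnz_g = np.count_nonzero(values, axis=1)
    masked_g = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_gene_prop = np.where(nnz_g > 0, masked_g / np.maximum(nnz_g, 1), 0.0)
    return MaskingResult(
        masked=masked,
        mask=mask,
        achieved_overall=float(mask.sum() / nnz),
        achieved_per_gene=per_gene_prop,
    )


def per_gene_specific_proportions(
    matrix: CountMatrix, q: float, seed: int | None = None
) -> np.ndarray:
    """Gene-specific masking proportions decreasing in mean expression.

    q_g proportional to exp(-mu_g / mu_bar) with mu_g the mean of the gene's
    non-zero counts and mu_bar the mean over all non-zero entries, clipped to
    [0, 0.99], with the overall scale calibrated by bisection so that the
    apportioned total matches round(q * nnz). Deterministic; ``seed`` is
    accepted for interface symmetry.
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    values = matrix.values
    nnz_g = np.count_nonzero(values, axis=1).astype(float)
    if q == 0:
        return np.zeros(matrix.n_genes)
    sums = values.sum(axis=1).astype(float)
    mu_g = np.where(nnz_g > 0, sums / np.maximum(nnz_g, 1.0), 0.0)
    mu_bar = values.sum() / max(np.count_nonzero(values), 1)
    shape = np.where(nnz_g > 0, np.exp(-mu_g / mu_bar), 0.0)
    target = _round_half_up(q * nnz_g.sum())

    def masked_total(c: float) -> int:
        q_g = np.clip(c * shape, 0.0, 0.99)
        return int(np.floor(q_g * nnz_g + 0.5).sum())  # round half up per gene

    lo, hi = 0.0, 1.0
    while masked_total(hi) < target and hi < 1e9:
        hi *= 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if masked_total(mid) >= target:
            hi = mid
        else:
            lo = mid
    return np.clip(hi * shape, 0.0, 0.99)


def masking_grid(
    matrix: CountMatrix,
    proportions=DEFAULT_PROPORTIONS,
    schemes=tuple(Scheme),
    seed: int = 0,
) -> list[tuple[MaskingSpec, MaskingResult]]:
    """All scheme x proportion combinations with independent seeded streams.

    The default grid (nine proportions 0.1..0.9 times five schemes) yields
    45 masked datasets per input matrix.
    """
    proportions = list(proportions)
    if not proportions:
        raise ValueError("proportions must be non-empty")
    results = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(schemes) * len(proportions))
    for child, (scheme, prop) in zip(children, product(schemes, proportions)):
        child_seed = int(child.generate_state(1)[0]) % (2**31)
        spec = MaskingSpec(Scheme(scheme), prop, child_seed)
        results.append((spec, mask_counts(matrix, spec)))
    return results
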