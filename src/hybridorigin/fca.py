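"""Correspondence analysis of the individuals x allele-count matrix.

Genotypes are coded as allele counts (0/1/2 per allele column, grouped by
locus; a missing genotype contributes zeros for that locus), and standard
chi-square-metric correspondence analysis is applied: standardized
residuals of the count matrix are decomposed by SVD and individuals are
placed in row principal coordinates. The fraction of total inertia per
axis summarizes how much genotypic variation each axis captures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import svd

from .datatypes import GenotypeTable


@dataclass
class FcaResult:
    coordinates: pd.DataFrame  # individuals x axes (row principal coordinates)
    inertia_fraction: np.ndarray  # per axis, non-increasing, sums to <= 1
    total_inertia: float
    n_axes: int
    column_labels: list[str]


def genotype_indicator_matrix(
    table: GenotypeTable,
) -> tuple[np.ndarray, list[str]]:
    """Individuals x alleles count matrix (entries 0, 1 or 2).

    Columns are labeled ``locus:allele``; a missing genotype leaves that
    locus's columns at zero for the individual.
    """
    if table.n_individuals < 2:
        raise ValueError("indicator matrix needs at least 2 individuals")
    cols = []
    blocks = []
    for l, locus in enumerate(table.loci):
        alleles = table.alleles_at(l)
        if len(alleles) == 0:
            continue
        block = np.zeros((table.n_individuals, len(alleles)))
        g = table.genotypes[:, l, :]
        present = g[:, 0] != 0
        idx = np.searchsorted(alleles, g[present])
        rows = np.flatnonzero(present)
        for c in range(2):
            np.add.at(block, (rows, idx[:, c]), 1.0)
        blocks.append(block)
        cols.extend(f"{locus}:{a}" for a in alleles)
    if not blocks:
        raise ValueError("table has no genotyped loci")
    mat = np.concatenate(blocks, axis=1)
    if not any(len(np.unique(table.alleles_at(l))) > 1 for l in range(table.n_loci)):
        raise ValueError("no polymorphic locus: ordination is degenerate")
    return mat, cols


def fca(
    matrix: np.ndarray,
    n_axes: int = 2,
    row_labels: list[str] | None = None,
    column_labels: list[str] | None = None,
) -> FcaResult:
    """Correspondence analysis of a non-negative matrix.

    Rows with zero mass (e.g. individuals missing at every locus) are
    placed at the origin. Axis signs are arbitrary.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or (X < 0).any():
        raise ValueError("input must be a 2-D non-negative matrix")
    total = X.sum()
    if total <= 0:
        raise ValueError("matrix total is zero; correspondence analysis undefined")
    max_axes = min(X.shape) - 1
    if n_axes > max_axes:
        raise ValueError(f"n_axes = {n_axes} exceeds min(rows, cols) - 1 = {max_axes}")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_r = r > 0
    keep_c = c > 0
    Pk = P[np.ix_(keep_r, keep_c)]
    rk = r[keep_r]
    ck = c[keep_c]
    S = (Pk - np.outer(rk, ck)) / np.sqrt(np.outer(rk, ck))
    U, sv, Vt = svd(S, full_matrices=False)
    # drop numerically-null dimensions
    sv = np.where(sv < 1e-12, 0.0, sv)
    total_inertia = float((sv**2).sum())
    coords_k = (U * sv) / np.sqrt(rk)[:, None]
    coords = np.zeros((X.shape[0], n_axes))
    coords[keep_r] = coords_k[:, :n_axes]
    inertia = sv[:n_axes] ** 2 / total_inertia if total_inertia > 0 else np.zeros(n_axes)
    if row_labels is None:
        row_labels = [f"row{i}" for i in range(X.shape[0])]
    frame = pd.DataFrame(
        coords,
        index=row_labels,
        columns=[f"axis{j + 1}" for j in range(n_axes)],
    )
    return FcaResult(
        coordinates=frame,
        inertia_fraction=inertia,
        total_inertia=total_inertia,
        n_axes=n_axes,
        column_labels=column_labels or [],
    )


def fca_of_table(table: GenotypeTable, n_axes: int = 2) -> FcaResult:
    """Correspondence analysis of a genotype table's allele-count coding."""
    mat, cols = genotype_indicator_matrix(table)
    return fca(mat, n_axes=n_axes, row_labels=table.individuals, column_labels=cols)
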