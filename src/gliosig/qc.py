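"""Cell and gene inclusion filters plus the normalisations used downstream.

The single-cell criteria: a gene is kept iff detected in more than
``min_cells_per_gene`` cells; a cell is kept iff it expresses more than
``min_genes_per_cell`` genes, its detected-gene count lies inside
``gene_count_range``, and its mitochondrial count share is below
``max_mito_percent`` (10% human, 20% mouse).  The gene filter is applied
first, then the cell filters on the gene-filtered matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io import LOG_NORMALIZED, RAW_COUNTS, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 300
    gene_count_range: tuple[float, float] = (200.0, 5000.0)
    max_mito_percent: float = 10.0

    @classmethod
    def for_species(cls, species: str) -> "QCThresholds":
        return cls(max_mito_percent=20.0 if species == "mouse" else 10.0)

    def validate(self) -> None:
        lo, hi = self.gene_count_range
        if lo > hi:
            raise ParameterError("gene_count_range lower bound exceeds upper bound")
        if not 0 <= self.max_mito_percent <= 100:
            raise ParameterError("max_mito_percent must lie in [0, 100]")


@dataclass
class QCReport:
    n_genes_in: int = 0
    n_genes_out: int = 0
    n_cells_in: int = 0
    n_cells_out: int = 0
    removed_by: dict[str, int] = field(default_factory=dict)


def apply_qc(counts: ExpressionMatrix, thresholds: QCThresholds, mito_gene_flags) -> tuple[ExpressionMatrix, QCReport]:
    """Filter genes then cells per the inclusion criteria; labels keep order."""
    if counts.mode != RAW_COUNTS:
        raise ParameterError("apply_qc expects raw counts")
    thresholds.validate()
    mito = np.asarray(mito_gene_flags, dtype=bool)
    if mito.shape != (counts.n_genes,):
        raise ParameterError("mito_gene_flags must align with gene_ids")

    detected = counts.values > 0
    gene_keep = detected.sum(axis=1) > thresholds.min_cells_per_gene
    sub = counts.subset(gene_mask=gene_keep)
    mito_sub = mito[gene_keep]

    det = sub.values > 0
    genes_per_cell = det.sum(axis=0)
    total = sub.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * sub.values[mito_sub, :].sum(axis=0) / total, 0.0)

    lo, hi = thresholds.gene_count_range
    pass_min = genes_per_cell > thresholds.min_genes_per_cell
    pass_range = (genes_per_cell >= lo) & (genes_per_cell <= hi)
    pass_mito = mito_pct < thresholds.max_mito_percent
    cell_keep = pass_min & pass_range & pass_mito

    report = QCReport(
        n_genes_in=counts.n_genes,
        n_genes_out=int(gene_keep.sum()),
        n_cells_in=counts.n_obs,
        n_cells_out=int(cell_keep.sum()),
        removed_by={
            "gene_min_cells": int((~gene_keep).sum()),
            "cell_min_genes": int((~pass_min).sum()),
            "cell_gene_count_range": int((~pass_range).sum()),
            "cell_mito_percent": int((~pass_mito).sum()),
        },
    )
    if report.n_cells_out == 0:
        warnings.warn("QC removed every cell; downstream stages will see an empty matrix")
    out = sub.subset(obs_mask=cell_keep)
    return out, report


def lognormalize(counts: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to a common library size then log1p-transform."""
    if counts.mode != RAW_COUNTS:
        raise ParameterError("lognormalize expects raw counts")
    total = counts.values.sum(axis=0)
    if np.any(total <= 0):
        raise ParameterError("cells with zero total counts present; run apply_qc first")
    values = np.log1p(counts.values / total[None, :] * target_sum)
    return ExpressionMatrix(values, counts.gene_ids, counts.obs_ids, mode=LOG_NORMALIZED)


def normalize_bulk(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size factors then log2(x + 1).

    The geometric-mean reference is taken over genes with all-positive counts;
    if none exists, library-size factors (scaled to mean 1) are used instead.
    """
    if counts.mode != RAW_COUNTS:
        raise ParameterError("normalize_bulk expects raw counts")
    vals = counts.values
    allpos = np.all(vals > 0, axis=1)
    if allpos.sum() == 0:
        log.warning("no gene with all-positive counts; falling back to library-size factors")
        lib = vals.sum(axis=0)
        factors = lib / lib.mean()
    else:
        ref = np.exp(np.mean(np.log(vals[allpos, :]), axis=1))
        ratios = vals[allpos, :] / ref[:, None]
        factors = np.median(ratios, axis=0)
    normalized = np.log2(vals / factors[None, :] + 1.0)
    return ExpressionMatrix(normalized, counts.gene_ids, counts.obs_ids, mode=LOG_NORMALIZED)
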