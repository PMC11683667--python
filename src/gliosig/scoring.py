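"""Gene-set scoring of cells and samples.

Three scorers: the binned-control module score for single cells (mean set-gene
expression minus the mean of expression-matched control genes), single-sample
GSEA (rank-based integrated difference between in-set and out-of-set
cumulative distributions, weight exponent ``alpha``), and pseudobulk
aggregation feeding the sample-level scorers.  The iterative refinement loop
prunes set genes whose expression correlates below ``r_min`` with the current
enrichment score, re-scoring every pass until a fixed point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import LOG_NORMALIZED, RAW_COUNTS, ExpressionMatrix, GeneSet, GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Observations × gene-set scores with method provenance."""

    scores: pd.DataFrame
    method: str = ""
    params: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def module_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell binned-control module score.

    Genes are ranked by mean expression and cut into ``n_bins``
    equal-frequency bins; each set gene draws ``n_ctrl`` control genes from
    its own bin (with replacement when the bin is smaller).  The score is the
    mean set-gene expression minus the mean expression of all sampled
    controls, per cell.
    """
    if expr.mode != LOG_NORMALIZED:
        raise ParameterError("module_score expects log-normalized expression")
    if n_bins > expr.n_genes:
        raise ParameterError("n_bins exceeds the number of genes")
    present = [g for g in gene_set.genes if g in set(expr.gene_ids)]
    if not present:
        raise ParameterError(f"no gene of set {gene_set.name!r} present in matrix: {gene_set.genes[:5]}...")

    rng = np.random.default_rng(seed)
    gene_mean = expr.values.mean(axis=1)
    order = np.argsort(gene_mean, kind="stable")
    bin_of = np.empty(expr.n_genes, int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    bins = [np.flatnonzero(bin_of == b) for b in range(n_bins)]

    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    set_ix = np.array([gene_pos[g] for g in present])
    ctrl_ix = []
    for gi in set_ix:
        pool = bins[bin_of[gi]]
        ctrl_ix.append(rng.choice(pool, size=n_ctrl, replace=n_ctrl > pool.size))
    ctrl_ix = np.concatenate(ctrl_ix)
    score = expr.values[set_ix, :].mean(axis=0) - expr.values[ctrl_ix, :].mean(axis=0)
    return pd.Series(score, index=expr.obs_ids, name=gene_set.name)


def _ssgsea_order(values: np.ndarray, genes: list[str]) -> np.ndarray:
    """Descending-value order with deterministic ties (value desc, symbol asc)."""
    idx = np.arange(len(genes))
    return np.array(sorted(idx, key=lambda i: (-values[i], genes[i])))


def ssgsea_score(values, genes: list[str], gene_set: GeneSet, alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment score for one observation.

    Genes are ranked descending by value; the in-set cumulative distribution
    weights gene at position i by its normalised rank value ``((N-i)/N)^alpha``
    (uniform at ``alpha = 0``), the out-of-set cumulative is uniform, and the
    score integrates their difference over all ranks.
    """
    values = np.asarray(values, float)
    if values.shape != (len(genes),):
        raise ParameterError("values and genes must align")
    members = set(gene_set.genes)
    in_set = np.array([g in members for g in genes])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ParameterError(f"no gene of set {gene_set.name!r} present")
    n = len(genes)
    if n_in == n:
        raise ParameterError("gene set covers every gene; out-of-set distribution undefined")

    order = _ssgsea_order(values, genes)
    in_ordered = in_set[order]
    rank_value = (n - np.arange(n)) / n  # 1, (n-1)/n, ..., 1/n
    weights = np.abs(rank_value) ** alpha
    w_in = np.where(in_ordered, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_ordered) / (n - n_in)
    return float((p_in - p_out).sum())


def ssgsea_scores(expr: ExpressionMatrix, gene_set: GeneSet, alpha: float = 0.25) -> pd.Series:
    """ssGSEA score of every observation (column) in the matrix."""
    out = [ssgsea_score(expr.values[:, j], expr.gene_ids, gene_set, alpha=alpha) for j in range(expr.n_obs)]
    return pd.Series(out, index=expr.obs_ids, name=gene_set.name)


def pseudobulk(counts: ExpressionMatrix, sample_of_cell: pd.Series, cell_mask=None) -> ExpressionMatrix:
    """Sum raw counts over masked cells within each sample.

    Samples left with zero masked cells are dropped with a warning; if every
    sample is empty the operation errors.
    """
    if counts.mode != RAW_COUNTS:
        raise ParameterError("pseudobulk expects raw counts")
    mask = np.ones(counts.n_obs, bool) if cell_mask is None else np.asarray(cell_mask, bool)
    samples = pd.Series(sample_of_cell).reindex(counts.obs_ids)
    cols = []
    names = []
    for s in samples.dropna().unique():
        sel = (samples == s).to_numpy() & mask
        if sel.sum() == 0:
            warnings.warn(f"sample {s} has no cells after masking; dropped from pseudobulk")
            continue
        cols.append(counts.values[:, sel].sum(axis=1))
        names.append(str(s))
    if not cols:
        raise ParameterError("mask removes every cell of every sample; pseudobulk is empty")
    return ExpressionMatrix(np.column_stack(cols), counts.gene_ids, names, mode=RAW_COUNTS)


@dataclass
class RefinementTrace:
    """Per-iteration record of the pruning loop."""

    rows: pd.DataFrame  # columns: iteration, gene, r, removed

    @property
    def n_iterations(self) -> int:
        return int(self.rows["iteration"].max()) if len(self.rows) else 0


def iterative_ssgsea(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    r_min: float = 0.5,
    min_set_size: int = 10,
    max_iter: int = 20,
    alpha: float = 0.25,
) -> tuple[GeneSet, ScoreTable, RefinementTrace]:
    """Iteratively prune set genes with correlation to the score below ``r_min``.

    Each pass recomputes per-sample ssGSEA scores on the current set, then the
    Pearson correlation of each retained gene's expression (across samples)
    with the score vector, and removes genes below the threshold.  The loop
    stops at a fixed point, when a removal would shrink the set below
    ``min_set_size`` (the current set is kept), or after ``max_iter`` passes.
    """
    if expr.mode != LOG_NORMALIZED:
        raise ParameterError("iterative_ssgsea expects log-normalized expression")
    if expr.n_obs < 3:
        raise ParameterError("need at least 3 samples")
    present = [g for g in gene_set.genes if g in set(expr.gene_ids)]
    if len(present) < min_set_size:
        raise ParameterError(
            f"only {len(present)} set genes present (< min_set_size={min_set_size})"
        )
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    current = list(present)
    trace_rows = []
    scores = None
    for it in range(1, max_iter + 1):
        cur_set = GeneSet(gene_set.name, current, gene_set.description)
        scores = ssgsea_scores(expr, cur_set, alpha=alpha)
        sv = scores.to_numpy()
        rs = {}
        for g in current:
            gv = expr.values[gene_pos[g], :]
            if np.std(gv) == 0 or np.std(sv) == 0:
                rs[g] = 0.0
            else:
                rs[g] = float(np.corrcoef(gv, sv)[0, 1])
        to_remove = [g for g in current if rs[g] < r_min]
        for g in current:
            trace_rows.append({"iteration": it, "gene": g, "r": rs[g], "removed": g in to_remove})
        if not to_remove:
            break
        if len(current) - len(to_remove) < min_set_size:
            log.warning(
                "refinement would shrink the set below %d genes; keeping the current set", min_set_size
            )
            break
        current = [g for g in current if g not in set(to_remove)]
    refined = GeneSet(gene_set.name + "_refined", current, f"refined at r>={r_min}")
    final_scores = ssgsea_scores(expr, refined, alpha=alpha)
    table = ScoreTable(
        final_scores.to_frame(),
        method="ssgsea_iterative",
        params={"r_min": r_min, "min_set_size": min_set_size, "max_iter": max_iter, "alpha": alpha},
    )
    return refined, table, RefinementTrace(pd.DataFrame(trace_rows))


def score_panel(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    method: str = "module_score",
    **params,
) -> ScoreTable:
    """Apply one scorer to every set of a collection; skipped sets are reported."""
    columns = {}
    skipped = []
    for s in collection:
        try:
            if method == "module_score":
                columns[s.name] = module_score(expr, s, **params)
            elif method == "ssgsea":
                columns[s.name] = ssgsea_scores(expr, s, **params)
            else:
                raise ParameterError(f"unknown scoring method {method!r}")
        except ParameterError as exc:
            if "unknown scoring method" in str(exc):
                raise
            skipped.append(s.name)
            log.warning("set %s skipped: %s", s.name, exc)
    return ScoreTable(pd.DataFrame(columns), method=method, params=dict(params), skipped=skipped)
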