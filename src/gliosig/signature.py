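"""Derivation of the Cd83+ tumor-cell gene signature.

The signature is the set of genes up-regulated (log2 fold change > 1,
Bonferroni-adjusted Wilcoxon p < 0.05) in Cd83+/Cd45- tumor cells from
gain-of-function animals relative to Cd83-/Cd45- tumor cells from wild-type
animals, subsequently mapped from mouse to human symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ParameterError
from .io import LOG_NORMALIZED, RAW_COUNTS, ExpressionMatrix, GeneSet

#: exact-null enumeration is used below this group-size / table-size envelope
EXACT_MIN_N = 8
EXACT_MAX_TABLE = 2500


def select_signature_populations(
    counts: ExpressionMatrix,
    tumor_calls: pd.Series,
    condition_labels: pd.Series,
    cd83_gene: str = "Cd83",
    cd45_gene: str = "Ptprc",
    gof_label: str = "GOF",
    wt_label: str = "WT",
) -> tuple[list[str], list[str]]:
    """Cd83+/Cd45- GOF tumor cells vs Cd83-/Cd45- WT tumor cells.

    Positivity is a detection statement, so it is defined on raw counts
    (count > 0) rather than normalised values.
    """
    if counts.mode != RAW_COUNTS:
        raise ParameterError("population selection uses raw counts for positivity")
    cd83 = pd.Series(counts.gene_values(cd83_gene), index=counts.obs_ids)
    cd45 = pd.Series(counts.gene_values(cd45_gene), index=counts.obs_ids)
    cells = pd.Index(counts.obs_ids)
    tumor = tumor_calls.reindex(cells).fillna(False).astype(bool)
    cond = condition_labels.reindex(cells)
    group_a = cells[tumor & (cond == gof_label) & (cd83 > 0) & (cd45 == 0)].tolist()
    group_b = cells[tumor & (cond == wt_label) & (cd83 == 0) & (cd45 == 0)].tolist()
    if not group_a:
        raise ParameterError("no Cd83+/Cd45- tumor cells in the GOF condition")
    if not group_b:
        raise ParameterError("no Cd83-/Cd45- tumor cells in the WT condition")
    return group_a, group_b


@lru_cache(maxsize=64)
def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the Mann-Whitney U statistic.

    ``counts[u]`` = number of the C(n1+n2, n1) equally likely rank
    assignments with U = u; computed by the standard recurrence
    N(u | i, j) = N(u - j | i - 1, j) + N(u | i, j - 1), which is equivalent
    to full enumeration of the distinguishable assignments.
    """
    size = n1 * n2 + 1
    # prev[j] = distribution for group sizes (i - 1, j); cur[j] for (i, j)
    prev = np.zeros((n2 + 1, size))
    prev[:, 0] = 1.0  # i = 0: U is always 0
    for _i in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0  # j = 0: U is always 0
        for j in range(1, n2 + 1):
            cur[j, j:] = prev[j, : size - j]
            cur[j, :] += cur[j - 1, :]
        prev = cur
    return prev[n2]


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of ``a``, p).

    Mid-ranks for ties.  The exact null (full enumeration via the standard
    counting recurrence) is used when the smaller group has at most 8 values,
    there are no ties, and the table is small enough to enumerate; otherwise
    the normal approximation with tie-corrected variance and a continuity
    correction is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n1, n2, n = a.size, b.size, a.size + b.size
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    has_ties = np.unique(pooled).size < n

    use_exact = mode == "exact" or (
        mode == "auto" and min(n1, n2) <= EXACT_MIN_N and not has_ties and n1 * n2 <= EXACT_MAX_TABLE
    )
    if use_exact and not has_ties:
        u = w - n1 * (n1 + 1) / 2.0
        dist = _u_distribution(n1, n2)
        total = dist.sum()
        ui = int(round(u))
        lower = dist[: ui + 1].sum() / total
        upper = dist[ui:].sum() / total
        return w, float(min(1.0, 2.0 * min(lower, upper)))

    mean_w = n1 * (n + 1) / 2.0
    tie_term = 0.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float(((t**3 - t).sum()))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    return w, float(min(1.0, 2.0 * norm.sf(z)))


@dataclass
class DEResult:
    """Per-gene differential-expression table with Bonferroni adjustment."""

    table: pd.DataFrame  # index gene; columns logFC, statistic, p_raw, p_adj, direction

    def __post_init__(self) -> None:
        required = {"logFC", "statistic", "p_raw", "p_adj", "direction"}
        if not required <= set(self.table.columns):
            raise ParameterError(f"DE table missing columns {required - set(self.table.columns)}")


def differential_expression(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    pseudocount: float = 1e-9,
) -> DEResult:
    """Wilcoxon rank-sum DE of group A vs group B on log-normalised values.

    log2 fold changes are computed on de-logged (expm1) group means with a
    pseudocount; p-values use the tie-corrected normal approximation (group
    sizes here are far beyond the exact-enumeration regime) and Bonferroni
    correction over all genes tested.
    """
    if expr.mode != LOG_NORMALIZED:
        raise ParameterError("differential_expression expects log-normalized values")
    ia = [expr.obs_ids.index(c) for c in group_a]
    ib = [expr.obs_ids.index(c) for c in group_b]
    if not ia or not ib:
        raise ParameterError("both groups must be non-empty")
    A = expr.values[:, ia]
    B = expr.values[:, ib]
    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    logfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    n1, n2 = len(ia), len(ib)
    n = n1 + n2
    pooled = np.concatenate([A, B], axis=1)
    ranks = rankdata(pooled, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mean_w = n1 * (n + 1) / 2.0
    # per-gene tie correction
    tie_term = np.empty(expr.n_genes)
    for g in range(expr.n_genes):
        _, t = np.unique(pooled[g], return_counts=True)
        tie_term[g] = (t**3 - t).sum()
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros(expr.n_genes)
    ok = var_w > 0
    z[ok] = np.maximum(np.abs(w[ok] - mean_w) - 0.5, 0.0) / np.sqrt(var_w[ok])
    p_raw = np.where(ok, 2.0 * norm.sf(z), 1.0)
    p_raw = np.minimum(p_raw, 1.0)
    p_adj = np.minimum(p_raw * expr.n_genes, 1.0)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "statistic": w,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(logfc > 0, "up", np.where(logfc < 0, "down", "none")),
        },
        index=pd.Index(expr.gene_ids, name="gene"),
    )
    return DEResult(table)


def derive_signature(de: DEResult, logfc_min: float = 1.0, padj_max: float = 0.05, name: str = "cd83_signature") -> GeneSet:
    """Up-regulated genes passing strict logFC and adjusted-p thresholds."""
    t = de.table
    keep = (t["logFC"] > logfc_min) & (t["p_adj"] < padj_max) & (t["direction"] == "up")
    genes = t.index[keep].tolist()
    if not genes:
        raise ParameterError("no gene passes the signature thresholds; signature would be empty")
    return GeneSet(name, genes, f"logFC>{logfc_min}, p_adj<{padj_max}")


def map_mouse_to_human(symbols, ortholog_table: pd.DataFrame | dict | None = None) -> tuple[list[str], dict]:
    """Map mouse symbols to human counterparts.

    With an ortholog table (two columns: mouse, human, or a dict) the table
    wins and unmapped symbols are dropped; otherwise the uppercase heuristic
    applies.  Duplicates after mapping are collapsed, order preserved.
    """
    mapping: dict[str, str] = {}
    if ortholog_table is not None:
        if isinstance(ortholog_table, dict):
            mapping = dict(ortholog_table)
        else:
            cols = list(ortholog_table.columns)
            mapping = dict(zip(ortholog_table[cols[0]], ortholog_table[cols[1]]))
    mapped: list[str] = []
    unmapped: list[str] = []
    seen: set[str] = set()
    for s in symbols:
        if ortholog_table is not None:
            if s in mapping:
                h = mapping[s]
            else:
                unmapped.append(s)
                continue
        else:
            h = s.upper()
        if h not in seen:
            seen.add(h)
            mapped.append(h)
    report = {
        "n_input": len(list(symbols)),
        "n_mapped": len(mapped),
        "n_unmapped": len(unmapped),
        "unmapped": unmapped,
        "unmapped_fraction": len(unmapped) / max(1, len(list(symbols))),
    }
    return mapped, report
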