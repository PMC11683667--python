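"""Malignant-cell calling from three independent evidence channels.

Human-style cohorts combine (i) a per-marker two-component Gaussian mixture
fitted by EM on log-normalised expression of SOX2 / EGFR / PDGFRA, (ii)
arm-level copy-number evidence from reference-centred, positionally smoothed
expression, and (iii) rare COSMIC-documented driver variants (IDH1/IDH2
R132H/R132C, or any qualifying EGFR variant).  A cell is called malignant if
it satisfies at least one channel.  Mouse-style cohorts use fixed
reference-quantile marker thresholds or GFP lineage labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .io import LOG_NORMALIZED, ExpressionMatrix

log = logging.getLogger(__name__)

#: printed mouse marker thresholds (99% quantile of a healthy-brain reference)
MOUSE_THRESHOLDS = {"Pdgfra": 2.64, "Egfr": 2.04, "Sox2": 1.95}

#: tumor-defining variant rules: gene -> allowed protein changes (None = any)
DEFAULT_DRIVER_RULES: dict[str, frozenset | None] = {
    "IDH1": frozenset({"R132H", "R132C"}),
    "IDH2": frozenset({"R132H", "R132C"}),
    "EGFR": None,
}


@dataclass
class MarkerMixtureModel:
    """Two-component 1-D Gaussian mixture for one marker gene."""

    marker: str
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    tumor_component: int = 1
    posterior_threshold: float = 0.5
    n_iter: int = 0
    final_loglik: float = float("nan")
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ParameterError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ParameterError("mixture variances must be positive")

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities for each value (rows = values)."""
        x = np.asarray(x, float)[:, None]
        logp = (
            -0.5 * np.log(2 * np.pi * self.variances[None, :])
            - 0.5 * (x - self.means[None, :]) ** 2 / self.variances[None, :]
            + np.log(self.weights[None, :])
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def tumor_posterior(self, x: np.ndarray) -> np.ndarray:
        return self.responsibilities(x)[:, self.tumor_component]


def fit_em_gmm(
    values,
    marker: str = "",
    init=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    variance_floor: float = 1e-6,
    n_starts: int = 2,
    seed: int = 0,
) -> MarkerMixtureModel:
    """Fit a two-class Gaussian mixture to 1-D expression values by EM.

    Initialisation is k-means++-style on the values with ``n_starts`` seeded
    restarts; the best final log-likelihood wins.  Variance collapse is
    handled by flooring, not by error; identical values have no two-class
    structure and raise.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ParameterError("need at least 10 finite values to fit a mixture")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical; no two-class structure to fit")

    rng = np.random.default_rng(seed)
    best: MarkerMixtureModel | None = None
    starts = [init] if init is not None else [_kmeanspp_init(x, rng) for _ in range(n_starts)]
    for means0 in starts:
        model = _run_em(x, np.asarray(means0, float), marker, tol, max_iter, variance_floor)
        if best is None or model.final_loglik > best.final_loglik:
            best = model
    assert best is not None
    # canonical order: component 0 has the smaller mean
    order = np.argsort(best.means)
    best.means = best.means[order]
    best.variances = best.variances[order]
    best.weights = best.weights[order]
    best.tumor_component = 1
    return best


def _kmeanspp_init(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    first = x[rng.integers(x.size)]
    d2 = (x - first) ** 2
    total = d2.sum()
    if total == 0:
        second = first + np.std(x) + 1e-3
    else:
        second = x[rng.choice(x.size, p=d2 / total)]
    return np.array([first, second], float)


def _run_em(x, means, marker, tol, max_iter, variance_floor) -> MarkerMixtureModel:
    n = x.size
    mu = means.copy()
    var = np.full(2, max(np.var(x), variance_floor))
    w = np.full(2, 0.5)
    trace: list[float] = []
    prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        logp = (
            -0.5 * np.log(2 * np.pi * var[None, :])
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
            + np.log(w[None, :])
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        trace.append(loglik)
        r = np.exp(logp - lse[:, None])
        # M step
        nk = r.sum(axis=0)
        nk = np.clip(nk, 1e-12, None)
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, variance_floor)
        if abs(loglik - prev) < tol:
            break
        prev = loglik
    return MarkerMixtureModel(
        marker=marker,
        weights=w,
        means=mu,
        variances=var,
        n_iter=n_iter,
        final_loglik=trace[-1],
        loglik_trace=trace,
    )


def assign_tumor_component(model: MarkerMixtureModel, reference_values=None, reference_labels=None) -> MarkerMixtureModel:
    """Pick the tumor component from a labelled reference, or the higher mean.

    The component whose mean is nearer the labelled tumor-class mean becomes
    the tumor component; with no (or one-class) labels, the higher-mean
    component is used.
    """
    if reference_values is None or reference_labels is None:
        model.tumor_component = int(np.argmax(model.means))
        return model
    vals = np.asarray(reference_values, float)
    labels = np.asarray(reference_labels)
    classes = set(labels.tolist())
    if classes != {"normal", "tumor"}:
        log.warning("labelled reference has classes %s; falling back to higher-mean component", sorted(classes))
        model.tumor_component = int(np.argmax(model.means))
        return model
    tumor_mean = vals[labels == "tumor"].mean()
    model.tumor_component = int(np.argmin(np.abs(model.means - tumor_mean)))
    if model.tumor_component != int(np.argmax(model.means)):
        log.info(
            "marker %s: labelled reference assigns the lower-mean component as tumor", model.marker
        )
    return model


def marker_indicator_matrix(models: dict[str, MarkerMixtureModel], expr: ExpressionMatrix) -> pd.DataFrame:
    """Binary markers × cells indicator: 1 iff tumor-class posterior > threshold."""
    if expr.mode != LOG_NORMALIZED:
        raise ParameterError("marker_indicator_matrix expects log-normalized expression")
    missing = [m for m in models if m not in expr.gene_ids]
    if missing:
        raise ParameterError(f"markers absent from matrix: {missing}")
    rows = {}
    for name, model in models.items():
        post = model.tumor_posterior(expr.gene_values(name))
        rows[name] = (post > model.posterior_threshold).astype(int)
    return pd.DataFrame(rows, index=expr.obs_ids).T


def cnv_evidence(
    expr: ExpressionMatrix,
    gene_arm_table: pd.DataFrame,
    reference_cells,
    smoothing_window: int = 21,
    arm_zshift_threshold: float = 3.0,
    min_genes_per_arm: int = 10,
):
    """Arm-level copy-number evidence from reference-centred expression.

    Per gene, expression is centred by the reference-cell mean; per arm, genes
    are smoothed along their table order by a moving average and averaged into
    an arm score.  An arm is called altered in a cell iff |score| exceeds
    ``arm_zshift_threshold`` reference standard deviations of that arm's
    scores.  Returns ``(cnv_flag per cell, arm-score DataFrame cells × arms)``.
    """
    if expr.mode != LOG_NORMALIZED:
        raise ParameterError("cnv_evidence expects log-normalized expression")
    ref_ix = [expr.obs_ids.index(c) for c in reference_cells]
    if not ref_ix:
        raise ParameterError("reference cell set is empty")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    centered = expr.values - expr.values[:, ref_ix].mean(axis=1, keepdims=True)

    scores = {}
    called = {}
    for arm, group in gene_arm_table.groupby("arm", sort=False):
        genes = [g for g in group["gene"] if g in gene_pos]
        if len(genes) < min_genes_per_arm:
            log.warning("arm %s has %d mapped genes (< %d); skipped", arm, len(genes), min_genes_per_arm)
            continue
        block = centered[[gene_pos[g] for g in genes], :]
        w = min(smoothing_window, block.shape[0])
        kernel = np.full(w, 1.0)
        # coverage-normalized moving average: no zero-padding bias at arm ends
        coverage = np.convolve(np.ones(block.shape[0]), kernel, mode="same")
        smoothed = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="same") / coverage, 0, block
        )
        arm_score = smoothed.mean(axis=0)
        ref_sd = arm_score[ref_ix].std(ddof=0)
        scores[arm] = arm_score
        if ref_sd == 0:
            called[arm] = np.zeros(expr.n_obs, bool)
        else:
            called[arm] = np.abs(arm_score) > arm_zshift_threshold * ref_sd
    score_df = pd.DataFrame(scores, index=expr.obs_ids)
    if called:
        flags = pd.Series(np.column_stack(list(called.values())).any(axis=1), index=expr.obs_ids)
    else:
        flags = pd.Series(False, index=expr.obs_ids)
    return flags, score_df


def snv_evidence(
    variants: pd.DataFrame,
    cell_ids,
    cosmic_required: bool = True,
    max_dbsnp_freq: float = 0.001,
    driver_rules: dict | None = None,
) -> pd.Series:
    """Flag cells carrying a rare, COSMIC-documented driver variant.

    A record qualifies iff it is COSMIC-documented, its dbSNP frequency is
    below ``max_dbsnp_freq`` (missing frequency passes), and it matches the
    driver rules (IDH1/IDH2 restricted to R132H/R132C; EGFR unrestricted).
    """
    rules = DEFAULT_DRIVER_RULES if driver_rules is None else driver_rules
    flags = pd.Series(False, index=list(cell_ids))
    if len(variants) == 0:
        return flags
    df = variants
    ok = pd.Series(True, index=df.index)
    if cosmic_required:
        ok &= df["in_cosmic"].astype(int) == 1
    freq = pd.to_numeric(df["dbsnp_freq"], errors="coerce")
    ok &= freq.isna() | (freq < max_dbsnp_freq)
    in_rules = df["gene"].isin(rules.keys())
    allowed = pd.Series(False, index=df.index)
    for gene, changes in rules.items():
        g = df["gene"] == gene
        allowed |= g if changes is None else g & df["protein_change"].isin(changes)
    ok &= in_rules & allowed
    for cid in df.loc[ok, "cell_id"].unique():
        if cid in flags.index:
            flags[cid] = True
    return flags


def call_tumor_cells(indicators: pd.DataFrame, cnv_flags: pd.Series, snv_flags: pd.Series) -> pd.Series:
    """Final malignancy call: any marker indicator OR CNV flag OR SNV flag."""
    cells = list(indicators.columns)
    if list(cnv_flags.index) != cells or list(snv_flags.index) != cells:
        raise ParameterError("evidence channels are not aligned on the same cells")
    any_marker = indicators.to_numpy().any(axis=0)
    return pd.Series(any_marker | cnv_flags.to_numpy() | snv_flags.to_numpy(), index=cells)


def reference_quantile_thresholds(reference_expr: ExpressionMatrix, markers, q: float = 0.99) -> dict[str, float]:
    """Per-marker q-quantile of reference expression (linear interpolation)."""
    out = {}
    for m in markers:
        out[m] = float(np.quantile(reference_expr.gene_values(m), q))
    return out


def annotate_mouse_tumor(
    expr: ExpressionMatrix,
    thresholds: dict[str, float] | None = None,
    gfp_counts=None,
) -> pd.Series:
    """Mouse-mode call: any marker strictly above its threshold, or GFP > 0."""
    if expr.mode != LOG_NORMALIZED:
        raise ParameterError("annotate_mouse_tumor expects log-normalized expression")
    thr = MOUSE_THRESHOLDS if thresholds is None else thresholds
    call = np.zeros(expr.n_obs, bool)
    for marker, cutoff in thr.items():
        if marker not in expr.gene_ids:
            log.warning("marker %s absent from matrix; treated as all-zero", marker)
            continue
        call |= expr.gene_values(marker) > cutoff
    if gfp_counts is not None:
        call |= np.asarray(gfp_counts, float) > 0
    return pd.Series(call, index=expr.obs_ids)
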