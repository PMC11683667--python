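"""Correlation panels and survival comparison of score-stratified cohorts.

Samples are split at the score quartiles (high: >= Q3, low: <= Q1, middle half
excluded) and compared with the Kaplan-Meier product-limit estimator and the
log-rank test.  Correlations between the program score and immune-module
scores use the Pearson product-moment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .scoring import ScoreTable


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_test(x, y) -> CorrelationResult:
    """Pearson r with the two-sided t test on n-2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def correlation_panel(
    program_scores: pd.Series,
    panel: ScoreTable,
    group_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson test of the program score against every panel column.

    With ``group_by`` (e.g. sample of origin for per-sample single-cell
    panels) each group is tested separately; groups with n < 3 or a constant
    vector are reported with missing statistics and flagged.
    """
    scores = panel.scores
    obs = scores.index
    prog = program_scores.reindex(obs)
    groups = pd.Series("all", index=obs) if group_by is None else pd.Series(group_by).reindex(obs)
    rows = []
    for gname, members in groups.groupby(groups):
        ix = members.index
        for col in scores.columns:
            row = {"group": gname, "gene_set": col, "n": len(ix), "r": np.nan, "p": np.nan, "flag": ""}
            try:
                res = pearson_test(prog.loc[ix], scores.loc[ix, col])
                row.update(r=res.r, p=res.p)
            except ParameterError as exc:
                row["flag"] = str(exc)
            rows.append(row)
    out = pd.DataFrame(rows)
    # unadjusted p mirrors the panel convention; BH column added for the user
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        p = out.loc[ok, "p"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 1.0
        for rank_i in range(m - 1, -1, -1):
            i = order[rank_i]
            running = min(running, p[i] * m / (rank_i + 1))
            adj[i] = running
        out.loc[ok, "p_bh"] = adj
    return out


def quartile_stratify(scores: pd.Series) -> pd.Series:
    """Assign high (>= Q3), low (<= Q1) or excluded, quartiles by interpolation.

    Boundary ties go to the extreme groups.  If every score is equal the
    distribution is degenerate and no sample is stratified.
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 8:
        warnings.warn("fewer than 8 samples; quartile strata may be very small")
    if s.nunique() == 1:
        warnings.warn("degenerate score distribution (all equal); no samples stratified")
        return pd.Series("excluded", index=s.index)
    q1, q3 = np.quantile(s.to_numpy(), [0.25, 0.75])
    strata = pd.Series("excluded", index=s.index)
    low = s <= q1
    high = s >= q3
    both = low & high  # only possible when ties collapse Q1 onto Q3
    if both.any():
        warnings.warn("ties span both quartile boundaries; ambiguous samples excluded")
    strata[low & ~both] = "low"
    strata[high & ~both] = "high"
    return strata


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray  # distinct event times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    median: float  # nan when the curve never reaches 0.5

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator over distinct event times."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ParameterError("empty survival input")
    if np.any(t < 0):
        raise ParameterError("negative survival times")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = []
    s = 1.0
    at_risk = []
    d_list = []
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d_list.append(d_i)
        surv.append(s)
    surv_arr = np.array(surv)
    median = float("nan")
    for ti, si in zip(event_times, surv_arr):
        if si <= 0.5:
            median = float(ti)
            break
    return KMCurve(
        times=event_times,
        at_risk=np.array(at_risk),
        events=np.array(d_list),
        survival=surv_arr,
        median=median,
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank test across k groups; chi-square with k-1 df (k=2 typical).

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the at-risk sets; the
    two-group statistic uses the exact variance term.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise ParameterError("need at least two groups")
    for lab in labels:
        if (g == lab).sum() == 0:  # pragma: no cover - unique() precludes
            raise ParameterError(f"group {lab} is empty")
    event_times = np.unique(t[e == 1])
    if labels.size == 2:
        lab = labels[0]
        o_minus_e = 0.0
        var = 0.0
        for ti in event_times:
            at_risk = t >= ti
            n = at_risk.sum()
            n1 = (at_risk & (g == lab)).sum()
            d = ((t == ti) & (e == 1)).sum()
            d1 = ((t == ti) & (e == 1) & (g == lab)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        if var == 0:
            return 0.0, 1.0
        chi2 = o_minus_e**2 / var
        return float(chi2), float(stats.chi2.sf(chi2, df=1))
    # k-group extension: sum over groups of (O-E)^2/E
    obs = np.zeros(labels.size)
    exp = np.zeros(labels.size)
    for ti in event_times:
        at_risk = t >= ti
        n = at_risk.sum()
        d = ((t == ti) & (e == 1)).sum()
        for j, lab in enumerate(labels):
            nj = (at_risk & (g == lab)).sum()
            obs[j] += ((t == ti) & (e == 1) & (g == lab)).sum()
            exp[j] += d * nj / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=labels.size - 1))


def survival_comparison(scores: pd.Series, survival: pd.DataFrame) -> dict:
    """Quartile-stratify scores, then KM + log-rank of high vs low strata.

    ``survival`` needs columns sample_id, time, event.  Returns strata,
    per-stratum KM curves and medians, and the log-rank statistic/p.
    """
    surv = survival.set_index("sample_id")
    common = [s for s in scores.index if s in surv.index]
    if len(common) < 8:
        warnings.warn("fewer than 8 samples with both score and survival data")
    strata = quartile_stratify(scores.loc[common])
    keep = strata != "excluded"
    sel = strata.index[keep]
    if keep.sum() == 0 or strata.loc[sel].nunique() < 2:
        raise ParameterError("stratification produced fewer than two non-empty strata")
    t = surv.loc[sel, "time"].to_numpy()
    e = surv.loc[sel, "event"].to_numpy()
    grp = strata.loc[sel].to_numpy()
    chi2, p = logrank_test(t, e, grp)
    curves = {
        lab: km_estimate(t[grp == lab], e[grp == lab]) for lab in np.unique(grp)
    }
    return {
        "strata": strata,
        "curves": curves,
        "medians": {lab: c.median for lab, c in curves.items()},
        "chi_square": chi2,
        "p": p,
    }
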