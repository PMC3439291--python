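"""Marker validation statistics: ROC cutoffs, contingency and rank tests,
Kaplan-Meier / log-rank recurrence-free survival, Cox proportional hazards,
and immunohistochemistry quantification arithmetic.

Candidate markers are dichotomized at the ROC cutoff maximizing Youden's
J = sensitivity + specificity - 1 on the recurrence indicator; the resulting
high/low classes feed 2x2 contingency tests, Kaplan-Meier curves with the
log-rank test, and univariate/multivariate Cox models reporting hazard ratios
with Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class CutoffResult:
    marker_id: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float


def roc_cutoff(values, labels, marker_id: str = "") -> CutoffResult:
    """Empirical ROC over all observed thresholds; AUC by the trapezoid rule;
    cutoff = the Youden-J-maximizing threshold, placed midway between adjacent
    observed values ("high" meaning strictly greater than the cutoff).
    Ties in J resolve to the lowest cutoff.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both outcome classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(y, v)
    auc = float(np.trapezoid(tpr, fpr))

    # candidate cutoffs: midpoints between adjacent distinct values, plus one
    # below the minimum and one above the maximum
    u = np.unique(v)
    mids = (u[:-1] + u[1:]) / 2.0
    cands = np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))
    pos, neg = y == 1, y == 0
    best = None
    for c in cands:  # ascending, so ties keep the lowest cutoff
        high = v > c
        sens = float(high[pos].mean())
        spec = float((~high[neg]).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cutoff, sens, spec = best
    return CutoffResult(
        marker_id=marker_id,
        auc=auc,
        cutoff=float(cutoff),
        sensitivity=sens,
        specificity=spec,
    )


@dataclass
class DichotomyResult:
    """High/low classes and the 2x2 class-by-outcome table.

    ``table`` rows are (high, low), columns (outcome 1, outcome 0);
    ``pct_high`` maps each outcome class to the percentage of its patients in
    the high-expression class.
    """

    high: np.ndarray
    table: pd.DataFrame
    pct_high: dict[int, float]
    degenerate: bool


def dichotomize(values, cutoff: float, outcomes) -> DichotomyResult:
    """Split at the cutoff (high = value strictly greater) and cross-tabulate
    against the outcome indicator."""
    if not np.isfinite(cutoff) and cutoff != -np.inf:
        raise ValueError("cutoff must be finite or -inf")
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    high = v > cutoff
    table = pd.DataFrame(
        [
            [int((high & (y == 1)).sum()), int((high & (y == 0)).sum())],
            [int((~high & (y == 1)).sum()), int((~high & (y == 0)).sum())],
        ],
        index=pd.Index(["high", "low"], name="class"),
        columns=pd.Index([1, 0], name="outcome"),
    )
    pct_high = {
        c: summarize_pct_high(table.loc["high", c], table.loc["low", c])
        for c in (1, 0)
        if table[c].sum() > 0
    }
    degenerate = bool(high.all() or (~high).all())
    return DichotomyResult(high=high, table=table, pct_high=pct_high, degenerate=degenerate)


def summarize_pct_high(n_high: int, n_low: int) -> float:
    """Percentage of patients in the high class within one outcome group."""
    total = n_high + n_low
    if total == 0:
        raise ValueError("empty outcome group")
    return 100.0 * n_high / total


def contingency_test(table) -> dict[str, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table,
    plus two-sided Fisher exact (point-probability rule) when 2x2."""
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2 = stats.chi2_contingency(t, correction=False)
    out = {"chi2_stat": float(chi2.statistic), "p_chi2": float(chi2.pvalue)}
    if t.shape == (2, 2):
        out["p_fisher"] = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return out


def group_compare(values, groups) -> dict[str, float]:
    """Two groups: Mann-Whitney U (exact enumeration when both n <= 8 and no
    ties, tie-corrected normal approximation otherwise).  Three or more:
    Kruskal-Wallis."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    samples = [v[g == lab] for lab in labels]
    if any(len(s) == 0 for s in samples) or len(labels) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if len(labels) == 2:
        a, b = samples
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return {"test": "mannwhitney", "stat": float(res.statistic), "p": float(res.pvalue)}
    res = stats.kruskal(*samples)
    return {"test": "kruskal", "stat": float(res.statistic), "p": float(res.pvalue)}


@dataclass
class KMCurves:
    """Per-group product-limit curves as step tables (time, survival, at-risk)."""

    curves: dict[str, pd.DataFrame]

    def survival_at(self, group: str, time: float) -> float:
        c = self.curves[group]
        past = c[c["time"] <= time]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


def km_estimate(times, events, groups) -> KMCurves:
    """Kaplan-Meier recurrence-free survival per group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t <= 0).any():
        raise ValueError("times must be > 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    g = np.asarray(groups)
    curves = {}
    for lab in pd.unique(g):
        m = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"]
        df = pd.DataFrame(
            {
                "time": sf.index.to_numpy(float),
                "survival": sf.iloc[:, 0].to_numpy(float),
                "at_risk": at_risk.reindex(sf.index).ffill().to_numpy(int),
            }
        )
        curves[str(lab)] = df.reset_index(drop=True)
    return KMCurves(curves=curves)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("log-rank test needs exactly 2 groups")
    if e.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    m = g == labels[0]
    res = _ll_logrank(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    return float(res.test_statistic), float(res.p_value)


class CoxSeparationError(RuntimeError):
    """Monotone partial likelihood: a covariate perfectly orders the events."""


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate with HR, Wald 95%
    CI, and p.

    Ties are handled by the Efron approximation; with continuous simulated
    times ties are absent and the estimate coincides with the Breslow partial
    likelihood.  Perfect separation (monotone likelihood) raises
    ``CoxSeparationError`` with the offending fit's diagnostics.
    """
    if data[event_col].sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    df = data[[time_col, event_col] + list(covariates)].copy()
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col=time_col, event_col=event_col)
        except (ConvergenceError, ConvergenceWarning, Warning) as err:
            raise CoxSeparationError(
                "Cox partial likelihood did not converge cleanly; this "
                "typically indicates perfect separation (a covariate that "
                f"monotonically orders the events): {err}"
            ) from err
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "HR": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    out.index.name = "covariate"
    return out


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; p from the t-approximation."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ValueError("need paired observations with n >= 3")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)


@dataclass(frozen=True)
class IHCQuantRecord:
    positive_area: float
    total_area: float
    od: float
    positive_cells: int
    cells_counted: int
    aiod: float
    li: float


def ihc_indices(
    positive_area: float,
    total_area: float,
    od: float,
    positive_cells: int,
    cells_counted: int,
) -> IHCQuantRecord:
    """Immunohistochemistry indices: AIOD = positive area x OD / total area;
    LI = positive cells per 1000 cells counted."""
    if total_area <= 0 or cells_counted <= 0:
        raise ValueError("total_area and cells_counted must be positive")
    if positive_area < 0 or positive_area > total_area:
        raise ValueError("positive_area must lie in [0, total_area]")
    if positive_cells < 0 or positive_cells > cells_counted:
        raise ValueError("positive_cells must lie in [0, cells_counted]")
    return IHCQuantRecord(
        positive_area=positive_area,
        total_area=total_area,
        od=od,
        positive_cells=positive_cells,
        cells_counted=cells_counted,
        aiod=positive_area * od / total_area,
        li=1000.0 * positive_cells / cells_counted,
    )
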