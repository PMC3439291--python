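"""Random-variance-model moderated t-test and DEG selection.

For small-n two-group microarray designs the gene-wise variance estimate is
unstable; the random variance model assumes the per-gene precision 1/sigma_g^2
is Gamma(a, scale=b) distributed across genes, which makes the observed
residual variance satisfy  s_g^2 * a * b ~ F(d, 2a)  with d = n1 + n2 - 2.
Fitting (a, b) by maximum likelihood over all genes yields a moderated
variance

    s~_g^2 = (d * s_g^2 + 2/b) / (d + 2a)

and a t statistic referred to d + 2a degrees of freedom — the extra 2a
degrees of freedom are what rescues a 3-vs-3 design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .synthetic import LabeledExpressionMatrix

#: optimizer bound for the prior shape; at the bound shrinkage is complete
#: (all genes share one variance) and the fit is flagged as boundary.
A_MAX = 1e4
B_MAX = 1e6


@dataclass(frozen=True)
class RVMPrior:
    """Fitted inverse-gamma variance prior: precision ~ Gamma(a, scale=b)."""

    a: float
    b: float
    n_genes_fit: int
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior parameters must be positive")


class RVMFitError(RuntimeError):
    pass


def _group_arrays(
    expr: LabeledExpressionMatrix, groups: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    g1, g2 = groups
    x1 = expr.values[expr.samples_in(g1)].to_numpy(float)
    x2 = expr.values[expr.samples_in(g2)].to_numpy(float)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    return x1, x2


def pooled_variances(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n1, n2 = x1.shape[1], x2.shape[1]
    ss1 = x1.var(axis=1, ddof=1) * (n1 - 1)
    ss2 = x2.var(axis=1, ddof=1) * (n2 - 1)
    return (ss1 + ss2) / (n1 + n2 - 2)


def _neg_log_lik(params: np.ndarray, s2: np.ndarray, d: int) -> float:
    log_a, log_b = params
    a, b = np.exp(log_a), np.exp(log_b)
    # density of s2 when ab*s2 ~ F(d, 2a): include the |d(ab s2)/d s2| Jacobian
    x = a * b * s2
    logpdf = stats.f.logpdf(x, d, 2 * a) + np.log(a * b)
    return -float(np.sum(logpdf))


def fit_rvm_prior(
    expr: LabeledExpressionMatrix, groups: tuple[str, str]
) -> RVMPrior:
    """Maximum-likelihood fit of the variance prior from gene-wise residual
    variances.

    Degenerate regimes are reported rather than hidden: all-zero variances
    raise; a fit running into the shape upper bound (which happens when the
    observed variances are *less* dispersed than a chi-square with d degrees
    of freedom allows, i.e. effectively equal true variances) is returned with
    ``at_boundary=True``.
    """
    x1, x2 = _group_arrays(expr, groups)
    if x1.shape[0] < 10:
        raise RVMFitError("need at least 10 genes to fit the variance prior")
    d = x1.shape[1] + x2.shape[1] - 2
    s2 = pooled_variances(x1, x2)
    s2 = s2[s2 > 0]
    if s2.size == 0:
        raise RVMFitError("all gene-wise variances are zero; cannot fit prior")

    # moment-based start: under the model E[1/ (ab s2)] ... a robust generic
    # start works fine because the likelihood is smooth in (log a, log b)
    start = np.array([np.log(2.0), np.log(1.0 / max(np.mean(s2), 1e-12))])
    res = optimize.minimize(
        _neg_log_lik,
        start,
        args=(s2, d),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    a = float(np.exp(res.x[0]))
    b = float(np.exp(res.x[1]))
    at_boundary = False
    if not np.isfinite(a) or a > A_MAX:
        # complete-shrinkage regime: clamp the shape and re-profile the scale
        a = A_MAX
        at_boundary = True
    if not np.isfinite(b) or b > B_MAX:
        b = B_MAX
        at_boundary = True
    if at_boundary:
        prof = optimize.minimize_scalar(
            lambda lb: _neg_log_lik(np.array([np.log(a), lb]), s2, d),
            bracket=(np.log(b) - 2, np.log(b) + 2),
            method="brent",
        )
        b = float(np.exp(prof.x))
    return RVMPrior(a=a, b=b, n_genes_fit=int(s2.size), at_boundary=at_boundary)


def rvm_t_test(
    expr: LabeledExpressionMatrix,
    groups: tuple[str, str],
    prior: RVMPrior,
) -> pd.DataFrame:
    """Per-gene moderated two-sample t-test.

    Returns a DataFrame indexed by gene with columns mean_g1, mean_g2,
    log_ratio (mean_g1 - mean_g2; group 1 is conventionally the recurrence
    group), s2, s2_tilde, t_stat, df, p, q, direction.
    """
    x1, x2 = _group_arrays(expr, groups)
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s2 = pooled_variances(x1, x2)
    s2_tilde = (d * s2 + 2.0 / prior.b) / (d + 2.0 * prior.a)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    df = d + 2.0 * prior.a
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "mean_g1": m1,
            "mean_g2": m2,
            "log_ratio": diff,
            "s2": s2,
            "s2_tilde": s2_tilde,
            "t_stat": t,
            "df": df,
            "p": p,
            "q": q,
            "direction": np.where(diff >= 0, "up", "down"),
        },
        index=expr.values.index,
    )
    out.index.name = "gene_id"
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEGSelection:
    up: tuple[str, ...]
    down: tuple[str, ...]
    p_max: float
    q_max: float
    min_abs_log_ratio: float

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up + self.down

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def select_degs(
    results: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.10,
    min_abs_log_ratio: float = 0.0,
) -> DEGSelection:
    """Gate genes on p < p_max AND q < q_max, partitioned by shift direction.

    A fold-change gate is available through ``min_abs_log_ratio`` but defaults
    to off: the selection rule is purely significance-based.
    """
    if results.empty:
        raise ValueError("empty DE results")
    keep = (results["p"] < p_max) & (results["q"] < q_max)
    if min_abs_log_ratio > 0:
        keep &= results["log_ratio"].abs() >= min_abs_log_ratio
    sel = results[keep]
    return DEGSelection(
        up=tuple(sel.index[sel["log_ratio"] > 0]),
        down=tuple(sel.index[sel["log_ratio"] <= 0]),
        p_max=p_max,
        q_max=q_max,
        min_abs_log_ratio=min_abs_log_ratio,
    )


@dataclass
class ClusterResult:
    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - r distances between rows; constant rows contribute
    distance 1 (zero correlation) to every pair, by declaration."""
    sd = x.std(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = np.where(sd[:, None] > 0, xc / np.maximum(sd[:, None], 1e-300), 0.0)
    r = (xn @ xn.T) / x.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices_from(dist, k=1)
    return np.maximum(dist[iu], 0.0)


def hierarchical_cluster(
    expr: LabeledExpressionMatrix,
    genes=None,
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of genes and samples for heatmap display.

    Distance is correlation distance (1 - Pearson r), the convention for
    expression heatmaps; linkage is average by default.  Samples are compared
    on gene-centered values (each gene's mean subtracted), matching how
    heatmaps display relative expression — without it, between-sample
    correlations are dominated by each gene's absolute level.
    """
    sub = expr.subset_genes(list(genes)) if genes is not None else expr
    x = sub.values.to_numpy(float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    gl = hierarchy.linkage(_correlation_distance(x), method=linkage_method)
    centered = x - x.mean(axis=1, keepdims=True)
    sl = hierarchy.linkage(_correlation_distance(centered.T), method=linkage_method)
    return ClusterResult(
        gene_order=[sub.values.index[i] for i in hierarchy.leaves_list(gl)],
        sample_order=[sub.values.columns[i] for i in hierarchy.leaves_list(sl)],
        gene_linkage=gl,
        sample_linkage=sl,
    )
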