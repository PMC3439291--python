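"""Gene-set over-representation scoring with the enrichment ratio Re.

For a category with Nf members among the N annotated universe genes, of which
nf fall in the n annotated differential genes, the enrichment ratio is

    Re = (nf / n) / (Nf / N),

i.e. the category's rate inside the differential set relative to its universe
rate.  Significance comes from a two-sided Fisher exact test (point-probability
rule) and a Pearson chi-square test without continuity correction on the 2x2
table [[nf, n - nf], [Nf - nf, N - n - (Nf - nf)]]; LgP is log10 of the Fisher
p-value.  Up- and down-regulated differential sets are scored separately and
BH-adjusted within direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .synthetic import AnnotationCollection


def enrichment_ratio(nf: int, n: int, Nf: int, N: int) -> float:
    """Re = (nf/n) / (Nf/N).  Nf=0 with nf=0 returns 0 by convention; Nf=0
    with nf>0 is impossible (the overlap cannot exceed the category)."""
    _check_counts(nf, n, Nf, N)
    if Nf == 0:
        if nf > 0:
            raise ValueError("nf > 0 requires Nf > 0")
        return 0.0
    return (nf / n) / (Nf / N)


def _check_counts(nf: int, n: int, Nf: int, N: int) -> None:
    if n <= 0 or N <= 0:
        raise ValueError("n and N must be positive")
    if nf < 0 or Nf < 0:
        raise ValueError("counts must be non-negative")
    if nf > n or Nf > N or nf > Nf or n > N:
        raise ValueError(f"inconsistent counts nf={nf}, n={n}, Nf={Nf}, N={N}")


def category_test(nf: int, n: int, Nf: int, N: int) -> tuple[float, float]:
    """(Fisher two-sided p, chi-square p) for the category 2x2 table.

    The Fisher test uses the point-probability (minimum-likelihood) two-sided
    rule; chi-square is Pearson's without continuity correction.  Degenerate
    tables (a zero margin) return p = 1 for both tests.
    """
    _check_counts(nf, n, Nf, N)
    table = np.array([[nf, n - nf], [Nf - nf, N - n - (Nf - nf)]])
    if (table < 0).any():
        raise ValueError("derived cell count negative; inputs inconsistent")
    p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return p_fisher, 1.0
    chi2 = stats.chi2_contingency(table, correction=False)
    return p_fisher, float(chi2.pvalue)


@dataclass
class EnrichmentTable:
    """Ranked per-term results for one differential-set direction."""

    direction: str
    n: int  # differential genes annotated to >= 1 term
    N: int  # universe genes annotated to >= 1 term
    table: pd.DataFrame  # term_id, term_name, nf, Nf, Re, p_fisher, p_chi2, q, LgP


def enrich(
    deg_genes: Iterable[str],
    direction: str,
    annotations: AnnotationCollection,
    universe: Iterable[str] | None = None,
) -> EnrichmentTable:
    """Score every annotation term for over-representation in ``deg_genes``.

    ``n`` counts differential genes annotated to at least one term and ``N``
    universe genes annotated to at least one term, so the two rates in Re are
    computed over comparable annotated backgrounds.  Terms are ranked by
    Fisher p; q is BH across terms within this direction.
    """
    deg = set(deg_genes)
    uni = set(universe) if universe is not None else set(annotations.universe)
    stray = deg - uni
    if stray:
        raise ValueError(
            f"differential genes absent from the universe: {sorted(stray)[:5]}"
        )
    annotated = set().union(*(m for _, m in annotations.terms.values()))
    annotated &= uni
    n = len(deg & annotated)
    N = len(annotated)
    if not deg:
        warnings.warn("empty differential gene set; enrichment table is empty")
        empty = pd.DataFrame(
            columns=["term_name", "nf", "Nf", "Re", "p_fisher", "p_chi2", "q", "LgP"]
        )
        empty.index.name = "term_id"
        return EnrichmentTable(direction=direction, n=n, N=N, table=empty)

    rows = []
    for term_id, (name, members) in annotations.terms.items():
        mem = members & annotated
        Nf = len(mem)
        nf = len(deg & mem)
        re_ = enrichment_ratio(nf, n, Nf, N) if Nf else 0.0
        p_f, p_c = category_test(nf, n, Nf, N)
        rows.append((term_id, name, nf, Nf, re_, p_f, p_c))
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "nf", "Nf", "Re", "p_fisher", "p_chi2"]
    ).set_index("term_id")
    out["q"] = bh_fdr(out["p_fisher"].to_numpy())
    with np.errstate(divide="ignore"):
        out["LgP"] = np.log10(out["p_fisher"].to_numpy())
    out = out.sort_values(["p_fisher", "term_id"], kind="mergesort")
    return EnrichmentTable(direction=direction, n=n, N=N, table=out)
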