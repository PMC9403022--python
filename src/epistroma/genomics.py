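"""Image-phenotype / transcriptome association.

Given per-sample tissue ratios and a genes x samples expression matrix:
rank-correlate every gene with the epithelial and stromal ratios (Spearman),
select the top fraction (default 1%) of genes by signed correlation per
tissue, and test the selection against a gene-set collection with the
hypergeometric over-representation test, Bonferroni-adjusted (Benjamini–
Hochberg offered as an alternative).  The reporting convention is the top 10
terms ordered by adjusted then raw p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentRow",
    "spearman_rho",
    "correlate_expression",
    "select_top_fraction",
    "ora_enrich",
    "top_terms",
    "RatioExpressionAnalysis",
    "RatioExpressionResults",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested gene set: hit count k of a selection of size n against a
    term of size K in a reference universe of size N."""

    term: str
    description: str
    k: int
    n: int
    K: int
    N: int
    enrichment_ratio: float
    p: float
    p_adj: float


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values rejected")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def correlate_expression(expr: pd.DataFrame, ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Spearman correlation against both tissue ratios.

    ``expr`` is genes x samples; ``ratios`` is indexed by sample with columns
    ``ratio_epi`` and ``ratio_stro``.  Returns a frame indexed by gene with
    columns ``rho_epi``, ``rho_stro`` and ``defined`` (False, with NaN rhos,
    for constant-expression genes).
    """
    if set(expr.columns) != set(ratios.index):
        raise ValueError("sample IDs of expression matrix and ratios do not match")
    ratios = ratios.loc[list(expr.columns)]

    X = expr.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite expression values rejected")
    ranks = stats.rankdata(X, axis=1)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((rc**2).sum(axis=1))
    defined = norms > 0

    out = {}
    for col, name in (("ratio_epi", "rho_epi"), ("ratio_stro", "rho_stro")):
        r = stats.rankdata(ratios[col].to_numpy(dtype=np.float64))
        r = r - r.mean()
        rn = np.sqrt((r**2).sum())
        if rn == 0:
            raise ValueError(f"{col} is constant across samples")
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rc @ r) / (norms * rn)
        rho[~defined] = np.nan
        out[name] = rho
    table = pd.DataFrame(out, index=expr.index)
    table["defined"] = defined
    return table


def select_top_fraction(
    table: pd.DataFrame,
    tissue: str = "epi",
    fraction: float = 0.01,
    absolute: bool = False,
) -> list[str]:
    """Top ``ceil(fraction * G)`` genes by signed (or absolute) Spearman
    correlation for the chosen tissue, descending; ties at the cut break by
    gene ID.  G counts all genes in the table; undefined rows sort last."""
    if table.empty:
        raise ValueError("empty correlation table")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if tissue not in ("epi", "stro"):
        raise ValueError("tissue must be 'epi' or 'stro'")
    col = f"rho_{tissue}"
    rho = table[col].to_numpy(dtype=np.float64)
    if absolute:
        rho = np.abs(rho)
    key = np.where(np.isnan(rho), -np.inf, rho)
    order = sorted(range(len(table)), key=lambda i: (-key[i], str(table.index[i])))
    n_take = math.ceil(fraction * len(table))
    return [str(table.index[i]) for i in order[:n_take]]


def ora_enrich(
    selection,
    annotation: dict[str, tuple[str, tuple[str, ...]]],
    reference,
    min_term_size: int = 5,
    adjust: str = "bonferroni",
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of a gene selection.

    For each term with at least ``min_term_size`` genes in the reference,
    p = P[X >= k] with X ~ Hypergeom(N, K, n) (upper tail, computed in log
    space by scipy).  ``adjust`` is 'bonferroni' (m = number of tested terms,
    capped at 1) or 'bh'.  Rows return sorted by raw p ascending.
    """
    reference = set(reference)
    selection = set(selection)
    if not reference:
        raise ValueError("empty reference universe")
    if not selection:
        raise ValueError("empty selection")
    if not selection <= reference:
        raise ValueError("selection must be a subset of the reference universe")
    if adjust not in ("bonferroni", "bh"):
        raise ValueError("adjust must be 'bonferroni' or 'bh'")

    N, n = len(reference), len(selection)
    rows = []
    for term, (desc, genes) in annotation.items():
        members = set(genes) & reference
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & selection)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        er = (k / n) / (K / N)
        rows.append((term, desc, k, K, p, er))

    m = len(rows)
    rows.sort(key=lambda r: (r[4], r[0]))
    if adjust == "bonferroni":
        adj = [min(1.0, m * r[4]) for r in rows]
    else:  # Benjamini-Hochberg step-up on the p-sorted rows
        adj = [0.0] * m
        prev = 1.0
        for i in range(m - 1, -1, -1):
            prev = min(prev, rows[i][4] * m / (i + 1))
            adj[i] = prev
    return [
        EnrichmentRow(term=t, description=d, k=k, n=n, K=K, N=N, enrichment_ratio=er, p=p, p_adj=a)
        for (t, d, k, K, p, er), a in zip(rows, adj)
    ]


def top_terms(rows: list[EnrichmentRow], k: int = 10) -> list[EnrichmentRow]:
    """First k rows under the ordering (p_adj, p, -enrichment_ratio, term)."""
    ranked = sorted(rows, key=lambda r: (r.p_adj, r.p, -r.enrichment_ratio, r.term))
    return ranked[:k]


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "description": r.description,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "enrichment_ratio": r.enrichment_ratio,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in rows
        ]
    )


@dataclass
class RatioExpressionResults:
    """Fitted association results: the correlation table, per-tissue top-gene
    selections and their enrichment rows."""

    correlations: pd.DataFrame
    selections: dict[str, list[str]]
    enrichment: dict[str, list[EnrichmentRow]]

    def summary(self, top: int = 10) -> str:
        lines = []
        for tissue in ("epi", "stro"):
            lines.append(f"[{tissue}] {len(self.selections[tissue])} selected genes")
            for r in top_terms(self.enrichment[tissue], top):
                lines.append(
                    f"  {r.term:<12} k={r.k:<4} K={r.K:<5} ER={r.enrichment_ratio:7.2f}"
                    f"  p={r.p:.3e}  p_adj={r.p_adj:.3e}"
                )
        return "\n".join(lines)


class RatioExpressionAnalysis:
    """Model-style front end: bind data, then fit.

    Parameters are the expression matrix (genes x samples), the per-sample
    ratio table, and a gene-set annotation; ``fit`` runs correlation,
    top-fraction selection for both tissues and over-representation against
    the reference universe (genes present in both the expression matrix and
    the annotation, unless overridden).
    """

    def __init__(self, expr: pd.DataFrame, ratios: pd.DataFrame, annotation: dict):
        self.expr = expr
        self.ratios = ratios
        self.annotation = annotation

    def fit(
        self,
        fraction: float = 0.01,
        min_term_size: int = 5,
        adjust: str = "bonferroni",
        reference: set | None = None,
        absolute: bool = False,
    ) -> RatioExpressionResults:
        table = correlate_expression(self.expr, self.ratios)
        if reference is None:
            annotated = set().union(*(set(g) for _, g in self.annotation.values()))
            reference = set(map(str, self.expr.index)) & annotated
        selections, enrich = {}, {}
        for tissue in ("epi", "stro"):
            sel = select_top_fraction(table, tissue=tissue, fraction=fraction, absolute=absolute)
            sel_ref = [g for g in sel if g in reference]
            selections[tissue] = sel
            enrich[tissue] = ora_enrich(sel_ref, self.annotation, reference, min_term_size, adjust)
        return RatioExpressionResults(correlations=table, selections=selections, enrichment=enrich)
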