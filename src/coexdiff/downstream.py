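"""Differential expression, gene-set enrichment and hub-gene ranking.

The downstream stage interprets the network results: per-gene two-sample
t-tests with Benjamini--Hochberg control, hypergeometric enrichment of
user-supplied gene sets (GMT), and degree ranking of genes in the
significant switched-pair network, whose top entries are the candidate
master regulators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DiffCorrRecord, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("coexdiff")

__all__ = [
    "DgeTable",
    "EnrichmentTable",
    "HubRanking",
    "differential_expression",
    "benjamini_hochberg",
    "enrich",
    "rank_hubs",
]

P_FLOOR = 1e-300


def benjamini_hochberg(p) -> list[float]:
    """Benjamini--Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


@dataclass(frozen=True)
class DgeTable:
    """Per-gene differential expression results (t-test + BH)."""

    table: pd.DataFrame  # index gene; mean_cond1, mean_cond2, t_stat, p, p_adj, significant

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def differential_expression(cond1: ExpressionMatrix, cond2: ExpressionMatrix,
                            welch: bool = False,
                            alpha: float = 0.05) -> DgeTable:
    """Two-sample t-test per gene with Benjamini--Hochberg adjustment.

    The default is the pooled-variance Student t; ``welch=True`` drops the
    equal-variance assumption.  Genes with zero variance in both groups get
    p = 1 when the means agree and a floored near-zero p (with a warning)
    when they differ.
    """
    if tuple(cond1.gene_ids) != tuple(cond2.gene_ids):
        raise ValueError("conditions must share the same genes in order")
    if cond1.n_samples < 2 or cond2.n_samples < 2:
        raise ValueError("need >= 2 samples per condition")
    x, y = cond1.values, cond2.values
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(x, y, axis=1, equal_var=not welch)
    mean1, mean2 = x.mean(axis=1), y.mean(axis=1)

    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    degenerate |= ~np.isfinite(p)
    if np.any(degenerate):
        same = np.isclose(mean1, mean2)
        n_forced = int(np.sum(degenerate & ~same))
        if n_forced:
            warnings.warn(
                f"{n_forced} genes have zero variance but unequal means; "
                "p floored at 1e-300"
            )
        p = np.where(degenerate, np.where(same, 1.0, P_FLOOR), p)
        t_stat = np.where(degenerate, np.where(same, 0.0, np.inf), t_stat)
    p = np.clip(p, P_FLOOR, 1.0)
    p_adj = np.asarray(benjamini_hochberg(p))
    df = pd.DataFrame(
        {
            "mean_cond1": mean1,
            "mean_cond2": mean2,
            "t_stat": t_stat,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=list(cond1.gene_ids),
    )
    df.index.name = "gene"
    return DgeTable(df)


@dataclass(frozen=True)
class EnrichmentTable:
    """Hypergeometric over-representation results per gene set."""

    table: pd.DataFrame  # index set; overlap, set_size, query_size, universe_size, p, p_adj, significant


def enrich(query, universe, sets: GeneSetCollection,
           alpha: float = 0.05) -> EnrichmentTable:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; the upper-tail
    p is P(X >= k) for overlap k with set size K, query size n and universe
    size N, followed by BH adjustment across sets.
    """
    query = list(dict.fromkeys(query))
    universe_set = set(universe)
    if not universe_set or not query:
        raise ValueError("query and universe must be non-empty")
    stray = [g for g in query if g not in universe_set]
    if stray:
        raise ValueError(f"query genes outside universe: {stray[:5]}")
    N, n = len(universe_set), len(query)
    query_set = set(query)

    rows = []
    for name, members in sets:
        in_universe = [g for g in members if g in universe_set]
        K = len(in_universe)
        k = len(query_set.intersection(in_universe))
        if K == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(1.0, max(P_FLOOR, p))))
    df = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "query_size", "universe_size", "p"],
    ).set_index("set")
    df["p_adj"] = benjamini_hochberg(df["p"]) if len(df) else []
    df["significant"] = df["p_adj"] < alpha
    return EnrichmentTable(df)


@dataclass(frozen=True)
class HubRanking:
    """Genes of the switched-pair network ranked by degree.

    Ties on degree are broken by the summed correlation reversal
    sum(|r1 - r2|) over incident edges, then by gene id; ranks are 1..n.
    """

    table: pd.DataFrame  # index gene; degree, reversal_score, rank

    def top(self, k: int) -> list[str]:
        return list(self.table.index[:k])


def rank_hubs(records) -> HubRanking:
    """Degree-rank genes over the unique pairs of the switched-pair network."""
    seen: dict[frozenset, DiffCorrRecord] = {}
    for r in records:
        key = frozenset((r.gene_a, r.gene_b))
        if key not in seen:
            seen[key] = r
    degree: dict[str, int] = {}
    reversal: dict[str, float] = {}
    for r in seen.values():
        for g in (r.gene_a, r.gene_b):
            degree[g] = degree.get(g, 0) + 1
            reversal[g] = reversal.get(g, 0.0) + abs(r.r1 - r.r2)
    if not degree:
        empty = pd.DataFrame(columns=["degree", "reversal_score", "rank"])
        empty.index.name = "gene"
        return HubRanking(empty)
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "reversal_score": pd.Series(reversal),
        }
    )
    df.index.name = "gene"
    df = df.sort_values(
        by=["degree", "reversal_score"], ascending=[False, False], kind="mergesort"
    )
    # stable sort on gene id first would scramble the primary keys; instead
    # resolve residual ties explicitly
    df = df.reset_index().sort_values(
        by=["degree", "reversal_score", "gene"], ascending=[False, False, True],
        kind="mergesort",
    ).set_index("gene")
    df["rank"] = np.arange(1, len(df) + 1)
    return HubRanking(df)
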