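"""Differential-correlation analysis between two conditions.

For every gene pair in a module the Pearson correlation is computed
separately in the two conditions (signed, unlike the unsigned network
construction: sign switches are the point here), the difference is tested
with Fisher's z

    z_k = atanh(r_k),  Z = (z_1 - z_2) / sqrt(1/(n_1 - 3) + 1/(n_2 - 3)),

and significance is assessed with an empirical-Bayes local false discovery
rate estimated from the module's collection of Z statistics against the
theoretical N(0, 1) null.  Pairs with lfdr below the cut whose correlation
changes sign between conditions are the "oppositely correlated" pairs.

The lfdr recipe (histogram + log-linear spline density, central-ratio pi0,
isotonic monotonicity in |z|) follows the standard empirical-null approach;
Benjamini--Hochberg q-values are always computed alongside as a cross-check
and as the fallback when too few statistics are available for a stable
density estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import interpolate, stats
from sklearn.isotonic import IsotonicRegression

from .io import DiffCorrRecord, ExpressionMatrix, TraitVector
from .modules import _standardize

logger = logging.getLogger("coexdiff")

__all__ = [
    "DiffCorrTable",
    "EigenMoleculeNetwork",
    "split_by_condition",
    "fisher_z_test",
    "correlation_p",
    "local_fdr",
    "diffcorr_scan",
    "switched_pairs",
    "eigen_molecule_network",
    "DIFFCORR_TSV_COLUMNS",
]

P_FLOOR = 1e-300          # never print hard zeros
R_CLAMP = 1.0 - 1e-7      # |r| = 1 is clamped before atanh


def split_by_condition(expr: ExpressionMatrix, traits: TraitVector,
                       ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split columns into (condition-1, condition-0) matrices, gene order kept."""
    traits = traits.aligned_to(expr)
    cond1 = [s for s, l in zip(traits.sample_ids, traits.labels) if l == 1]
    cond2 = [s for s, l in zip(traits.sample_ids, traits.labels) if l == 0]
    # TraitVector guarantees >= 4 per class (Fisher z needs n - 3 > 0)
    return expr.subset_samples(cond1), expr.subset_samples(cond2)


def _clamp_r(r: float | np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation of magnitude 1 clamped before atanh")
    return np.clip(r, -R_CLAMP, R_CLAMP)


def fisher_z_test(r1: float, n1: int, r2: float, n2: int,
                  ) -> tuple[float, float]:
    """Fisher z-test for equality of two independent Pearson correlations.

    Returns the standardized difference Z and its two-sided normal p-value.
    ``p`` is floored at 1e-300 so extreme differences never print as 0.
    """
    if min(n1, n2) < 4:
        raise ValueError("Fisher z requires n >= 4 in each condition")
    z1 = np.arctanh(_clamp_r(r1))
    z2 = np.arctanh(_clamp_r(r2))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = float((z1 - z2) / se)
    p = 2.0 * stats.norm.sf(abs(z_stat))
    return z_stat, float(min(1.0, max(P_FLOOR, p)))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p for a single Pearson r via t = r sqrt((n-2)/(1-r^2))."""
    if n < 4:
        raise ValueError("need n >= 4")
    r = float(_clamp_r(r))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(1.0, max(P_FLOOR, p)))


@dataclass(frozen=True)
class LfdrDiagnostics:
    """How the lfdr was estimated (or why it fell back to BH)."""

    method: str            # "spline" or "bh_fallback"
    pi0: float
    n_bins: int
    n_values: int


def _bh(p: np.ndarray) -> np.ndarray:
    from .downstream import benjamini_hochberg
    return np.asarray(benjamini_hochberg(list(p)))


def local_fdr(z_values, n_bins: int = 120, n_basis: int = 7,
              ) -> tuple[np.ndarray, LfdrDiagnostics]:
    """Empirical-Bayes local FDR for a collection of z statistics.

    The marginal density f(z) is estimated from a histogram smoothed by a
    Poisson log-linear fit on a cubic B-spline basis; the null is the
    theoretical N(0, 1).  pi0 is the median of phi(z)/f(z) over the central
    half of the data, capped at 1.  lfdr(z) = pi0 * phi(z) / f(z), capped
    to [1e-300, 1] and made monotone non-increasing in |z| by isotonic
    regression.

    With fewer than 50 values (or a degenerate histogram) the estimate
    falls back to Benjamini--Hochberg q-values of the two-sided normal
    p-values, with a logged notice.
    """
    z = np.asarray(list(z_values), dtype=float)
    n = z.size
    if n == 0:
        raise ValueError("no z-values given")
    p_two_sided = 2.0 * stats.norm.sf(np.abs(z))

    def fallback(reason: str) -> tuple[np.ndarray, LfdrDiagnostics]:
        logger.warning("local_fdr: falling back to BH q-values (%s)", reason)
        q = np.clip(_bh(p_two_sided), P_FLOOR, 1.0)
        return q, LfdrDiagnostics("bh_fallback", 1.0, 0, n)

    if n < 50:
        return fallback(f"only {n} values, need >= 50")
    if np.ptp(z) < 1e-12:
        return fallback("degenerate (constant) z-values")
    if n < 200:
        logger.warning("local_fdr: %d z-values; density estimate may be unstable", n)

    lo, hi = z.min(), z.max()
    pad = 1e-6 * max(1.0, hi - lo)
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]

    # cubic B-spline basis with n_basis functions over the data range
    degree = 3
    n_interior = max(0, n_basis - degree - 1)
    interior = np.quantile(z, np.linspace(0, 1, n_interior + 2)[1:-1]) \
        if n_interior else np.array([])
    knots = np.concatenate([
        np.repeat(edges[0], degree + 1), interior, np.repeat(edges[-1], degree + 1),
    ])
    design = interpolate.BSpline.design_matrix(
        centers, knots, degree, extrapolate=True).toarray()
    try:
        fit = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
        eta = design @ fit.params
    except Exception as exc:
        return fallback(f"spline fit failed: {exc}")
    if not np.all(np.isfinite(eta)):
        return fallback("non-finite density fit")

    fitted = np.exp(eta)
    density_bins = fitted / fitted.sum() / width
    # evaluate at each z by interpolating the log-density between bin centres
    log_density = np.interp(z, centers, np.log(np.maximum(density_bins, 1e-320)))
    f_hat = np.exp(log_density)
    phi = stats.norm.pdf(z)

    central = (z >= np.quantile(z, 0.25)) & (z <= np.quantile(z, 0.75))
    ratio = phi[central] / np.maximum(f_hat[central], 1e-320)
    pi0 = float(min(1.0, np.median(ratio)))

    lfdr = np.clip(pi0 * phi / np.maximum(f_hat, 1e-320), P_FLOOR, 1.0)
    # enforce monotone non-increasing lfdr in |z|
    iso = IsotonicRegression(increasing=False, y_min=P_FLOOR, y_max=1.0)
    lfdr = iso.fit_transform(np.abs(z), lfdr)
    return np.asarray(lfdr), LfdrDiagnostics("spline", pi0, n_bins, n)


@dataclass(frozen=True)
class DiffCorrTable:
    """All pairwise differential-correlation records for one module."""

    records: tuple[DiffCorrRecord, ...]
    n1: int
    n2: int
    diagnostics: LfdrDiagnostics
    excluded_genes: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [r.gene_a for r in self.records],
                "gene_b": [r.gene_b for r in self.records],
                "r_cond1": [r.r1 for r in self.records],
                "p_cond1": [r.p1 for r in self.records],
                "r_cond2": [r.r2 for r in self.records],
                "p_cond2": [r.p2 for r in self.records],
                "z_stat": [r.z_stat for r in self.records],
                "p_diff": [r.p_diff for r in self.records],
                "q_diff": [r.q_diff for r in self.records],
                "lfdr": [r.lfdr for r in self.records],
                "switched": ["true" if r.switched else "false"
                             for r in self.records],
            }
        )


DIFFCORR_TSV_COLUMNS = (
    "gene_a", "gene_b", "r_cond1", "p_cond1", "r_cond2", "p_cond2",
    "z_stat", "p_diff", "q_diff", "lfdr", "switched",
)


def diffcorr_scan(cond1: ExpressionMatrix, cond2: ExpressionMatrix,
                  module_genes=None) -> DiffCorrTable:
    """Scan all gene pairs of a module for differential correlation.

    Correlations are signed here.  Zero-variance genes in either condition
    are excluded with a warning.  The lfdr is estimated over this module's
    z statistics only; records are sorted by (lfdr, |z| descending, pair).
    """
    if module_genes is None:
        module_genes = list(cond1.gene_ids)
    module_genes = list(module_genes)
    sub1 = cond1.subset_genes(module_genes)
    sub2 = cond2.subset_genes(module_genes)

    sd1, sd2 = sub1.values.std(axis=1), sub2.values.std(axis=1)
    bad = (sd1 == 0) | (sd2 == 0)
    excluded = tuple(g for g, b in zip(module_genes, bad) if b)
    if excluded:
        logger.warning("excluding %d zero-variance genes from scan: %s",
                       len(excluded), list(excluded)[:5])
        module_genes = [g for g, b in zip(module_genes, bad) if not b]
        sub1, sub2 = sub1.subset_genes(module_genes), sub2.subset_genes(module_genes)

    m = len(module_genes)
    if m < 2:
        raise ValueError("need >= 2 usable genes for a pair scan")
    n1, n2 = sub1.n_samples, sub2.n_samples
    R1 = np.clip(np.corrcoef(sub1.values), -1.0, 1.0)
    R2 = np.clip(np.corrcoef(sub2.values), -1.0, 1.0)

    iu = np.triu_indices(m, k=1)
    r1, r2 = R1[iu], R2[iu]
    r1c, r2c = _clamp_r(r1), _clamp_r(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (np.arctanh(r1c) - np.arctanh(r2c)) / se
    p_diff = np.clip(2.0 * stats.norm.sf(np.abs(z_stat)), P_FLOOR, 1.0)

    def corr_p(r: np.ndarray, n: int) -> np.ndarray:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        return np.clip(2.0 * stats.t.sf(np.abs(t), df=n - 2), P_FLOOR, 1.0)

    p1, p2 = corr_p(r1c, n1), corr_p(r2c, n2)
    lfdr, diagnostics = local_fdr(z_stat)
    q_diff = np.clip(_bh(p_diff), P_FLOOR, 1.0)

    records = [
        DiffCorrRecord(
            gene_a=module_genes[i], gene_b=module_genes[j],
            r1=float(r1[k]), n1=n1, r2=float(r2[k]), n2=n2,
            p1=float(p1[k]), p2=float(p2[k]),
            z_stat=float(z_stat[k]), p_diff=float(p_diff[k]),
            lfdr=float(lfdr[k]), switched=bool(r1[k] * r2[k] < 0),
            q_diff=float(q_diff[k]),
        )
        for k, (i, j) in enumerate(zip(*iu))
    ]
    records.sort(key=lambda r: (r.lfdr, -abs(r.z_stat), r.gene_a, r.gene_b))
    return DiffCorrTable(tuple(records), n1, n2, diagnostics, excluded)


def switched_pairs(table: DiffCorrTable, lfdr_cut: float = 0.05,
                   ) -> list[DiffCorrRecord]:
    """Significant sign-switching pairs: switched and lfdr below the cut."""
    return [r for r in table.records if r.switched and r.lfdr < lfdr_cut]


@dataclass(frozen=True)
class EigenMoleculeNetwork:
    """Correlation-clustered submodules of one module and their eigengene graph."""

    submodules: dict[str, tuple[str, ...]]       # label -> member genes
    eigengenes: dict[str, np.ndarray]
    edges: tuple[tuple[str, str, float], ...]    # (label_a, label_b, correlation)


def eigen_molecule_network(expr: ExpressionMatrix, module_genes,
                           n_submodules: int = 2,
                           edge_threshold: float = 0.3) -> EigenMoleculeNetwork:
    """Group a module's genes by expression pattern and link the group summaries.

    Genes are clustered by average linkage on (1 - signed Pearson
    correlation) and cut into ``n_submodules`` groups; each group gets an
    eigengene (first PC, or the standardised profile for singletons) and
    groups are connected when |cor(eigengene_a, eigengene_b)| reaches
    ``edge_threshold``.
    """
    from scipy.cluster.hierarchy import average, fcluster
    from scipy.spatial.distance import squareform

    module_genes = list(module_genes)
    if not 2 <= n_submodules <= len(module_genes):
        raise ValueError("need module size >= n_submodules >= 2")
    sub = expr.subset_genes(module_genes)
    corr = np.clip(np.corrcoef(sub.values), -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    linkage = average(squareform((dist + dist.T) / 2.0, checks=False))
    labels = fcluster(linkage, t=n_submodules, criterion="maxclust")

    submodules: dict[str, tuple[str, ...]] = {}
    eigengenes: dict[str, np.ndarray] = {}
    pos = {g: i for i, g in enumerate(module_genes)}
    for lab in sorted(set(labels)):
        genes = [g for g, l in zip(module_genes, labels) if l == lab]
        name = f"sub{lab}"
        submodules[name] = tuple(genes)
        z = _standardize(sub.values[[pos[g] for g in genes]])
        if len(genes) == 1:
            eig = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
            mean_profile = z.mean(axis=0)
            if mean_profile.std() > 0 and np.corrcoef(eig, mean_profile)[0, 1] < 0:
                eig = -eig
        norm = np.linalg.norm(eig)
        eigengenes[name] = eig / (norm if norm > 0 else 1.0)

    edges: list[tuple[str, str, float]] = []
    names = list(submodules)
    for a, b in combinations(names, 2):
        ea, eb = eigengenes[a], eigengenes[b]
        if ea.std() == 0 or eb.std() == 0:
            continue
        r = float(np.corrcoef(ea, eb)[0, 1])
        if abs(r) >= edge_threshold:
            edges.append((a, b, r))
    return EigenMoleculeNetwork(submodules, eigengenes, tuple(edges))
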