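"""Module detection on TOM dissimilarity and module--trait statistics.

Genes are clustered by average linkage on 1 - TOM and cut at a fixed
fraction of the tallest merge; clusters below the minimum size fall into
"grey" (unassigned), with one reassignment pass that lets a grey gene join
its nearest module when the mean dissimilarity is small enough.  This is a
deliberately simple stand-in for the recursive dynamic tree cut heuristic:
recovery of planted modules, not label equivalence with that algorithm, is
the contract (see docs/methods.md).

Module summaries follow the field's conventions: the module eigengene is
the first principal component of the module's standardised expression, the
module--trait association is the (point-biserial) Pearson correlation of
eigengene and 0/1 trait, gene significance (GS) is |cor(gene, trait)| and
module membership (MM) is |cor(gene, eigengene)|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform

from .io import Dendrogram, ExpressionMatrix, ModuleAssignment, TraitVector, GREY

logger = logging.getLogger("coexdiff")

__all__ = [
    "MODULE_COLORS",
    "ModuleEigengenes",
    "ModuleTraitTable",
    "GeneTraitStats",
    "cluster_samples",
    "detect_modules",
    "module_eigengenes",
    "module_trait",
    "gene_significance_mm",
    "select_key_modules",
]

# standard WGCNA colour sequence, assigned by descending module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


def _color_name(rank: int) -> str:
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module{rank + 1}"


def _standardize(values: np.ndarray) -> np.ndarray:
    """Z-score each row; zero-variance rows become all zeros."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mean) / sd


def cluster_samples(expr: ExpressionMatrix,
                    cut_height_quantile: float = 0.99,
                    ) -> tuple[Dendrogram, tuple[str, ...]]:
    """Flag outlier samples by average-linkage clustering on Euclidean distance.

    Genes are standardised first so no single high-variance gene dominates.
    The tree is cut at the given quantile of its merge heights — raised to a
    robust upper fence (median + 10 IQR of merge heights) so that trees
    whose top merges are all ordinary (homogeneous cohorts) are never cut —
    and only the largest resulting cluster is kept; removed samples are
    logged.
    """
    if expr.n_samples < 4:
        raise ValueError("need >= 4 samples to assess outliers")
    z = _standardize(expr.values)
    d = pdist(z.T, metric="euclidean")
    linkage = average(d)
    dend = Dendrogram(linkage, expr.sample_ids)
    heights = linkage[:, 2]
    q1, q3 = np.percentile(heights, [25, 75])
    fence = float(np.median(heights) + 10.0 * (q3 - q1))
    h = max(float(np.quantile(heights, cut_height_quantile)), fence)
    labels = fcluster(linkage, t=h, criterion="distance")
    counts = pd.Series(labels).value_counts()
    keep_label = counts.index[0]
    kept = tuple(s for s, l in zip(expr.sample_ids, labels) if l == keep_label)
    if len(kept) < 4:
        raise ValueError("largest sample cluster has < 4 samples; data too fragmented")
    removed = [s for s in expr.sample_ids if s not in set(kept)]
    if removed:
        logger.warning("removed %d outlier samples: %s", len(removed), removed[:10])
    return dend, kept


def detect_modules(dist: np.ndarray, gene_ids,
                   min_module_size: int = 30,
                   cut_fraction: float = 0.99,
                   reassign_threshold: float = 0.85,
                   ) -> tuple[Dendrogram, ModuleAssignment]:
    """Cut the gene tree on TOM dissimilarity into colour-labelled modules.

    Average-linkage clusters are formed below ``cut_fraction`` of the
    tallest merge; clusters smaller than ``min_module_size`` become grey.
    A single reassignment pass then moves each grey gene into the module
    minimising its mean dissimilarity, provided that mean is below
    ``reassign_threshold``.  Modules are named by colour in descending size
    order; equal-size modules are ordered by their lexicographically
    smallest member so repeated runs give identical labels.
    """
    gene_ids = tuple(gene_ids)
    n = len(gene_ids)
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n):
        raise ValueError("dissimilarity shape does not match gene ids")
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    linkage = average(squareform(dist, checks=False))
    dend = Dendrogram(linkage, gene_ids)
    h = cut_fraction * float(linkage[:, 2].max())
    raw = fcluster(linkage, t=h, criterion="distance")

    members: dict[int, list[int]] = {}
    for idx, lab in enumerate(raw):
        members.setdefault(int(lab), []).append(idx)
    kept = {lab: idxs for lab, idxs in members.items()
            if len(idxs) >= min_module_size}

    assignment_idx = np.full(n, -1, dtype=int)  # -1 = grey
    for lab, idxs in kept.items():
        assignment_idx[idxs] = lab
    if not kept:
        logger.warning("no cluster reached min_module_size=%d; all genes grey",
                       min_module_size)

    # one-pass nearest-module reassignment of grey genes
    grey_idx = np.nonzero(assignment_idx == -1)[0]
    if kept:
        labs = sorted(kept)
        for gi in grey_idx:
            means = [dist[gi, kept[lab]].mean() for lab in labs]
            best = int(np.argmin(means))
            if means[best] < reassign_threshold:
                assignment_idx[gi] = labs[best]

    # colour labels by descending size, tie-broken by smallest member gene id
    final_members: dict[int, list[int]] = {}
    for idx, lab in enumerate(assignment_idx):
        if lab != -1:
            final_members.setdefault(int(lab), []).append(idx)
    ordering = sorted(
        final_members.items(),
        key=lambda kv: (-len(kv[1]), min(gene_ids[i] for i in kv[1])),
    )
    color_of = {lab: _color_name(rank) for rank, (lab, _) in enumerate(ordering)}
    assignment = {
        g: (GREY if assignment_idx[i] == -1 else color_of[int(assignment_idx[i])])
        for i, g in enumerate(gene_ids)
    }
    return dend, ModuleAssignment(assignment)


@dataclass(frozen=True)
class ModuleEigengenes:
    """First-PC summary profile per module plus bookkeeping for tie-breaks."""

    sample_ids: tuple[str, ...]
    eigengenes: dict[str, np.ndarray]        # module -> unit-norm per-sample vector
    variance_explained: dict[str, float]
    module_sizes: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.eigengenes, index=list(self.sample_ids))


def module_eigengenes(expr: ExpressionMatrix,
                      modules: ModuleAssignment) -> ModuleEigengenes:
    """First principal component of each module's standardised expression.

    The eigengene is the first right singular vector over samples, scaled to
    unit norm, with its sign fixed so it correlates non-negatively with the
    module's mean expression profile.  Zero-variance genes are dropped with
    a warning.
    """
    eigengenes: dict[str, np.ndarray] = {}
    var_explained: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for label, genes in modules.modules().items():
        sub = expr.subset_genes(genes)
        sd = sub.values.std(axis=1)
        if np.any(sd == 0):
            drop = [g for g, s in zip(genes, sd) if s == 0]
            logger.warning("module %s: dropping %d zero-variance genes",
                           label, len(drop))
            genes = [g for g in genes if g not in set(drop)]
            sub = expr.subset_genes(genes)
        if len(genes) < 2:
            raise ValueError(f"module {label} has < 2 usable genes")
        z = _standardize(sub.values)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if mean_profile.std() > 0 and np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        eigengenes[label] = eig / np.linalg.norm(eig)
        var_explained[label] = float(s[0] ** 2 / np.sum(s ** 2))
        sizes[label] = len(genes)
    return ModuleEigengenes(expr.sample_ids, eigengenes, var_explained, sizes)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(1.0, p))


@dataclass(frozen=True)
class ModuleTraitTable:
    """Per-module eigengene--trait correlation with p-values and sizes."""

    table: pd.DataFrame  # index: module; columns: r, p, n_samples, n_genes

    def __post_init__(self) -> None:
        required = {"r", "p", "n_samples", "n_genes"}
        if not required <= set(self.table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")


def module_trait(me: ModuleEigengenes, traits: TraitVector) -> ModuleTraitTable:
    """Correlate each module eigengene with the binary trait (point-biserial)."""
    if tuple(traits.sample_ids) != tuple(me.sample_ids):
        raise ValueError("trait samples not aligned with eigengene samples")
    y = traits.labels.astype(float)
    if y.std() == 0:
        raise ValueError("trait is constant; correlation undefined")
    rows = []
    for label, eig in me.eigengenes.items():
        r, p = _pearson_with_p(eig, y)
        rows.append((label, r, p, len(y), me.module_sizes[label]))
    df = pd.DataFrame(rows, columns=["module", "r", "p", "n_samples", "n_genes"])
    return ModuleTraitTable(df.set_index("module"))


@dataclass(frozen=True)
class GeneTraitStats:
    """Gene significance, module membership and their per-module coupling."""

    gs: pd.Series                 # gene -> |cor(expr, trait)|
    mm: pd.Series                 # gene (non-grey) -> |cor(expr, eigengene)|
    gs_mm_correlation: dict[str, float]  # module -> cor(GS, MM) over members


def gene_significance_mm(expr: ExpressionMatrix, traits: TraitVector,
                         me: ModuleEigengenes, modules: ModuleAssignment,
                         signed: bool = False) -> GeneTraitStats:
    """Gene significance |cor(gene, trait)| and module membership |cor(gene, ME)|.

    With ``signed=True`` the raw correlations are returned instead of their
    absolute values.  Also reports, per module, the correlation between GS
    and MM over member genes — strongly positive for trait-linked modules.
    """
    traits = traits.aligned_to(expr)
    y = traits.labels.astype(float)
    z = _standardize(expr.values)
    yz = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    gs_vals = z @ yz / len(y)
    if not signed:
        gs_vals = np.abs(gs_vals)
    gs = pd.Series(gs_vals, index=list(expr.gene_ids), name="GS")

    mm_index: list[str] = []
    mm_vals: list[float] = []
    gs_mm: dict[str, float] = {}
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for label, genes in modules.modules().items():
        eig = me.eigengenes[label]
        ez = (eig - eig.mean()) / eig.std()
        rows = [gene_pos[g] for g in genes]
        mm_module = z[rows] @ ez / len(eig)
        if not signed:
            mm_module = np.abs(mm_module)
        mm_index.extend(genes)
        mm_vals.extend(mm_module.tolist())
        gs_module = gs.loc[genes].values
        if np.std(gs_module) > 0 and np.std(mm_module) > 0:
            gs_mm[label] = float(np.corrcoef(gs_module, mm_module)[0, 1])
        else:
            gs_mm[label] = float("nan")
    mm = pd.Series(mm_vals, index=mm_index, name="MM")
    return GeneTraitStats(gs, mm, gs_mm)


def select_key_modules(mt: ModuleTraitTable, alpha: float = 0.05,
                       allow_single: bool = False) -> tuple[str, str | None]:
    """Pick the most positively and most negatively trait-correlated modules.

    Both must be significant at ``alpha``.  Ties on r are broken by larger
    module size, then label order.  With ``allow_single`` a missing negative
    (or positive) slot returns None instead of raising.
    """
    df = mt.table.dropna(subset=["r"])
    if len(df) < 2 and not allow_single:
        raise ValueError("need >= 2 modules with finite trait correlation")
    sig = df[df["p"] < alpha]
    if sig.empty:
        raise ValueError(
            f"no module significant at p < {alpha}; review thresholds"
        )
    flat = sig.reset_index()
    pos_candidates = flat[flat["r"] > 0].sort_values(
        by=["r", "n_genes", "module"], ascending=[False, False, True],
        kind="mergesort",
    )
    neg_candidates = flat[flat["r"] < 0].sort_values(
        by=["r", "n_genes", "module"], ascending=[True, False, True],
        kind="mergesort",
    )
    if pos_candidates.empty:
        if not allow_single:
            raise ValueError("no significantly positively correlated module")
        positive = None
    else:
        positive = str(pos_candidates["module"].iloc[0])
    if neg_candidates.empty:
        if not allow_single:
            raise ValueError("no significantly negatively correlated module")
        negative = None
    else:
        negative = str(neg_candidates["module"].iloc[0])
    return positive, negative
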