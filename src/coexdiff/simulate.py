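"""Two-condition expression simulator with planted network structure.

The generator emulates a case--control transcriptomic design: blocks of
co-expressed genes (modules) driven by latent factors, a subset of modules
whose factor mean is shifted in the disease condition (trait-linked
modules), and gene pairs whose correlation flips sign between conditions
(the "oppositely correlated" pairs the differential-correlation stage is
built to find).

Model
-----
Each module m has a per-sample latent factor f_m ~ N(0, 1).  A gene g in
module m is

    x_g(s) = sqrt(rho) * f_m(s) + sqrt(1 - rho) * eps_g(s),  eps ~ N(0, 1)

so the expected within-module Pearson correlation is exactly rho
(lambda^2 / (lambda^2 + sigma^2) with lambda = sqrt(rho), sigma =
sqrt(1 - rho)).  Trait-linked modules add delta (in factor-SD units) to
f_m for disease samples.  Each planted switch pair (a, b) is carried by a
pair-private factor g_p: gene a loads +sqrt(rho) in both conditions while
gene b loads +sqrt(rho) in condition 1 and -sqrt(rho) in condition 2, so
the pair's expected correlation is +rho vs -rho and the sign flip is
confined to the planted pair.  Background genes are independent N(0, 1)
noise.

Default sizes (150 disease / 80 control samples) echo a typical sepsis
case--control cohort at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix, ModuleAssignment, TraitVector

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate",
    "score_module_recovery",
    "score_switch_recovery",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the planted-structure generator.

    ``module_sizes`` are the planted block sizes; genes beyond their sum are
    independent background.  ``rho`` is the expected within-module Pearson
    correlation, ``delta`` the disease-condition shift of trait-linked
    module factors in factor-SD units, ``n_samples`` the (disease, control)
    sample counts.
    """

    n_genes: int = 300
    module_sizes: tuple[int, ...] = (50, 50, 50, 50)
    rho: float = 0.7
    delta: float = 1.0
    n_samples: tuple[int, int] = (150, 80)
    trait_linked_modules: tuple[int, ...] = (1, 2)
    n_switch_pairs: int = 0
    switch_module: int = 1
    loading_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("each module needs >= 2 genes")
        n_modules = len(self.module_sizes)
        if any(not 1 <= m <= n_modules for m in self.trait_linked_modules):
            raise ValueError("trait_linked_modules must index planted modules (1-based)")
        if self.n_switch_pairs:
            if not 1 <= self.switch_module <= n_modules:
                raise ValueError("switch_module out of range")
            if 2 * self.n_switch_pairs > self.module_sizes[self.switch_module - 1]:
                raise ValueError("too many switch pairs for the module size")
        if min(self.n_samples) < 4:
            raise ValueError("need >= 4 samples per condition")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulation, for recovery scoring."""

    module_of_gene: dict[str, int]  # 0 = background
    trait_linked_modules: frozenset[int]
    switch_pairs: tuple[tuple[str, str], ...]
    params: SimulationParams

    def planted_labels(self, gene_ids) -> np.ndarray:
        return np.array([self.module_of_gene[g] for g in gene_ids])


def simulate(params: SimulationParams | None = None, *,
             seed: int | None = None,
             ) -> tuple[ExpressionMatrix, TraitVector, SyntheticTruth]:
    """Draw one two-condition expression dataset with planted structure.

    Returns the expression matrix (genes x samples, disease samples first),
    the 0/1 trait vector, and the :class:`SyntheticTruth` needed to score
    module and switch-pair recovery.  Fully reproducible: the same
    (params, seed) always yields bit-identical output.
    """
    if params is None:
        params = SimulationParams()
    if seed is not None:
        params = SimulationParams(**{**asdict(params), "seed": seed})
    rng = np.random.default_rng(params.seed)

    n1, n2 = params.n_samples
    n_samples = n1 + n2
    n_genes = params.n_genes
    condition = np.concatenate([np.ones(n1, dtype=int), np.zeros(n2, dtype=int)])

    gene_ids = tuple(f"G{i + 1:04d}" for i in range(n_genes))
    sample_ids = tuple(
        [f"D{i + 1:03d}" for i in range(n1)] + [f"H{i + 1:03d}" for i in range(n2)]
    )

    lam = np.sqrt(params.rho)
    sig = np.sqrt(1.0 - params.rho)

    module_of_gene: dict[str, int] = {g: 0 for g in gene_ids}
    # per-gene idiosyncratic noise; module rows rescale it below so every
    # gene keeps unit variance
    noise = rng.standard_normal((n_genes, n_samples))
    values = noise.copy()

    # assign module blocks contiguously from the front
    start = 0
    blocks: list[tuple[int, int, int]] = []  # (module index, start, stop)
    for m, size in enumerate(params.module_sizes, start=1):
        stop = start + size
        blocks.append((m, start, stop))
        for g in gene_ids[start:stop]:
            module_of_gene[g] = m
        start = stop

    # switch pairs claim the tail genes of their module: they ride a
    # pair-private factor instead of the module factor, with fixed loading
    # sqrt(rho) so the expected pair correlation is +rho vs -rho
    switch_pairs: list[tuple[str, str]] = []
    switch_genes: set[int] = set()
    if params.n_switch_pairs:
        _, blk_start, blk_stop = blocks[params.switch_module - 1]
        tail = list(range(blk_stop - 2 * params.n_switch_pairs, blk_stop))
        flip = np.where(condition == 1, 1.0, -1.0)
        for k in range(params.n_switch_pairs):
            ia, ib = tail[2 * k], tail[2 * k + 1]
            switch_genes.update((ia, ib))
            pair_factor = rng.standard_normal(n_samples)
            values[ia] = sig * noise[ia] + lam * pair_factor
            values[ib] = sig * noise[ib] + lam * pair_factor * flip
            switch_pairs.append((gene_ids[ia], gene_ids[ib]))

    # module factors; trait-linked modules alternate the sign of the
    # disease shift so the design contains both an up- and a down-regulated
    # module, as in a typical case--control cohort.  Per-gene loadings are
    # jittered around sqrt(rho) so members differ in how tightly they track
    # the factor, as real modules do.
    trait_sign = {
        m: (1.0 if rank % 2 == 0 else -1.0)
        for rank, m in enumerate(sorted(params.trait_linked_modules))
    }
    for m, blk_start, blk_stop in blocks:
        factor = rng.standard_normal(n_samples)
        if m in params.trait_linked_modules:
            factor = factor + trait_sign[m] * params.delta * condition
        rows = [i for i in range(blk_start, blk_stop) if i not in switch_genes]
        rho_g = params.rho * (
            1.0 + rng.uniform(-params.loading_jitter, params.loading_jitter,
                              size=len(rows))
        )
        rho_g = np.clip(rho_g, 0.0, 0.98)
        lam_g = np.sqrt(rho_g)[:, None]
        sig_g = np.sqrt(1.0 - rho_g)[:, None]
        values[rows] = sig_g * noise[rows] + lam_g * factor

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    traits = TraitVector(sample_ids, condition)
    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        trait_linked_modules=frozenset(params.trait_linked_modules),
        switch_pairs=tuple(switch_pairs),
        params=params,
    )
    return expr, traits, truth


def score_module_recovery(found: ModuleAssignment, truth: SyntheticTruth) -> float:
    """Adjusted Rand index between the found partition and the planted one.

    Background genes form their own planted class and grey its own found
    class, so leaving background unassigned scores as agreement.
    """
    genes = found.gene_ids
    if set(genes) != set(truth.module_of_gene):
        raise ValueError("gene universe mismatch between assignment and truth")
    planted = truth.planted_labels(genes)
    labels = [found.label_of(g) for g in genes]
    label_codes = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
    found_codes = np.array([label_codes[l] for l in labels])
    return float(adjusted_rand_score(planted, found_codes))


def score_switch_recovery(records, truth: SyntheticTruth,
                          lfdr_cut: float = 0.05) -> tuple[float, float]:
    """Recall and empirical FDR of flagged sign-switch pairs vs planted truth.

    A pair is flagged when ``switched`` is set and its lfdr is below the
    cut.  Recall is flagged-planted / planted; empirical FDR is
    flagged-non-planted / flagged (0 when nothing is flagged).
    """
    planted = {frozenset(p) for p in truth.switch_pairs}
    flagged = {
        frozenset((r.gene_a, r.gene_b))
        for r in records
        if r.switched and r.lfdr < lfdr_cut
    }
    if not planted:
        return (float("nan"), 0.0 if not flagged else 1.0)
    hits = len(planted & flagged)
    recall = hits / len(planted)
    fdr = 0.0 if not flagged else (len(flagged) - hits) / len(flagged)
    return (float(recall), float(fdr))
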