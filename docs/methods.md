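# Methods

This note documents the statistical machinery in `coexdiff`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the places where the design was genuinely open.

## Network construction

The pipeline assumes a gene × sample matrix of log-scale expression with
finite entries (missing values resolved at read time: drop the gene, or
impute its row mean). Correlation is plain Pearson; network construction
is *unsigned* (S_ij = |cor|), so positively and negatively co-regulated
genes land in the same module. The soft threshold a_ij = S_ij^β keeps the
network weighted while suppressing weak correlations.

**Scale-free fit.** For each candidate β (default 1..20) the connectivity
k_i = Σ_{j≠i} a_ij is computed, k values are split into 10 equal-count
bins, and log10 of the *width-normalised* bin frequency (an empirical
density of k) is regressed on log10 of the bin mean. The fit index is the
R² of that line, reported as 0 unless the slope is negative. Equal-count
bins are robust to the heavy right tail of k; the width normalisation is
what makes them informative — raw equal-count frequencies are constant by
construction. The smallest β reaching the target R² (default 0.80) wins;
if none does, the best-fitting β is returned with a warning. When the
user skips selection entirely the documented default is β = 5, the power
reported for the GSE134347 sepsis cohort (R² = 0.81). Note this is a
plain R² with a sign gate, not the signed-R² variant some tools report;
the two agree whenever the slope is negative.

**Topological overlap.** TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
with l_ij = Σ_u a_iu a_ju. Two conventions are ambiguous in the usual
formula and fixed here: k_i excludes the self-adjacency (diagonal) term,
and the l_ij sum runs over u ∉ {i, j} — including the endpoints can push
TOM above 1. The diagonal is set to 1 by convention. An isolated gene
(zero adjacency row) has a zero TOM row; a fully connected unit adjacency
gives TOM ≡ 1. Computation is blocked over rows (configurable block
size) to bound memory; the result is block-size invariant and matches a
triple-loop evaluation to 1e-12 on random matrices. The clustering
dissimilarity is 1 − TOM with a zero diagonal.

## Sample QC

Samples are clustered by average linkage on Euclidean distance of
per-gene standardised expression. The tree is cut at the
`cut_height_quantile` (default 0.99) of merge heights, **raised to a
robust fence of median + 10·IQR of the merge heights**, and only the
largest cluster is kept. The fence is the load-bearing part: in a
homogeneous cohort the top merges are tightly packed, so a bare quantile
cut would always shed a few ordinary samples; the fence ensures that only
merges that are genuine height outliers (e.g. a sample shifted by many
SDs on all genes) are ever cut. `cut_height_quantile=1.0` disables QC.

## Module detection

Genes are clustered by average linkage on 1 − TOM and cut at
`cut_fraction` (default 0.99) of the tallest merge. Clusters below
`min_module_size` (default 30) fall into "grey"; a single reassignment
pass then lets each grey gene join the module minimising its mean
dissimilarity if that mean is below 0.85. Modules are named by the
conventional colour sequence (turquoise, blue, brown, …) in descending
size order, with equal-size ties ordered by the lexicographically
smallest member id, so repeated runs are label-identical.

This is a deliberately simple static-cut approximation of the recursive
dynamic tree cut heuristic: the contract is recovery of planted module
structure (adjusted Rand index ≥ 0.9 on the default simulation), not
label equivalence with the published algorithm. Module merging by
eigengene similarity is *not* performed.

**Eigengenes.** Each module's genes are standardised; the eigengene is
the first right singular vector over samples (unit norm), sign-fixed to
correlate non-negatively with the module mean profile; the variance
explained by it is reported. Module–trait association is the Pearson
(point-biserial) correlation of eigengene and 0/1 trait, with the
two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df. Gene significance
GS = |cor(gene, trait)| and module membership MM = |cor(gene, eigengene)|
(signed variants behind a flag). Key-module selection takes the most
positive and most negative significant r (p < 0.05), ties broken by
module size, then label.

## Differential correlation

Correlations here are **signed** — the one deliberate convention split
from the unsigned network stage, because sign switches are the object of
study. For each gene pair in a module, r₁ and r₂ are the per-condition
Pearson correlations (|r| clamped at 1 − 1e-7 before atanh, with a
warning), and

    Z = (atanh r₁ − atanh r₂) / sqrt(1/(n₁−3) + 1/(n₂−3))

with a two-sided N(0,1) p. Per-condition correlation p-values use the
t transform above. No p-value or lfdr is ever printed as a hard zero;
everything is floored at 1e-300.

**Local FDR.** Estimated per module (not pooled across modules), from
the module's Z collection: a 120-bin histogram over the data range is
smoothed by a Poisson log-linear fit on a 7-function cubic B-spline
basis, giving the marginal density f̂(z); the null is the theoretical
N(0,1) density φ. π₀ = min(1, median of φ(z)/f̂(z) over the central half
of the data), and lfdr(z) = min(1, π₀ φ(z)/f̂(z)), made monotone
non-increasing in |z| by isotonic regression. With fewer than 50 values,
or a degenerate histogram, the estimate falls back to BH q-values of the
normal p-values with a logged notice; below 200 values a stability
warning is emitted. BH q-values are always computed alongside as a
cross-check. Calibration, verified in the test suite: on 5000 pure-null
z-values essentially nothing reaches lfdr < 0.05, while >90% of a 5%
component shifted to z = 6 does.

A pair is a significant sign switch when lfdr < `lfdr_cut` (default
0.05) *and* r₁·r₂ < 0. Records are sorted by (lfdr, |Z| desc, pair id)
for diff-stable output. The eigen-molecule view groups a module's genes
by average linkage on 1 − signed correlation into a requested number of
submodules, summarises each by its eigengene and connects submodules
with |cor| above a threshold (default 0.3).

## Downstream

Differential expression is the pooled-variance two-sample t-test
(literal "Student's t"; Welch behind a flag, advisable when group
variances differ), BH-adjusted, significant at adjusted p < 0.05.
Zero-variance genes get p = 1 when group means agree, else a floored
near-zero p with a warning. Enrichment is database-free hypergeometric
over-representation of a query list in user-supplied GMT sets
(upper-tail P(X ≥ k), BH across sets, cutoff 0.05); sets are intersected
with the universe first. Hub ranking counts degrees over the unique
significant switched pairs; ties are broken by the summed correlation
reversal Σ|r₁ − r₂| over incident edges — rewarding stronger rewiring —
then by gene id.

## Synthetic data

The generator emulates a case–control cohort at desk scale. Defaults:
300 genes, four 50-gene modules, within-module correlation ρ = 0.7,
150 disease / 80 control samples (echoing a 156/82 sepsis cohort),
two trait-linked modules with shift δ = 1.0 factor-SD.

Each module m has a latent factor f_m ~ N(0,1) per sample; member gene g
is x_g = λ_g f_m + √(1−ρ_g) ε with λ_g = √ρ_g, so its expected
within-module correlation with a peer h is λ_g λ_h ≈ ρ. Per-gene ρ_g is
jittered uniformly by ±20% (relative) around ρ: real modules are not
exchangeable — members differ in how tightly they track the shared
signal — and this heterogeneity is what makes gene significance and
module membership co-vary across a trait-linked module's members. The
jitter biases the mean pairwise correlation by < 0.4% of ρ.

Trait-linked modules add ±δ to their factor for disease samples, with
the sign alternating across trait-linked modules so the design always
contains both an up- and a down-regulated module — without the
alternation no negatively trait-correlated module could exist and
key-module selection would have nothing to select on the negative side.

Planted switch pairs ride **pair-private factors**: gene a loads +√ρ in
both conditions, gene b +√ρ in condition 1 and −√ρ in condition 2, so
the pair's expected correlation is +ρ vs −ρ and the flip is confined to
the planted pair. (Flipping a gene's module-factor loading instead would
flip its correlation with every module member, making "false positives"
out of dozens of genuinely rewired but unplanted pairs.) The trade-off
is that switch-pair genes do not co-express with their nominal module,
so module *detection* does not place them there; switch-pair recovery is
therefore evaluated by scanning the planted gene set directly.

What the generator does **not** emulate: probe effects, batch structure,
heteroscedastic or non-Gaussian noise, correlated background genes, or
covariate-driven confounding. Passing tests demonstrate that the
machinery recovers the structure it is built to find under clean
Gaussian factor structure at realistic sample sizes — not that it is
robust to array-specific artefacts.

## Numerical and reproducibility notes

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; the same (parameters, seed) reproduces
  bit-identical matrices and byte-identical pipeline outputs, and
  `run_manifest.json` records per-file sha256 checksums to prove it.
- Matrix symmetry is enforced by averaging with the transpose and
  clipping to the valid range; validation tolerances are 1e-12.
- Degenerate inputs (constant genes, constant traits, < 4 samples per
  condition, empty modules) raise early with the offending identifiers
  named rather than propagating NaNs.
- Default problem sizes in the tests and acceptance measurements (300
  genes, 230 samples, 10 replicate seeds for recovery statistics, 2000
  pairs × 10 seeds for type-I error) were chosen as the smallest designs
  at which the recovery and calibration properties are stable.

## Known limitations

- Static-cut module detection will fragment or miss modules with strongly
  nested correlation structure that the recursive dynamic cut resolves.
- The lfdr density fit needs a few hundred statistics to be stable; small
  modules silently get the more conservative BH fallback (flagged in the
  diagnostics).
- Only two conditions and a single binary trait are supported; no
  time-course designs, no covariate adjustment, no signed or bicor
  network variants.
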