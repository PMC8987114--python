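# coexdiff

Weighted gene co-expression networks with differential-correlation
analysis for two-condition expression studies.

`coexdiff` is aimed at transcriptomics analysts working with case–control
expression matrices (e.g. disease vs healthy cohorts profiled on arrays or
RNA-seq) who want to go beyond differential expression: it finds groups of
co-expressed genes associated with the condition, then hunts inside those
groups for gene **pairs whose correlation flips sign between conditions** —
a signature of rewired regulation that per-gene statistics cannot see —
and ranks the hub genes of the resulting rewiring network.

## Method

**Stage 1 — weighted co-expression network.** From a genes × samples
matrix X, compute the unsigned correlation S_ij = |cor(X_i, X_j)|, raise
it to a soft-threshold power β (chosen so the connectivity distribution is
approximately scale-free; a_ij = S_ij^β), and convert the adjacency to the
topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_u a_iu a_ju  (u ∉ {i, j}),   k_i = Σ_{j≠i} a_ij.

Genes are clustered by average linkage on 1 − TOM and cut into modules
(minimum size 30). Each module is summarised by its eigengene (first
principal component of the standardised module expression), correlated
with the 0/1 trait, and the most positively and most negatively
trait-correlated modules are selected.

**Stage 2 — differential correlation.** Within each selected module every
gene pair is tested for a change of correlation between conditions with
Fisher's z: z_k = atanh(r_k), Z = (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)).
Significance is assessed by an empirical-Bayes **local false discovery
rate** over the module's Z statistics (lfdr < 0.05), with BH q-values
reported alongside. Pairs that are significant *and* change sign
(r₁·r₂ < 0) form the sign-switch network; its highest-degree nodes are the
candidate master regulators.

A synthetic-data module generates two-condition matrices with planted
modules, trait-linked modules and planted sign-switch pairs, so the whole
pipeline is testable without any download.

## Worked example

Simulate a 300-gene, 230-sample cohort (150 disease / 80 control, four
planted modules, two trait-linked) and run the full pipeline:

```sh
coexdiff simulate --out-dir data --seed 1
coexdiff run-all --expression data/expression.tsv \
                 --traits data/traits.tsv --out-dir results --seed 1
```

`results/module_trait.tsv` then holds the module–trait associations:

```
module      r              p               n_samples  n_genes
turquoise    0.4181383374  3.78485042e-11  230        50
blue        -0.3884909601  1.05416137e-09  230        50
brown        0.1185002473  0.07286445784   230        50
yellow       0.01826181982 0.7829565371    230        50
```

The two planted trait-linked modules surface as the top positive
(turquoise, r = 0.42) and top negative (blue, r = −0.39) modules; the two
neutral modules are non-significant. The pipeline then scans both key
modules for differential correlations and writes `diffcorr_*.tsv`,
`switched_pairs.tsv`, `hubs.tsv`, `dge.tsv` and a `run_manifest.json` with
per-file checksums (rerunning with the same seed reproduces every file
byte for byte).

The differential-correlation engine can also be driven directly. With ten
sign-switch pairs planted in a 50-gene module (ρ = 0.6, n = 150/80):

```python
import coexdiff as cd

params = cd.SimulationParams(n_genes=50, module_sizes=(50,), rho=0.6,
                             n_samples=(150, 80), trait_linked_modules=(),
                             n_switch_pairs=10, seed=1)
expr, traits, truth = cd.simulate(params)
cond1, cond2 = cd.split_by_condition(expr, traits)
table = cd.diffcorr_scan(cond1, cond2, expr.gene_ids)
flagged = cd.switched_pairs(table, lfdr_cut=0.05)
recall, fdr = cd.score_switch_recovery(table.records, truth)
```

which prints, for seed 1:

```
10 significant sign-switch pairs (recall 1.00, empirical FDR 0.00)
G0031-G0032: r1=+0.62 r2=-0.68 z=+11.0 lfdr=7.17e-26
G0033-G0034: r1=+0.69 r2=-0.59 z=+10.8 lfdr=1.05e-24
G0035-G0036: r1=+0.66 r2=-0.59 z=+10.4 lfdr=5.02e-22
top hubs: ['G0031', 'G0032', 'G0033', 'G0034']
```

All ten planted pairs are recovered at lfdr < 0.05 with no false flags;
each flagged pair's correlation is strongly positive in the disease
samples and strongly negative in the controls (or vice versa), and the
hub ranking points straight at the genes carrying the rewiring.

## Layout

| module                 | contents                                              |
|------------------------|-------------------------------------------------------|
| `coexdiff.io`          | domain types, TSV/GMT readers, edge-TSV/GraphML export |
| `coexdiff.simulate`    | planted-structure generator and recovery scoring      |
| `coexdiff.network`     | correlation, adjacency, scale-free fit, TOM           |
| `coexdiff.modules`     | sample QC, module detection, eigengenes, GS/MM        |
| `coexdiff.diffcorr`    | Fisher z, local FDR, pair scan, eigen-molecule graph  |
| `coexdiff.downstream`  | t-test DGE, BH, hypergeometric enrichment, hub ranks  |
| `coexdiff.config`/`cli`| YAML config, orchestration, manifest, subcommands     |

See `docs/methods.md` for the statistical details and design choices.
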