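# Methods

## Model and assumptions

`paretoselect` casts differential-expression screening as a multiple-criteria
optimization over genes. Each gene is represented by *C* performance
measures in minimization sense; the output is the Pareto-efficient frontier —
the genes for which no competitor is at least as good on every measure and
strictly better on one. The method is nonparametric and comparison-based: it
assumes nothing about the distribution of expression values, requires no
normalization across criteria (criteria may be in incommensurate units, as
in a meta-analysis over independent studies), and has no tunable
significance threshold. Its implicit assumptions are:

* the stored expression matrix is used as-is (no background correction, log
  transform or batch adjustment is applied — whatever preprocessing produced
  the file defines the units);
* group statistics (mean, median) computed over the available samples are
  meaningful summaries, which requires at least two non-missing values per
  gene per group (genes failing this are excluded and reported);
* "most changed" is captured by the absolute difference of a group statistic
  between two conditions. Direction of change is deliberately discarded.

Focusing on the frontier minimizes false positives at the cost of false
negatives: a truly changed gene can be nudged off the frontier by
experimental error. Peeling consecutive frontiers (remove the frontier,
recompute on the remainder) is the provided mitigation; layer indices are
reported so users can widen the candidate list in a principled order.

## The penalty-matrix computation

For criterion *k* the pairwise matrix δ^k holds −1 / 0 / W for win / tie /
loss of gene *i* against *j* (W an integer penalty, default 1000; validated
W > C so that a mixed record p·W − q, q ≤ C, can never collide with a
multiple of W). The sum α over criteria is a nonnegative multiple of W
exactly for the "tied-or-worse everywhere" pairs that witness (weak)
dominance; such entries score γ = (C/2)·W, a total loss (α = C·W) scores
C·W, everything else 0. Row sums β, diagonal included, then satisfy:

* β floor: βᵢ ≥ (C/2)·W, with equality iff no gene is tied-or-worse-everywhere
  against *i* other than itself;
* membership: gene *i* is on the frontier iff βᵢ < C·W iff βᵢ = (C/2)·W.

Two successive "tied-or-worse" events (the self term plus any real one)
already reach C·W, which is why the (C/2)·W constant is the unique choice
that makes the C·W cutoff meaningful for any C ≥ 2 while reducing to the
two-criteria special case (γ = W for α ∈ {0, W}, 2W for α = 2W).

Numerical choices:

* δ/α are int64; γ/β are carried internally in doubled integer units so
  (C/2)·W stays exact for odd C. No floating-point comparison enters the
  membership test.
* Ties require exact equality by default. An optional tolerance `tol`
  (|mᵢ − mⱼ| ≤ tol counts as a tie) exists for noisy criteria but is off by
  default, since raw stored values are compared.
* β is computed in row chunks (≤ 2²⁴ matrix elements at a time), so the full
  n×n matrices are never materialized; a 22k-probe table runs in a few
  hundred MB.
* Up to five criteria per analysis are accepted at the criteria-building
  layer; the core computation itself is not limited.

### Duplicates

Genes with exactly identical criteria vectors cannot strictly dominate each
other, so classical Pareto conditions retain them; the raw penalty scheme,
however, scores each pair member γ = (C/2)·W against the other, pushing the
whole group past the cutoff. Default behavior collapses exact duplicates to
one representative before the computation, restores all members in the
output and reports the duplicate groups; `collapse_duplicates=False` (CLI
`--strict-duplicates`) reproduces the raw exclusion. The default is
preferred because dropping a nondominated gene merely for having a twin
discards a valid candidate.

### Tournament partitioning and β provenance

`tournament_frontier` splits the table into consecutive blocks, solves each
locally, pools the local winners and re-solves the pool. Because dominance
by a pool member implies dominance by some local winner, membership equals
the direct computation for every partition size and input order (tested
property). The β values reported for eliminated genes refer to their local
block and those for pool members to the final pool; frontier members always
show β = (C/2)·W regardless. With duplicate collapsing off, duplicate
groups split across blocks may escape the raw mutual exclusion, so strict
mode should be used with the direct path.

## Criteria construction

One criterion per (contrast, statistic): the absolute difference of the
group mean or median (even-count median = midpoint of the two central order
statistics) between two disjoint sample groups, negated so larger changes
rank better. Negation is used as the minimization transform because the
frontier is invariant under any strictly decreasing per-column transform
(tested property), and negation keeps the values interpretable. Statistics
are computed over non-missing entries; genes with fewer than two usable
values in any group of any contrast are excluded and listed. Probes are
never collapsed to gene symbols — the analysis runs at row level and symbols
are carried for reporting only.

## Synthetic data generator

`generate_dataset` emulates a curated two-condition microarray study:
i.i.d. background around `baseline` (default 8.0 expression units) with
`noise_sd` (default 1.0), group sizes defaulting to 15 control / 16 cancer
samples (the never-smoker arm sizes of the lung-cancer study this package
targets), GDS-style annotations (disease state, smoking status, gender) and
`n_planted` large-effect genes (default 5 at `effect_size` 10·noise_sd).

Planted effects are spread along a mean-versus-median tradeoff: planted gene
*p* receives a uniform shift (median shift) interpolating 1.5×→0.5×
`effect_size` and a compensating offset on a sub-median minority of shifted
samples that moves the group mean the opposite way (0.5×→1.5×), keeping the
average of the two shifts at `effect_size`. This makes the planted set
mutually nondominated by construction — the tradeoff situation the frontier
method exists for — so for effects well clear of the noise the first
frontier of a mean+median analysis is exactly the planted set. A uniform
shift would instead make the planted genes near-duplicates in criteria
space, letting sampling noise decide dominance among them.

The generator does **not** simulate probe-level microarray artifacts
(hybridization efficiency, batch effects, intensity-dependent variance) or
correlation between genes; passing recovery tests therefore demonstrates the
selection machinery, not robustness to real-array noise structure. A
log-normal background option exercises the mean/median divergence that makes
the two single-study criteria genuinely conflict.

Problem sizes used in the shipped tests (500 genes × 31 samples × 20 seeds
for recovery; random tables up to n = 200–300 for oracle and invariance
sweeps) were chosen as the smallest sizes at which the tested properties are
nondegenerate; all scale linearly in memory via chunking.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `penalty` (W) | 1000 | — | integer penalty; any W > C gives identical frontiers, the default follows the method's standard setting |
| `n_layers` | 1 | — | consecutive frontiers to peel |
| `partition_size` | None | genes | tournament block size; None = direct chunked computation |
| `collapse_duplicates` | True | — | retain nondominated exact duplicates |
| `tol` | 0.0 | expression units | optional tie tolerance |
| `statistic` | median | — | per-contrast group statistic (single-study runs use mean **and** median) |

## Design choices and limitations

* **Estimator shape.** The computation is exposed as scikit-learn-style
  estimators (`ParetoFrontierFinder.fit(X)` with `frontier_mask_`, `beta_`,
  `layers_`; `ContrastCriteria` as a transformer) so frontier selection
  composes with sklearn tooling; module-level functions wrap them for
  script use.
* **W does not scale with n.** The membership test compares β against C·W
  and every γ contribution is a multiple of W/2, so the logic is independent
  of the number of genes; no scaling is applied.
* **GDS vocabulary.** Subset types and descriptions are normalized
  (lower-cased, trimmed, separators unified) before filtering; the shipped
  `GDS3257_GROUPS` table maps the HNS/HCS/CNS/CCS shorthand to annotation
  filters and may need adjustment if GEO revises the curated labels. Former
  smokers are retained by the reader but selected by no shipped group.
* **Exact reproduction of published gene lists** from GDS3257 depends on
  using the same stored value matrix; frontier sizes are asserted, gene
  identities are soft-checked.
* The frontier says nothing about statistical significance or effect
  direction; it is a screening device whose output should feed confirmatory
  analysis.
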