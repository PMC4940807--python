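# paretoselect

Pareto-efficient frontier selection of highly differentially expressed genes.

## The problem

Ranking genes by a single score (a fold change, a *p*-value) forces an
arbitrary weighting whenever several legitimate measures of expression change
disagree. `paretoselect` instead treats differential-expression screening as
a multiple-criteria optimization (MCO) problem: each gene *g&#7522;* is scored
on *C* conflicting performance measures *m&#7522;¹, …, m&#7522;^C* — for a
single two-group study, the absolute difference of group **means** and of
group **medians** between control and disease samples; for a meta-analysis,
one absolute **median** difference per independent contrast, up to five in
one run. Differences are negated so every criterion is minimized, and the
genes reported are those on the **Pareto-efficient frontier**: no other gene
is at least as good on every criterion and strictly better on one. No
normalization, weighting, user threshold or distributional assumption is
involved, so results are reproducible across analysts. It is aimed at
transcriptomics researchers screening curated expression matrices (e.g. GEO
GDS datasets) for candidate biomarkers.

## The method

The frontier is found by an exact full pairwise comparison scheme. For each
criterion *k*, an *n*×*n* matrix δ^k is built:

    δᵢⱼᵏ = −1  if mᵢᵏ < mⱼᵏ
            0  if mᵢᵏ = mⱼᵏ
            W  if mᵢᵏ > mⱼᵏ        (W: integer penalty, default 1000)

The sum αᵢⱼ = Σₖ δᵢⱼᵏ is a nonnegative multiple of *W* exactly when gene *i*
is tied-or-worse than *j* on **every** criterion. Those entries map to
γᵢⱼ = (C/2)·W — or C·W when *i* is strictly worse everywhere (αᵢⱼ = C·W) —
and all other entries to 0. With row sums βᵢ = Σⱼ γᵢⱼ (the self term
γᵢᵢ = (C/2)·W included), the frontier is

    gᵢ* = { gᵢ : βᵢ < C·W }

i.e. membership cutoff 2000 for two criteria at W = 1000; frontier members
have βᵢ = (C/2)·W exactly. The computation is row-chunked (memory
O(chunk·n)), and a tournament mode partitions large tables, pools local
winners and re-solves the pool — provably the same frontier for any
partitioning or input order. Successive frontiers can be "peeled" (remove
the frontier, recompute) to soften false negatives due to experimental
noise, and an independent brute-force dominance oracle is included for
verification.

## Worked example

The canonical six-gene, two-criteria table g1(1,4), g2(3,4), g3(5,6),
g4(7,5), g5(3,2), g6(4,1) ships with the package:

```python
from paretoselect import worked_example, pareto_frontier

table = worked_example()
result = pareto_frontier(table, W=1000)
print("frontier:", result.frontier_ids)
print(result.beta.to_string())
```

prints

```
frontier: ['g1', 'g5', 'g6']
g1    1000.0
g2    3000.0
g3    9000.0
g4    9000.0
g5    1000.0
g6    1000.0
```

g1, g5 and g6 sit at the β floor (C/2)·W = 1000 — nothing is at least as
good as them everywhere — and pass the cutoff C·W = 2000; g2 (tied-or-worse
than g1 on both criteria) and the dominated g3, g4 do not.

The same analysis from the shell, via the estimator-style API's CLI wrapper:

```sh
$ paretoselect frontier --criteria-tsv criteria.tsv --out report.tsv
n=6 alternatives, C=2 criteria, W=1000, membership cutoff CW=2000
beta: min=1000 median=2000 max=9000
layer 0: 3 alternatives (g1, g5, g6)
report written to report.tsv
```

For expression data, `paretoselect frontier --input GDS3257.soft --format
soft --group-a "disease state=control" --group-a "stress=never smoked"
--group-b "disease state=lung cancer" --group-b "stress=never smoked" --out
report.tsv` builds the mean+median criteria from a GEO SOFT file and reports
the frontier; `paretoselect meta` runs a 2–5-contrast meta-analysis, and
`paretoselect simulate` generates synthetic data with planted large-effect
genes. The scikit-learn-style classes (`ParetoFrontierFinder`,
`ContrastCriteria`) expose the same computations programmatically with
`fit`/`transform`, `get_params` and fitted `_`-suffixed attributes.

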