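# mirmint

Integrated miRNA–mRNA expression analysis for two-channel tumor
cohorts: exact **TNoM** differential expression, exact
**minimum-hypergeometric (mHG)** ranked-list enrichment, and a
**pivot-miRNA** framework that links miRNAs to biological processes
through the genes correlated (or anti-correlated) with them.

## Who this is for

Researchers analyzing paired miRNA/mRNA expression matrices (e.g.
breast-tumor microarray cohorts with intrinsic-subtype, TP53, ER and
proliferation annotations) who want distribution-free exact statistics
rather than parametric approximations, plus a fully synthetic cohort
generator with planted ground truth for validating every step.

## The statistics

**TNoM** (Threshold Number of Misclassifications) scores a feature by
the minimum number of samples misclassified by the best single
expression threshold over both orientations. Its p-value,
P(TNoM ≤ k), is computed exactly over all C(N, n1) equiprobable label
arrangements by lattice-path counting — no asymptotics, no
permutation sampling. Differential-expression tables report k, exact
p, Welch t-test p, log2 fold change and Benjamini–Hochberg q.

**mHG** tests whether a gene set H concentrates at the top of a
ranked gene list. With λ_i = 1 iff the i-th ranked gene is in H and
b_n = Σ_{i≤n} λ_i,

    s = min_{1≤n≤N} HGT(b_n; N, B, n),   HGT(b; N, B, n) = P(X ≥ b),

X hypergeometric. The exact p-value P(mHG ≤ s) is computed by dynamic
programming over the (n, b) lattice, so the optimization over all
prefix cuts is corrected for exactly.

Ranked lists come from three schemes: (A) differential-expression
score, (B) Spearman correlation to a pivot miRNA across the cohort,
and (C) predicted-targeting (context) score — e.g. a pivot's top 2000
predicted targets tested for enrichment among its anti-correlatees,
the signature of direct repression. Scheme B in both orientations
yields a signed miRNA × gene-set association matrix (±log10 p) and a
concordance analysis against differential expression.

## Worked example

Simulate a cohort with 8 subtype-differential miRNAs planted at 2
noise-SD and 50 anti-correlated targets of one pivot, run the standard
pipeline (replicate averaging → detection filter → 75th-percentile
normalization → log2), and test both analyses:

```python
from mirmint import (CohortConfig, PlantedDE, TargetSpec, generate_cohort,
                     generate_target_table, differential_expression_table,
                     target_anticorrelation_enrichment, replicate_groups)
from mirmint.preprocess import preprocess_mirna
from mirmint.io import annotations_to_frame

config = CohortConfig(
    n_samples=80, n_mirna=300, n_mrna=2000, replicates=2,
    subtype_proportions={"basal-like": 0.5, "luminal-A": 0.5},
    planted_de=[PlantedDE(8, 2.0, "up", ("subtype", "basal-like", "luminal-A"))],
    target_spec=TargetSpec(pivot=0, n_targets=50, rho=-0.5),
    seed=1,
)
mirna, mrna, annotations, truth = generate_cohort(config)
mi = preprocess_mirna(mirna, replicate_groups(mirna))
mr = preprocess_mirna(mrna)
ann = annotations_to_frame(annotations)
basal = ann.index[ann.subtype == "basal-like"].tolist()
luminal = ann.index[ann.subtype == "luminal-A"].tolist()

table = differential_expression_table(mi, basal, luminal)
print(table.head(5).to_string(index=False))

targets = generate_target_table(truth, seed=1)
pivot_id = truth.target_pairs[0][0]
res = target_anticorrelation_enrichment(pivot_id, mi.feature_vector(pivot_id),
                                        mr, targets)
print(f"{pivot_id}: mHG s={res.s:.3g} at n*={res.n_star}, p={res.p_exact:.3g}")
```

prints

```
feature_id  k       tnom_p          t_p  log2_fc direction            q
  miR-0145  9 4.421988e-12 1.288615e-13 2.090516        up 6.632982e-10
  miR-0231  9 4.421988e-12 8.283828e-16 2.255597        up 6.632982e-10
  miR-0019 10 3.139612e-11 4.005343e-11 1.652877        up 1.883767e-09
  miR-0096 10 3.139612e-11 3.829083e-17 2.488353        up 1.883767e-09
  miR-0197 10 3.139612e-11 5.982861e-12 2.150577        up 1.883767e-09

miR-0001: mHG s=1.22e-68 at n*=45, p=2.6e-67
```

The top rows are planted miRNAs: each needs at least 9 misclassified
samples at the best threshold in this 39-vs-41 contrast, with exact
p ≈ 4e-12 and q well under 0.05 (all 8 planted features are recovered
at q < 0.05). The enrichment line says 44 of the pivot's top-ranked
targets sit among its 45 strongest anti-correlatees, an arrangement
with exact probability ~1e-67 under the null — the planted
miRNA→target repression is unmistakable.

All of this is also available from a shell via the `mirmint` CLI
(`simulate`, `preprocess`, `de`, `enrich`, `pivot`, `pivot-matrix`,
`target-enrich`, `classify`, `lma`); run `mirmint --help`.

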