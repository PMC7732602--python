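# methylclass

Classification of tumor subtypes from DNA-methylation profiles, built around
the feature-selection protocol used for methylation-based glioblastoma (GBM)
subtyping: Monte Carlo feature selection (MCFS) over beta-value matrices,
incremental feature selection (IFS) with three classifier families scored by
the multiclass Matthews correlation coefficient (MCC), evaluation on an
independent cohort, probe→gene mapping, and hypergeometric functional
enrichment of the selected genes.

The package is aimed at computational epigenomics work where the input is a
probes × samples matrix of beta values (methylation fractions in [0, 1],
e.g. from an Illumina 450K array), a sample → subtype label table, and a
probe → gene annotation manifest. A synthetic-cohort generator with planted
differentially methylated probes provides ground truth for validating every
stage.

## The method

**MCFS ranking.** With `M` probes, draw `s` random projections of
`m ≪ M` probes; on each projection grow `t` decision trees, each on a
stratified bootstrap of the samples (information-gain splits on beta-value
thresholds). A probe `g` is scored by its relative importance

```
RI_g = Σ_τ (wAcc_τ)^u · Σ_{n_g(τ)} IG(n_g(τ)) · ( no.in n_g(τ) / no.in τ )^v
```

summing over all `s·t` trees τ and all nodes `n_g(τ)` that split on `g`;
`IG` is the split's information gain, the fraction term weights a node by
the samples reaching it, and `wAcc` (the tree's weighted accuracy — mean
per-class recall on the bootstrap's held-out samples) weights the whole
tree. `u = v = 1` by default. Probes are ranked by decreasing RI.

**IFS sweep.** Nested top-k prefixes of the ranking (k = 10, 20, 30, …)
are each scored by stratified 10-fold cross-validation with three
classifiers — a one-vs-rest SVM (polynomial kernel, degree 1, C = 1), a
10-tree random forest, and a RIPPER-style sequential-covering rule learner
(rarest class first, most frequent class as fall-through default). The
prefix with maximal multiclass MCC is the optimal feature subset per family
(ties go to the smaller subset); the optimal classifier can then be scored
once on an independent test cohort.

**Enrichment.** Optimal probes are mapped to gene symbols through the
annotation manifest and tested for over-representation in user-supplied
gene-set collections (GMT) with the hypergeometric upper tail
P(X ≥ k), BH-FDR adjusted per namespace at α = 0.05.

## Worked example

```python
from methylclass import (
    ClassifierSpec, MCFSConfig, default_training_design, generate_cohort,
    ifs_sweep, run_mcfs,
)

cohort = generate_cohort(default_training_design(seed=1))   # 347 samples, 7 subtypes, 2000 probes
ranking = run_mcfs(cohort.matrix, cohort.labels, MCFSConfig(s=400, t=2, seed=1))

truth = cohort.truth_probes()                               # 70 planted probes
print(f"truth probes in top 200: {len(truth & set(ranking.top(200)))}/70")

result = ifs_sweep(
    cohort.matrix, cohort.labels, ranking,
    [ClassifierSpec("svm", seed=1), ClassifierSpec("rf", seed=1)],
    step=10, folds=10, seed=1, max_features=200,
)
for family, (n, mcc) in sorted(result.optimal.items()):
    print(f"{family}: optimal subset = {n} features, CV MCC = {mcc:.3f}")
```

prints

```
truth probes in top 200: 70/70
random_forest: optimal subset = 120 features, CV MCC = 0.786
svm: optimal subset = 140 features, CV MCC = 0.989
```

i.e. MCFS recovers every planted probe within the top 200 of 2,000, and the
IFS optimum for the SVM reaches near-perfect cross-validated agreement with
the true subtypes, while the deliberately small 10-tree forest plateaus
lower — the same ordering the protocol reports on real cohorts.

The same protocol is scriptable from the shell:

```sh
methylclass simulate --preset training --n-probes 2000 --seed 1 --out sim/
methylclass rank --matrix sim/beta_matrix.tsv --labels sim/labels.tsv \
    --projections 400 --trees 2 --seed 1 --out ranking.tsv
methylclass ifs --matrix sim/beta_matrix.tsv --labels sim/labels.tsv \
    --ranking ranking.tsv --max-features 200 --seed 1 --out ifs/
methylclass run-all --config pipeline.yaml
```

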