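# Methods

## Problem setting

The pipeline addresses supervised subtype classification from array
methylation data: a probes × samples matrix of beta values (methylated
signal fraction per CpG probe, in [0, 1]), a sample → subtype assignment,
and far more probes than samples. The driving use case is seven-way
glioblastoma subtyping on cohorts of a few hundred samples measured on
tens of thousands of probes, with heavy class imbalance (the bundled
presets use 41/56/14/16/64/143/13 training samples per class, 347 total,
and 13/104/19/17/44/118/9, 324 total, for the independent test cohort).
The goal is not only a classifier but an interpretable, ranked set of
discriminative probes.

## Monte Carlo feature selection

MCFS ranks probes by aggregating their split contributions over a large
ensemble of decision trees grown on random feature projections:

* `s` projections of `m` probes are drawn uniformly without replacement
  (defaults `s = 1000`, `m = ceil(0.05·M)`; the originating program's
  defaults are not published, so these are explicit, overridable choices
  in the small-m / many-projections regime the method assumes).
* Per projection, `t = 5` trees are grown, each on a stratified bootstrap:
  per class, `round(2/3 · n_c)` samples drawn **with replacement**; the
  samples never drawn form that tree's evaluation set. This reading keeps
  the "bootstrap sample sets" wording while guaranteeing held-out samples
  for tree quality.
* Trees are binary, split on midpoint thresholds between consecutive
  distinct beta values by maximal information gain (entropy, log base 2),
  and stop at pure nodes, `min_leaf = 2`, or zero best gain; no pruning.
* Tree quality `wAcc` is the unweighted mean of per-class recalls on the
  held-out samples (classes absent from the held-out set are skipped; an
  empty held-out set scores 0). "Weighted accuracy" has no published
  formula in this protocol; mean per-class recall is the standard choice
  and keeps RI non-negative.
* RI sums, over every tree and every node splitting on the probe,
  `wAcc^u · IG · (n_node/n_tree)^v` with `u = v = 1` by default.

Determinism: one master seed feeds a counter-indexed seed tree
(`SeedSequence((seed, stage, projection, tree))`), so results do not
depend on execution order; all ties (equal gains, equal RI) break
lexicographically on probe ID.

## Incremental feature selection and scoring

Candidate subsets are nested top-k prefixes in steps of 10 (a final
partial prefix covers all M probes when M is not a multiple of the step).
Each (prefix, classifier) pair is scored by stratified 10-fold
cross-validation: per class, samples are shuffled by seed and dealt
round-robin to folds, which handles classes smaller than the fold count
(they are simply absent from some folds, with a warning). Fold
predictions pool into one confusion matrix summarized by:

* **multiclass MCC** — the K-category correlation coefficient
  `(c·s − p·t) / sqrt((s² − p·p)(s² − t·t))` over the confusion matrix
  (trace `c`, total `s`, row sums `t`, column sums `p`), defined as 0 when
  a variance term vanishes. It reduces exactly to the classical binary
  MCC for K = 2.
* **overall accuracy** — trace over total. Whether the protocol's
  "overall accuracy" is trace-over-total or class-balanced is ambiguous;
  trace-over-total is used and `balanced_accuracy` is exposed as the
  alternative.

The optimum per family is the prefix maximizing MCC, ties resolved to the
smaller prefix. The ranking is computed once on the full training set
before cross-validation — faithful to the published protocol, and
optimistically biased relative to re-ranking inside each fold; the
independent-test evaluation (refit once on the full training cohort, score
once on the held-out cohort) is the unbiased check.

## Classifier families

* **SVM** — one-vs-rest SVC with polynomial kernel, degree 1 (the Weka
  SMO default the protocol relies on), γ = 1, coef0 = 0, C = 1. SMO's
  internal attribute normalization is deliberately not replicated: beta
  values are already on [0, 1]. Score ties resolve to the lowest class
  index.
* **Random forest** — 10 trees (fixed by the protocol), unpruned,
  `floor(sqrt(F))` candidate features per split, bootstrap per tree.
* **Rule learner** — a simplified RIPPER: classes from rarest to most
  frequent (frequency ties break lexicographically), sequential covering
  per class with a stratified 2/3 grow / 1/3 prune split; rules grow by
  greedily adding threshold conditions (probe ≤ c or probe > c)
  maximizing FOIL information gain, are pruned by deleting trailing
  conditions while the pruning-set worth (p − n)/(p + n) improves, and
  rule addition stops when a rule's pruning-set error exceeds 50%. The
  most frequent class is the unconditioned default. RIPPER's
  post-induction optimization passes and MDL stopping are intentionally
  omitted — a documented divergence from JRip.

## Synthetic cohorts

The generator emulates the study design, not array chemistry. Background
probes draw i.i.d. Beta(2, 2) (mean 0.5); each class owns a disjoint block
of informative probes whose within-class distribution shifts the Beta mean
by ±`effect_delta` (default 0.3, half hyper-, half hypomethylated) at
fixed concentration a + b, preserving the variance scale. Class sizes
default to the cohort breakdowns above; the probe count defaults to 2,000
at desk scale (42,383 mirrors the full-scale study). Train/test preset
pairs share planted probes so selection on one cohort can be scored on the
other. Not simulated: probe–probe correlation, bimodal fully-(un)methylated
probes, batch effects, copy-number artifacts, cross-hybridization — so
passing tests demonstrate correctness of the machinery and recoverability
of planted signal, not performance on real arrays.

## Enrichment

The hypergeometric upper tail P(X ≥ k) is computed by exact summation in
log space (gammaln + logsumexp), stable for array-scale universes;
BH-FDR adjustment is applied per namespace (BP / CC / MF / pathway
collections are corrected separately, matching per-category reporting).
The default universe is every gene in the annotation manifest. No
GO-graph propagation is performed.

## Numerical and scale choices

* Beta values within 1e-9 of [0, 1] are snapped to the range; anything
  further out is a hard error. Missing values error by default; optional
  per-probe median imputation.
* Validation-scale runs use 2,000 probes with an MCFS ensemble of
  `s = 400, t = 2` (800 trees): planted-probe recovery saturates at this
  ensemble size (every one of the 70 planted probes ranks in the top 200
  across seeds), so larger ensembles only add runtime. The IFS sweep in
  those runs examines the top 200 ranks; the rule learner, whose fits are
  ~40× slower than the SVM's, is swept on a coarser grid.
* A known boundary case: with the protocol-fixed 10-tree forest on the
  seven-class preset at effect size 0.3, the IFS-optimal random-forest
  MCC concentrates at ≈ 0.78–0.82 across seeds (the forest, not the
  ranking, is the ceiling — a 100-tree forest on the same features scores
  ≈ 0.86). Summaries of forest performance at this scale should therefore
  be read as "≈ 0.8", with seed-to-seed spread of ±0.02.

## Limitations

The pipeline takes the probe matrix as given (no IDAT processing,
normalization, or the unstated 485k → 42k probe filter of the full-scale
study). Classifier implementations follow documented defaults rather than
bit-reproducing Weka's SMO/JRip. Enrichment is generic over user-supplied
GMT collections; no ontology snapshots are shipped.
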