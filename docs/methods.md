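# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `toxmark`. It describes what the code computes; all
empirical statements here are reproduced by the test suite or the
pipeline itself.

## Study setting and data model

The package targets cross-dataset biomarker discovery for non-genotoxic
hepatocarcinogenicity from 1-day, maximum-tolerated-dose rat-liver
microarray profiles. Each dataset is a chemicals × probes matrix of
preprocessed log2 expression values (`ExpressionDataset`), one row per
chemical (replicate animals are assumed pre-averaged upstream; the
package has no replicate axis). Probes are platform-specific; gene
symbols are the namespace shared across platforms. Cells may be missing
(NaN), and every stage must tolerate that — it is the reason margin-based
classifiers are not part of the model set.

## Curation

Per-source labels are one of NGHC, NHC, or GENOTOXIC_ONLY. Merging rules:

* NGHC and NHC from different sources → status INCONSISTENT (quarantined,
  later reclassified by the models), regardless of other labels;
* only GENOTOXIC_ONLY → EXCLUDED (genotoxic mechanisms are detectable by
  established assays and are out of scope);
* NGHC + GENOTOXIC_ONLY → NGHC (mixed mechanism counts as non-genotoxic);
* GENOTOXIC_ONLY + NHC with no NGHC → a data-integrity error: the sources
  contradict each other in a way no documented rule resolves, so it is
  surfaced rather than silently fixed.

Name canonicalization is lowercase + whitespace collapse + dash
normalization, and is idempotent. No synonym or CAS resolution is
attempted; curated lists are name-keyed, and synonym mapping is left
pluggable.

## Synthetic studies

`generate_study` emulates the features of the real multi-study design
that matter to the pipeline:

* **Two platform families.** An "affy-like" family with 1–3 probes per
  gene plus a few unmapped probes, and a "codelink-like" family with one
  probe per gene — exercising probe→gene collapsing and cross-family
  incomparability. Full-scale probe universes (~31k / ~10k) are not
  simulated; the desk default is 500 genes, which preserves every
  qualitative behaviour while keeping tests fast.
* **Dataset-specific chemical subsets** drawn from a global pool of 50
  NGHC / 224 NHC chemicals; default per-dataset class counts are 25/47,
  39/138, 35/121 and 12/93, matching the four real datasets.
* **Planted markers.** `n_planted_markers` genes (default 4) are shifted
  by `effect_size` (default −1.0 log2 units, i.e. 2-fold down-regulation
  in NGHC-treated profiles — the direction observed for the real
  consensus biomarkers).
* **Noise** is i.i.d. Gaussian on the log2 scale (`noise_sd`, default
  0.5), i.e. log-normal multiplicative noise on the original scale — the
  standard microarray approximation, which also makes effect sizes
  directly interpretable as log2 fold changes.
* **Platform baseline shifts**: a per-(family, gene) offset with sd
  `baseline_shift_sd` (default 0.3) added to all chemicals, reproducing
  the observation that expression levels agree within a platform family
  but not across families. Offsets cancel in within-dataset group
  contrasts by construction.
* **Missingness** is uniform at `missing_rate` (default 5%), missing
  completely at random and label-independent.

All draws derive from one master seed through named substreams
(truth, platforms, baselines, per-dataset chemicals and noise, the
independent set), so any stage can be regenerated independently and
`generate_independent_set` shares the gene-level ground truth with the
study while drawing disjoint chemicals (defaults 9 NGHC / 54 NHC on the
small family, mirroring the external validation cohort).

What the generator does **not** emulate: dose–response and time series,
array-level artifacts, correlated gene modules, batch effects within a
platform, and informative missingness. Tests passing on this generator
therefore demonstrate the pipeline's correctness and its behaviour under
the stated noise model — not performance on real arrays.

## Differential expression and consensus

Per probe, a two-sample *t*-test (classical pooled-variance by default —
the variant a WEKA-era analysis implies; Welch is a config switch) and a
fold change. With log2 inputs the default fold-change convention is
geometric: log2FC = mean difference, FC = 2^log2FC; an arithmetic
convention (ratio of anti-logged means) is available since "original
scale" could be read either way. A probe passes at *p* < 0.05 (strict)
and FC ≥ 1.5 or ≤ 1/1.5 (inclusive, matching the printed inequalities).
No multiple-testing correction is applied by default, matching the
procedure being reproduced; Benjamini–Hochberg can be layered on by the
caller. Missing cells are dropped per probe per group; a probe with fewer
than two usable values in either group cannot pass. Degenerate cases:
zero variance in both groups gives t = 0, p = 1 at equal means and the
smallest positive double at unequal means.

A gene is a DEG if **any** of its probes passes (cross-platform probe IDs
are incomparable, so consensus must be gene-level; the any-probe rule is
the permissive choice and is documented as a decision, not derivable from
the source procedure). The consensus set is the exact intersection of the
per-dataset gene-level DEG sets, with per-dataset provenance retained.

## Classifiers

All six families share the estimator contract: `fit(X, y)`,
`predict_proba`, `predict_score` (probability of NGHC), `predict` (hard
call at 0.5 — a tie maps to NHC: no positive hazard call without majority
evidence), NaN tolerated everywhere.

**C4.5-style tree.** Binary splits at midpoints between consecutive
distinct observed values; information gain computed on the instances
observing the feature and discounted by the observed-weight fraction;
the split maximizes gain ratio among candidates with at least average
gain. Instances missing the split feature descend both branches with
weights proportional to the observed branch weights, at fit and at
predict time (a row missing the root feature scores the branch-weighted
mixture of the subtree scores). Pruning is pessimistic with confidence
factor 0.25 and a minimum leaf weight of 2 (the classical defaults); the
upper confidence bound on the leaf error rate is the exact binomial
(inverse regularized incomplete beta) rather than Quinlan's normal
approximation — the reference toolkit's exact internals are not
documented, so this package defines its own contract and verifies
family-level agreement with reference implementations on complete data
only.

**Bagging** fits `n_trees` pruned trees on size-n bootstrap resamples;
the score is the mean of the member class-probability estimates, which
equals the vote fraction whenever leaves are pure (and reduces exactly to
the single tree when bootstrap is disabled and `n_trees=1`).
**AdaBoost.M1** uses the reweighting form with pruned trees, multiplying
correct instances' weights by err/(1−err) per round, stopping early at
weighted error 0 or ≥ 0.5; the score is the α-weighted vote fraction.
**Random forest** grows unpruned bootstrap trees with
1 + ⌊log₂ M⌋ candidate features per node (floor; M = 4 gives 3).
Ensemble member *i* is seeded from (random_state, *i*), so a 10-tree
ensemble is a prefix of the 20-tree one.

**Gaussian naive Bayes** estimates per-class, per-feature mean/variance
from observed values (variance floored at 1e−9); missing features drop
out of the likelihood product, and a feature with fewer than two observed
values in a class is skipped for that class. A row with no usable feature
scores the class prior.

**kNN** uses Euclidean distance over mutually observed features rescaled
by √(M/m_observed); a pair with no mutually observed feature is
infinitely far; distance ties break by training order; the score is the
NGHC fraction among the k nearest (grid {1, 3, 5}).

## Evaluation

AUC follows the pairwise definition with ties counted half, implemented
as a tie-grouped ROC curve whose trapezoidal area keeps the pair-count
identity exact (verified against a brute-force all-pairs oracle to
1e−12). LOOCV produces one held-out score per chemical from a clone
never trained on it, with per-fold seeds derived from the master seed; a
fold whose training part collapses to one class is scored by the training
prior and flagged. Tuning is **non-nested**: the same LOOCV both selects
the parameter (tree counts, default grid 5–50 in steps of 5; k ∈ {1,3,5})
and reports its AUC, reproducing the original procedure — the reported
AUC is therefore optimistically biased, which is accepted as part of the
protocol being replicated. Ties in the grid resolve to the smallest
parameter. Independent testing applies only models whose training
platform family matches the test set's; others are reported as skipped.

## Robustness

The resampling protocol draws 60 subsets of 80 chemicals preserving the
pool's NGHC:NHC ratio (nearest-integer per class, remainder to the
majority class: a 39/138 pool gives 18/62) with every pairwise overlap
strictly below 50% of the subset size. Plain greedy rejection sampling
cannot finish this at the default scale: any 60×80-from-177 plan has a
*fixed* total pairwise overlap determined by element multiplicities,
giving a mean pairwise overlap of at least 35.4 against a bound of 40, so
blind draws stop being accepted after roughly fifty placements. The
sampler therefore runs rejection sampling first (sufficient for looser
configurations; `max_attempts` bounds the draws per subset) and, if
placement stalls, rebuilds the plan by a balanced construction: element
multiplicities are dealt as evenly as possible across subsets within each
class, then penalty-guided single-element swaps (cost = squared excess
over the admissible overlap, plus a small charge for pairs sitting
exactly at it) repair the remaining violations. Both phases are
deterministic given the seed, and an independent verifier re-checks
every invariant (size, class composition, all pairwise overlaps,
overlap-matrix consistency) from the emitted plan alone. Marker-subset
robustness uses all leave-one-marker-out panels in marker order; by
default one subset plan is reused across panels so their AUCs are
comparable.

Per-subset performance is LOOCV AUC of the configured classifier on the
marker features; the summary is the mean and sample SD over subsets.

## Reclassification

Each quarantined chemical is scored by every dataset model for which it
has a profile; score > 0.5 calls NGHC, otherwise NHC (the 0.5 tie rule is
conservative and documented — the aggregation itself never weighs
datasets). The verdict is NGHC or NHC on strict majority and UNDEFINED on
a tie. The packaged 16-chemical call table reproduces the published
3 / 11 / 2 partition; for the five chemicals decided jointly by three
datasets only the aggregate NHC outcome is published, so all three calls
are transcribed as NHC and the assumption is flagged in the fixture's
metadata.

## Numerical and interface choices

* Scores, not hard labels, are canonical outputs (needed for ROC).
* Probe-level matrices are collapsed to gene features by the mean of
  observed probe values; a gene absent from a platform yields an all-NaN
  feature column, keeping feature spaces aligned across platforms and
  exercising the missing-value contracts.
* Model documents serialize to versioned JSON (tree structure, Gaussian
  parameters, stored kNN instances).
* The pipeline writes every artifact as TSV/JSON plus a manifest of
  SHA-256 hashes; identical config + seed gives identical hashes.
* Desk-scale defaults (500 genes; unit tests use 40–200 genes and
  reduced class counts) were chosen so the full suite runs in about a
  minute while preserving the qualitative regime — planted effects of
  −1.0 log2 at noise 0.5 give the same near-ceiling separability that the
  real four-marker panels show.

## Known limitations

* The generator's independence assumptions (genes, cells, missingness)
  make consensus recovery easier than on real correlated arrays; recovery
  rates reported by the tests are upper bounds on realistic behaviour.
* Non-nested tuning inflates LOOCV AUCs; nested CV is deliberately not
  implemented to stay faithful to the replicated protocol.
* No confidence intervals on AUC and no significance tests between
  models.
* The C4.5 variant implements no subtree raising, and its pessimistic
  bound differs in the tails from implementations using the normal
  approximation; pruned trees may therefore differ in depth from WEKA's
  J48 on the same data even though family-level behaviour agrees.
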