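# Methods

`cpgrank` extends an array-based epigenome-wide association study (EWAS)
to every CpG dinucleotide in a genome. Arrays assay only a small
fraction of CpGs; the package treats "is this CpG associated with the
trait?" as a supervised classification problem over genomic/epigenomic
context features, trains on the array CpGs where the association test
has already spoken, and scores the rest of the genome.

## The model

**Unit of analysis.** A CpG site is the C of a forward-strand CG
dinucleotide, 0-based. A CpG is its own reverse complement, so one
strand suffices; soft-masked bases count and N breaks a dinucleotide.

**Association testing.** Per CpG, methylation (the beta fraction in
[0,1], or its logit where variance stabilisation is wanted) is
regressed by OLS on the trait plus covariates (age, sex, batch, neuron
proportion in the synthetic design); the p-value is the two-sided
t-test on the trait coefficient. Binary traits use the same linear
model (a linear probability model), which mirrors common array-EWAS
practice; a logistic alternative was considered and rejected to keep
the engine identical across trait kinds. Degenerate cases are
conventions, not crashes: an all-constant CpG gets p = 1 (detected via
max−min, which is exact where a standard deviation picks up mean
round-off); a rank-deficient design yields NA p-values with a warning.
Logit of boundary beta values clamps to [1e-3, 1−1e-3] with a warning.

**Training-set construction.** Positives are array CpGs with p ≤ p_pos
(default 1e-5; the sensible range is 1e-7..1e-5 and the threshold
trades training-set size against label quality). Each positive gets 10
matched negatives — the nearest remaining candidates by mean-beta
distance, processed in ascending-p order so the strongest positives
match first — drawn from CpGs with p > 0.40 in *every* supplied trait.
Matching is greedy nearest-neighbour without replacement rather than a
tolerance window (no principled tolerance exists); a guard
(`max_beta_diff`, default 0.1) turns silent bad matches into a
shortfall error naming the positive that failed. Ties break by genomic
distance, then lexicographic site id, so output is independent of
input row order. The 1:10 imbalance is kept at evaluation time because
it approximates the true scarcity of trait-associated CpGs.

**Consensus feature selection.** Four base learners — L2-regularized
logistic regression (RLR), linear SVM, random forest (RF), and
gradient-boosted trees (GBDT, XGBoost) — each rank features on the
training data: |weight| for RLR/SVM (inputs z-scored with training-set
statistics so weights are comparable; tree learners see raw values),
Gini importance for RF, gain for GBDT. Ranking-stage hyperparameters
are fixed defaults because feature selection precedes tuning. Each
learner keeps its top 100; features are then ordered by vote count
(0–4), ties broken by the two-sided Wilcoxon rank-sum p comparing
feature values between positive and negative CpGs (exact for tie-free
groups of ≤ 8 per side, normal approximation with continuity
correction otherwise), residual ties by feature name. The top 60
survive. One-sided versus two-sided tie-breaking was an open choice;
two-sided is used since either direction of shift is informative.

**Ensemble training.** Nested cross-validation: 10 stratified outer
folds (nine-to-one splits), and inside each outer training part a
3-fold inner CV scores hyperparameter candidates by mean F1.
The search is a budgeted, seeded random draw from per-learner spaces
(RLR: C ∈ 10^[−3,2]; SVM: linear/RBF kernel, C, gamma; RF: 100–400
trees, depth 3–15; GBDT: 50–300 trees, depth 2–8, learning rate
10^[−2,−0.5]); spaces are modest on purpose so desk-scale runs finish
in minutes. Ties keep the first-evaluated configuration. Within every
fitted fold, positives are uniformly up-sampled with replacement to
match the negatives; test folds are never resampled. Out-of-fold
member probabilities therefore cover every training site exactly once
and all reported metrics are pooled out-of-fold values at the natural
imbalance (the pooled-vs-per-fold ambiguity is resolved in favour of
pooled and recorded in the model manifest).

Soft voting is the unweighted mean of member probabilities. The SVM
contributes a logistic squash of its decision function — probability
calibration is deliberately out of scope, the squash preserves rank
order, and 0.5 coincides with the decision boundary. All 15 non-empty
member subsets are compared on soft-voted out-of-fold F1 (AUPRC
optionally); the winner is refit on the full training set using, per
member, the tuned configuration with the highest inner-CV F1 across
folds. The RLR+GBDT pair is the deployment default: in practice the
high-recall linear model and high-precision boosted trees offset each
other. Precision/recall/F1 use a 0.5 threshold on the vote.

**Genome-wide ranking.** Every enumerated CpG gets its feature vector
through its 200-bp bin (feature tracks are binned at 200 bp, so CpGs
sharing a bin share a vector); uncovered bins fall back to training
medians and are counted in a warning. Scoring streams in chunks of
10,000 (recorded in the manifest); chunking cannot change scores. Per
trait, scores become ranks (1 = highest; ties share the best rank of
their block, so equal scores get equal significance), the log-scale
rank score LRS = −log10(rank/total), and the empirical p = rank/total.
A composite over traits — the sum of per-trait LRS by default, mean
and max available — drives the stepwise "detached" locus selection:
walk sites by descending composite and keep one only if it lies at
least `spacing_bp` (10 kb for reporting, 500 bp for validation
designs) from every kept site on the same chromosome.

**Validation calls.** For targeted resequencing designs, CpGs within
500 bp merge transitively into clusters; a cluster is called
associated when any member reaches unadjusted p < 0.05 on any trait.
No multiplicity adjustment is applied across traits — that reproduces
the validation design this mirrors, and the output metadata flags it.

**Enrichment.** Each CpG gets exactly one annotation category, the
most regulatory of its overlaps (enhancer > promoter > exon > intron >
near-gene (1–5 kb of a TSS) > intergenic; UTRs are not separate
categories since they sit inside first/last exons); 15-state chromatin
segmentations work the same way with states as categories. The
expected proportion of a category is its frequency among all
*enumerated CpGs*, not its base-pair share of the genome — the CpG is
the unit of analysis. Observed-vs-expected deltas are tested with an
exact binomial tail (upper for enrichment, lower behind a depletion
switch). Gene retrieval around loci uses half-open windows
[pos − w, pos + w): a gene starting exactly w away is excluded.

## The synthetic study generator

The generator emits what the pipeline's real inputs would be, with
known ground truth. Defaults are the package's study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| samples | 500 | within the 113–717 range of typical brain cohorts; near-full power at p ≤ 1e-5 for the default effect |
| genome | 2 × 750 kb | ~15,000 CpGs at 10/kb (the human genome averages ~9/kb); gives a negative-matching pool ~18× the positives |
| causal CpGs per trait | 350 | with 50% array coverage, ~175 positives → ~1,900 training CpGs, matching the 1,706–3,181 range the design targets |
| causal effect | 0.25 logit units per SD of the latent, × U(0.4, 1.6) per CpG | heterogeneous effects leave a tail of "suggestive" CpGs just above threshold, as real EWAS do |
| features | 200 tracks, 10 informative, shift d = 1.5 at causal bins | a planted-signal design strong enough that failure indicates a pipeline defect, not noise |
| array fraction | 0.5 | leaves an off-array causal set for recovery tests (real arrays cover ~2–3%; 50% keeps desk-scale power) |

Methylation is built on the logit scale: a bimodal hypo/hyper baseline
per CpG (mixture of Beta draws), additive covariate effects (age, sex,
batch, neuron proportion), a causal shift proportional to a latent
pathology burden, and N(0, 0.5) noise, then squashed back to (0,1).
The latent loads on age and neuron proportion (0.3 each), so traits
are genuinely confounded and covariate adjustment is load-bearing.
The binary trait thresholds the latent at its median; the continuous
trait is the latent itself — all traits share causal CpGs, as
correlated clinical measures of one pathology do. Additivity on the
logit scale keeps the model invertible for testing. Informative
feature tracks gain +d in bins containing a causal CpG; missingness is
applied at bin level so the same-bin-same-vector invariant survives.
All randomness flows from one integer seed through named per-stage
generators, so stages are reproducible in isolation.

What the generator does *not* emulate: array probe chemistry and
cross-hybridisation, batch structure needing dedicated correction,
spatial correlation of methylation along the chromosome, LD-like
feature redundancy, and read-level bisulfite noise. Passing tests
therefore demonstrate that the machinery is correct and calibrated
under the stated generative model — not that real-data performance
will match.

## Problem sizes and numerical choices

The test suite runs five full planted-signal studies (~15,000 CpGs,
~1,900 training sites, tuning budget 5 per learner per fold with the
RLR+GBDT pair) plus five label-permuted null runs at a reduced scale
(one 400-kb chromosome, 300 samples, ~330 training sites); these sizes
were chosen so a complete run stays a desk-scale exercise. Rank math
is additionally exercised at the published genome-wide total
(26,573,858) as pure arithmetic — scoring a genome of that size is
out of scope for the bundled studies, though the interfaces support it.

Numerical conventions collected in one place: p-values clip to
[tiny, 1]; beta clamps to [1e-3, 1−1e-3] before logit; tied scores
share the minimum rank; tied feature votes break by Wilcoxon p then
name; tied hyperparameter scores keep the first draw; tied composite
scores order by (chrom, pos). Median imputation constants and scaling
statistics are estimated on the training set only and stored in the
model artifact so genome-wide scoring reuses them verbatim.

## Known limitations

- Consensus feature selection is a pre-CV stage: it runs once on the
  full training set, and the nested CV that follows estimates
  performance *conditional on the selected features*. When the feature
  pool is large relative to the training set this inflates out-of-fold
  estimates (selecting 60 of 200 features on ~300 permuted-label sites
  can push apparent AUC to ~0.7). The null-calibration check therefore
  permutes labels after selection, isolating the CV machinery; users
  comparing feature sets should hold out data entirely or move
  selection inside the outer folds.
- The linear probability model for binary traits is a documented
  simplification; very unbalanced binary traits would warrant the
  logistic switch.
- Greedy beta-matching is univariate; propensity or multi-covariate
  matching is out of scope.
- The random hyperparameter search meets the same contract as
  model-based samplers (budget, seed, F1 objective, deterministic
  ties) but explores less efficiently at large budgets.
- Enrichment p-values are marginal per category; no across-category
  multiplicity correction is applied.
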