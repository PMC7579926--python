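# Methods

This note documents the statistical models, the synthetic-data generator,
numerical choices, and the design decisions taken where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The count model and the synthetic cohort generator

Every downstream stage assumes bulk RNA-seq counts that are approximately
negative binomial with a dispersion that falls with the mean.  The
simulator draws, for gene *g* and sample *s*,

    K_gs ~ NB(mu_gs, disp(mu_gs)),   Var(K) = mu + disp·mu²
    mu_gs = sf_s · plate_s · baseline_g · 2^(Σ_k beta_gk x_ks)

with `disp(mu) = a0/mu + a1` (defaults a0 = 1, a1 = 0.05).  The two-term
trend reproduces the shot-noise-plus-overdispersion shape the normalization
stage must fit, and makes the simulator and the seed-reference estimator
mutually checkable: the trend recovered from simulated counts should match
(tested to within 25% over the mid-expression range).

Covariate effects are log2 fold changes on disjoint gene blocks:

| effect            | default block size | default log2FC | sign pattern |
|-------------------|--------------------|----------------|--------------|
| cancer            | 200                | 1.0            | alternating  |
| smoking (current) | 150                | 1.5            | alternating  |
| cohort            | 100                | 0.5            | alternating  |
| inhaled medication| 100                | 0.75           | alternating  |

Smoking is deliberately the strongest effect and cancer a moderate one:
in bronchial airway data the smoking response dominates the transcriptome
while the malignancy signal is comparatively weak, which is exactly the
regime the clinical–genomic ensemble is designed for.  No quantitative
effect sizes are published for timing or inhaled medication on expression,
so those defaults are free parameters of the simulator, chosen once at
values that make the corresponding classifiers learnable but imperfect —
they are not claims about real data.

Specimen-collection timing is not a flat fold change.  A brushing collected
*after* other cytology/pathology sampling contains relatively more basal
and blood cells and fewer ciliated cells, so the simulator shifts cell-type
mixing proportions (prior mix: basal .25 / ciliated .40 / secretory .20 /
blood .10 / immune .05; after mix: .33/.25/.20/.17/.05) and applies the
implied log-ratios to the cell-type signature gene blocks.  `timing_shift`
in [0, 1] interpolates between the two mixes.

Sex chromosomes: chrY genes (default 9) have mean 50 in males and a leaky
0.1 in females, so the gender index is discriminative but not degenerate;
chrX genes (default 60 at desk scale) behave as ordinary genes and supply
the index denominator.

Cohort structure: two cohorts with independently configurable fractions of
malignant, current-smoker, collected-after and inhaled-medication samples.
The default `frac_after` (0.03 vs 0.62) reproduces the cohort–timing
confounding of the real study populations (97% vs 38% collected prior);
setting both equal removes it.

Plate design: samples are laid out on 96-well plates (87 patients + 4
control + 5 sentinel wells).  Controls and sentinels are fixed biological
identities replicated once per plate; every sample on a plate shares an
additive Gaussian plate effect on the natural-log scale (default s.d. 0.1;
the variance-component recovery checks use 0.3 so the target 0.09 is well
above estimation noise at 10 plates × 9 replicates).

Default scale is 2,000 genes, 600 patients, ~7 plates — large enough for
stable dispersion trends and CV, small enough for desk-scale runs.  What
the simulator does **not** model: read-level effects (GC/length bias,
mapping), per-gene×sample normalization factors, strand structure,
library-prep chemistry beyond a global plate shift, and correlated
gene–gene noise within blocks.  Tests passing on this generator therefore
demonstrate algorithmic correctness and statistical calibration under the
assumed NB model, not performance on real brushings.

## Seed-reference normalization

The seed reference freezes (i) per-gene geometric means over the seed
samples (zero if any seed count is zero; such genes are excluded from the
size-factor median) and (ii) a dispersion–mean trend.  A new sample is
normalized alone: size factor = median over reference-positive genes of
count/geometric-mean, then `g(count/sf)` with

    g(x) = ∫₀ˣ dμ / sqrt(μ + disp(μ)·μ²).

Gene-wise dispersions are estimated per gene by a method-of-moments start
refined with a bounded 1-d likelihood maximization (log-dispersion in
[log 1e-8, log 20], xatol 0.01) at means fitted by Poisson IRLS on the seed
design (diagnosis label, clinical smoking status, collection timing;
dummy-coded).  If that design is collinear or wider than the seed set, the
fit falls back to intercept-only (logged) rather than failing — relevant
only for toy-sized seeds.  The trend is a lowess fit (tricube weights,
frac 0.4, 3 robustness iterations) of log dispersion on log mean over genes
with normalized mean ≥ 1, interpolated linearly in log space and floored at
1e-8, with flat extrapolation.

The VST integral is precomputed on a 10,000-point log-spaced grid from 1e-8
to 50× the seed's maximum normalized mean (plus the exact zero node) by
cumulative trapezoid, and evaluated by linear interpolation with terminal-
slope extrapolation.  The integrand behaves like μ^(-1/2) near zero and is
integrable; the head of the integral below 1e-8 is negligible at the
tolerances used (batch-vs-single-sample agreement is asserted at 1e-6).
One size factor per sample and one trend per reference are used; the
per-strand normalization factors of the original laboratory pipeline are
intentionally out of scope since the synthetic data model carries no strand
annotation.

Gene filters: *low expressers* are genes with TPM < 1 in more than 99% of
training samples (TPM = count/length normalized to 1e6 per sample; the
boundary is strict, so a gene at exactly 99% is kept).  *Batch-sensitive*
genes replace a factor-analysis (RUV-style) step with the criterion that
motivates it — excessive variability under constant assay conditions: per
gene, the mean over replicated control/sentinel identities of its
normalized-expression variance across plates, flagging the top 2% by
default.  The factor count of the published RUV step is not recoverable,
and the replicate-variance quantile rule is deterministic and directly
testable by spike-in recovery.

Clinical imputation: years-since-quit, pack-years, nodule size and age get
their stratum median (cohort × indication × pre-test risk), falling back to
the cohort median for empty strata (logged); missing inhaled medication is
"no"; missing collection timing is predicted by the timing classifier.
Observed values are never overwritten.

## Genomic indexes

**Gender.**  `index = Σ_i log2(y_i + 1) / log2(Σ_j x_j)` over the chrY/chrX
panel; call Male iff index > 3.16, strictly — an index of exactly 3.16 is
Female.  The denominator requires Σx ≥ 2.  On synthetic data the panel is
taken from the simulated annotation; the real 9-gene/611-gene identities
are not public.

**ssGSEA.**  Within one sample, genes are ranked by expression descending
(ties broken by gene-id order, deterministically); the rank statistic of
the gene at position i (1-based) is N − i + 1.  The score is
Σ_i [P_in(i) − P_out(i)], where P_in is the in-set ECDF weighted by
|rank|^0.25 and P_out the unweighted out-of-set ECDF.  These are the
original ssGSEA conventions (weight exponent 0.25, no permutation
normalization).  Because only ranks enter, the score is invariant to
strictly monotone transforms.  If the gene set covers the whole measured
universe the out-of-set ECDF is undefined and the score is 0 by documented
convention.

**Smoking index.**  A current-vs-former model trained in three steps inside
each outer CV split: (1) NB Wald DE on smoking status (design: gender and
cohort) at FDR < 0.05; (2) feature reduction retaining a proportion 0.1,
0.2 or 0.5 of the genes by hierarchical clustering (so four candidate sets
including the unreduced one — with a single clustering method, "retain a
fraction" is the interpretation used for the reduction proportions);
(3) elastic-net logistic regression and a linear SVM per candidate set,
hyperparameters by inner-CV random search with the one-standard-error
rule.  Outer CV partitions are balanced by smoking status × pre-test
risk × cohort.  The best (feature set, learner) by mean outer AUC is refit
on all data; the shipped default elastic-net hyperparameters are
(α, λ) = (0.129, 0.131) in the glmnet parameterization (see below).  The
index is the unthresholded logit, oriented so current smokers score
higher.  The package's CV defaults are desk-scale (5 folds; configurable
repeats and search budget); the gene panel size on synthetic data is
whatever the penalty selects and is recorded on the fitted model, not
forced to the published 248.

## Timing classifier

Binary prior/after model restricted to the union of the cell-type
signatures.  Four feature options (none; DE at adjusted p < 0.05; DE plus
reduction at proportions 0.2 and 0.5) × three learners (elastic-net LR,
linear SVM, and their uniform-average probability ensemble — uniform
because the source describes a weighted average without giving weights, and
uniform is deterministic).  Selection by CV AUC, refit on all data.  The
decision boundary is fixed at 0.5 on the probability scale; the call is
"after" iff probability strictly exceeds 0.5.

## Differential expression and feature reduction

Per-gene NB GLM with log link on raw counts, log size factors as offset,
and dispersion anchored to the seed-reference trend evaluated at the
gene's normalized mean — no per-gene re-estimation, keeping DE consistent
with normalization and fully deterministic.  All genes are fit
simultaneously by batched IRLS (working weights μ/(1 + φμ), 15 iterations
or Δβ < 1e-10, 1e-10 ridge on the normal equations for numerical safety).
Wald statistic from the observed-information standard error; two-sided
normal p-values; Benjamini–Hochberg adjustment.  The case group may be
augmented with auxiliary out-of-indication malignant samples; auxiliary
samples contribute to all design coefficients, not only the contrast (the
simpler of the two readings; flagged as a possible deviation from the
original pipeline).

Feature reduction: distance 1 − |Pearson r| across samples, average-linkage
agglomerative clustering cut to ⌈proportion·n⌉ clusters, one representative
per cluster — the member with the smallest DE p-value, ties broken by
gene-id order.  A proportion of 1 is the identity.  HOPACH is not
implemented: the published pipeline treated it as interchangeable with
hierarchical clustering, and its median-split heuristics are not specified
well enough to reproduce.

## The ensemble classifier

Design matrices: continuous covariates standardized by training mean/s.d.
(statistics frozen in the builder), binary covariates coded 0/1 (second
sorted level = 1; unseen categories at scoring raise), interaction columns
as products of the encoded mains, deterministic column order.

Components:

1. clinical-dominant elastic-net LR on {age, gender, pack-years, smoking
   index} with all six pairwise interactions (the interaction set is not
   enumerated in the source; all-pairwise is the natural complete choice);
2. genomic-dominant linear SVM on {gender, smoking index} + genes, with
   Platt-type logistic calibration of the training margins so its output is
   a probability that can be averaged with the logistic components (the
   source does not say how SVM scores become probabilities);
3. clinical-genomic elastic-net LR on {age, gender, inhaled medication,
   timing, smoking index} + genes + all clinical×gene interactions;
4. hierarchical GLM: stage 1 is an unpenalized logistic fit of the clinical
   mains; its linear predictor enters stage 2 — an elastic-net logistic fit
   over clinical mains + genes — as a fixed offset with coefficient 1,
   never penalized or re-estimated.  Stage-1 separation (|standardized
   coefficient| > 30 or solver failure) triggers a ridge-stabilized
   fallback (C = 1), logged.  Stage 2 uses a GLM elastic-net fit with the
   intercept unpenalized.

Ensemble score: probabilities clipped to [1e-6, 1 − 1e-6], averaged
uniformly, then logit.

Elastic-net parameterization: hyperparameters are stored glmnet-style as
(α, λ) — penalty λ(α‖β‖₁ + (1−α)/2‖β‖₂²) on the mean log-loss — and mapped
to scikit-learn's saga solver via C = 1/(nλ); features are standardized
internally and coefficients reported on the original scale.  All stochastic
solvers are seeded, so fits are reproducible.

Nested CV: outer partitions balanced by label × smoking status × timing
(rare strata merged; partitions leaving a fold single-class are redrawn
with a fresh sub-seed, max 10 attempts).  Hyperparameters are tuned per
outer split on an inner CV by random search; the tuning metric is the
primary endpoint — specificity at sensitivity ≥ 0.9 on pooled inner
out-of-fold scores of within-indication low/intermediate pre-test-risk
samples — not AUC, and the one-standard-error rule prefers the most
regularized configuration within one SE of the best.  Each repeat reports
that specificity on pooled outer out-of-fold scores plus the AUC; the
result carries the median and IQR across repeats.  Defaults are 5 folds,
10 outer repeats and a 50-configuration budget; the test suite runs 2
repeats with budgets of 1–3 so the whole suite stays at desk scale.

## Risk re-stratification

With p the group prevalence — computed as #malignant / (#malignant +
#benign + #local-benign), local-benign subjects entering the denominator
only — and sensitivity/specificity computed on adjudicated subjects only:

    down:  %re = (1−p)·spec + p·(1−sens),   NPV = (1−p)·spec / %re
    up:    %re = p·sens + (1−p)·(1−spec),   PPV = p·sens / %re

A zero re-stratified fraction leaves the predictive value undefined and
raises (except p = 0, where the down-direction NPV is 1 by convention).

Boundary calibration scans the midpoints of consecutive unique scores plus
sentinels beyond the extremes — provably equivalent to scanning all
thresholds.  The down boundary maximizes specificity subject to
sensitivity ≥ 0.90 (ties: higher sensitivity, then lower threshold); each
up boundary maximizes the up-classification rate subject to post-test
PPV ≥ its floor (0.65 intermediate, 0.90 high) at the group prevalence.
Unattainable constraints return the nearest-feasible threshold flagged
infeasible — never a silent relaxation.

Confidence intervals are exact Clopper–Pearson (the beta-quantile form;
for x = n the lower limit is (0.025)^(1/n)).  Predictive-value intervals
propagate the sensitivity/specificity interval endpoints through the
closed forms at fixed prevalence; the originating study does not state its
predictive-value CI method, so these are labelled as propagated intervals.

Technical QC: replicated control/sentinel scores are decomposed by REML
(`score ~ 1 + (1|identity) + (1|plate)`, crossed) into biological, plate
and residual variance, with total technical s.d. also reported as a
fraction of the 1%-trimmed score range; probe-lot bias is an OLS fit
`new = shift + rotation · dev` on paired replicate scores (≥ 3 pairs,
non-degenerate development scores).

## Known limitations

- The published real-cohort performance numbers (validation AUC, CV
  specificity, the 248/998/441/16-gene panels) depend on undeposited data
  and are not reproduction targets; synthetic-data panels and AUCs are
  penalty- and simulation-determined.
- Dispersion estimation profiles the likelihood at Poisson-fitted means
  rather than jointly refitting means per candidate dispersion; at seed-set
  sizes this biases the trend negligibly relative to its 25% recovery
  tolerance.
- The hierarchical model's stage-2 fit uses a coordinate-wise elastic-net
  GLM whose convergence tolerance (200 iterations) is looser than the saga
  fits; its null-gene behaviour is guarded by an explicit equivalence test.
- `score_variance_components` assumes Gaussian scores; heavy-tailed score
  distributions will inflate the residual component.
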