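# Methods

This note records the models, the synthetic-data assumptions, the numerical
choices, and the places where the design was genuinely open.

## Synthetic cohort generator

The source cohort (581 primary-care participants, 90 with a
structured-interview depression diagnosis) is available only on request, so
every stage runs on synthetic cohorts calibrated from the published
descriptive tables.

**What is emulated.** Marginal means/SDs per diagnostic group for ~60
continuous features across five blocks (questionnaire/observer totals,
laboratory, HRV, anthropometric, biographic), categorical rates per group
(education, smoking, financial difficulties, 18 binaries), four latent
subtypes inside the depressed group (Adaptive, Late Depression,
Immuno-Metabolic, Overweight Non-Inflammatory; default sizes 26/27/9/28)
whose profiles override the group-level biomarker, age and episode-count
parameters, questionnaire totals that decompose into item scores, and
missing-completely-at-random cells.

**Sampling model.** Continuous features are drawn blockwise from a
multivariate normal with exchangeable within-block correlation ρ (default
0.3; blocks = modalities, independent across blocks), then clipped to
physiological plausibility bounds from the shipped data dictionary and
rounded if ordinal.  Because clipping a Gaussian biases the mean when a
bound is within ~2 SD (e.g. a mean-7.5/SD-8 disability total against a
floor of 0 gains ≈ +1.0), the generator solves per feature and group for
the *latent* mean whose clipped expectation equals the printed mean
(closed-form clipped-normal expectation, Brent root-finding).  Means are
therefore calibrated for every feature; clipped SDs shrink slightly below
the printed SDs, which is accepted.

**Items from totals.** The tables print questionnaire totals; the models
consume items.  Item scores are allocated by a uniformly random bounded
composition (a multivariate-hypergeometric draw) so items always sum to the
rounded, clipped total and respect the per-item scale (PHQ-9 9×0–3, WHO-5
5×0–5, WHODAS-12 12×0–4, PHQ-15 15×0–2).

**What is not emulated, and what that means.** Real questionnaire data have
item-level factor structure, skewed non-Gaussian marginals beyond what
clipping induces, informative missingness, site effects and medication
heterogeneity; the generator has none of these (MCAR by design, one
correlation parameter, no cross-block dependence).  Passing tests therefore
demonstrate that the *pipeline machinery* is correct and leakage-free under
a cohort with the published first and second moments — not that the printed
real-data accuracies generalize.  Item allocation also makes every item of
a questionnaire exchangeable apart from sampling noise, so the identity of
the "top five" items is a property of the synthetic cohort, not of the
instrument.

## Preprocessing

All transforms are fitted on a training split and applied unchanged
elsewhere.  Rare categorical levels (< 5% of training rows, strict) merge
into `other`; unseen levels map to `other`.  KNN imputation (k = 7) uses a
nan-aware Euclidean distance over standardized continuous coordinates and
one-hot categorical coordinates scaled so one feature mismatch contributes
1; missing cells take the mean (continuous) or lexicographic-first mode
(categorical) of the k nearest training rows.  Standardizing before the
distance is a documented default; the source description is silent.
Yeo-Johnson λ is fitted per feature by maximum likelihood
(scikit-learn's optimizer) with constant features passed through as
identity and flagged; outputs are standardized on the training split.

## Boruta

Each iteration appends a freshly row-shuffled shadow copy of every feature,
fits a class-weight-balanced random forest, and scores a "hit" for every
real feature whose impurity importance exceeds the best shadow importance.
Hits are tested against Binomial(iterations, 1/2): rejections every
iteration at α/p (Bonferroni over the p features), confirmations only at
every 10th iteration with the threshold further divided by the number of
looks (alpha spending over interim analyses).  Features still undecided at
the cap (100 iterations) are confirmed only if their median importance
exceeds the **75th percentile** of the per-iteration shadow maxima.

Two of these choices deserve their rationale.  First, the per-iteration
forest is deliberately small (10 trees, depth 5).  With a large forest the
gain importances are nearly deterministic, and the *luckiest* noise feature
in a fixed sample — whose chance correlation with the labels sits at the
top order statistic — beats the fresh shadow maximum well over half the
time, so the binomial test confirms it no matter the sample size (the
effect is scale-free: chance correlations and shadow maxima both shrink
as 1/√n).  Importance noise from a small forest attenuates such features'
hit rates below 1/2 (measured 0.08–0.45 across null datasets) while planted
features with a 1.5-SD group shift still hit in ≥ 97% of iterations.
Second, the common median-vs-median "rough fix" for leftover tentative
features confirms roughly half of these hovering null features; the upper
quantile restores a conservative resolution without costing clearly
relevant features, which are confirmed by the binomial test long before the
cap.

## Greedy forward wrapper

Starting from the empty set, the wrapper adds the candidate that maximizes
stratified inner-CV balanced accuracy of the boosted-tree model (ties to
the lower candidate index) and stops at the first improvement below ε
(default 0.001).  The recorded trace scores are the actual inner-CV scores
and are bit-reproducible.  A wrapper of this kind needs at least one member
of an interacting pair to carry marginal signal; a pure-XOR pair with zero
marginals is invisible to any forward selection, which is why the
pair-recovery tests plant a marginal component in one member and use an
exhaustive ≤ 2-subset scan as the oracle.

## Pipelines and base models

Boosting hyperparameters are fixed (300 rounds, depth 3, learning rate 0.1,
subsample 0.8, histogram trees): no tuning grid keeps nested CV honest and
cheap.  P4 keeps principal components up to 80% cumulative training
variance, fits a linear SVM (C = 1) with balanced weights, and calibrates
its decision scores with a held-in logistic fit because stacking and the
cascade need probabilities; its feature importances are
|loadingsᵀ·coefficients| mapped back to inputs.  A predicted probability of
exactly 0.5 counts as non-depressed (screening favours specificity).
The registry stores the printed feature counts of the nine models as
metadata; resolved feature lists come from this package's data dictionary
and can be smaller (the source cohort carried e.g. 26 HRV columns across
postures where the tables print six lying-position indices).  The exact
15-item list of the best model is in an unavailable supplement; the shipped
list is synthetic-reference-derived (one Boruta importance pass over the 26
WHO-5 + PHQ-9 + WHODAS items on the reference cohort, top 15 by median
importance, frozen in the registry and marked as such).

## Nested evaluation and the cascade

Stratified 5×5 folds are deterministic per seed; each outer fold fits
imputation, selection and the classifier on outer-train only (inner folds
drive greedy selection and threshold tuning) and predicts outer-test once.
The engine hashes the outer-test rows before and after fitting and raises
on any mutation.  Metrics aggregate as the unweighted mean over outer folds
(pooled-confusion aggregation is available).  The PHQ-9 baseline is
computed on the full cohort's observed totals (whether the source study
cross-validated it is unstated).

Propagation thresholds are tuned on inner CV over the grid
{0.50, 0.55, …, 0.95, 1.00}; ties prefer the smaller propagated fraction
(fewer per-case examinations), then the smaller τ.  Certainty bands use
half-open intervals [0.50, 0.67), [0.67, 0.83), [0.83, 1.0], reading the
printed integer ranges (50–66, 67–82, 83–100) as displayed roundings.  The
second step retrains the full 15-item model (not a residual model), and an
optional biomarker third step exists but is off by default — it did not
improve accuracy in the source study.  Traffic-light cells render as
"correct/total (pct%)" with one decimal; empty cells render as undefined
rather than 0%.

## Subtyping

Clustering consumes only lab + HRV + anthropometric columns (enforced by a
modality filter; the exact source variable list is in an unavailable
supplement, so the default is the full biomarker block, configurable).
The scan covers k = 2–8 × {full, tied, diag, spherical}, each fitted by EM
with 10 restarts and ridge 1e-6; BIC is the selection key with AIC and
silhouette (hard assignments, transformed space) reported alongside, ties
going to fewer parameters.  Profiling and naming use imputed, untransformed
values plus age.  Naming rules: majority vote of highest CRP / lowest SDNN /
highest Baevskii → Immuno-Metabolic; highest BMI remaining → Overweight
Non-Inflammatory; oldest remaining → Late Depression; remainder → Adaptive;
exact ties leave clusters unlabelled with a diagnostic.

A structural finding from the recovery experiments: under this generator
(exchangeable ρ = 0.3 inside blocks, independence across blocks) the true
within-cluster covariance is nearly diagonal, so at n = 360 planted
depressed cases BIC prefers diagonal mixtures and absorbs the residual
block correlation by adding components (k = 5–7), while forced k = 4
diagonal fits recover the planted subtypes well (ARI ≥ 0.7 in 8/10 seeds)
and forced k = 4 *full* fits overfit their ~10³ covariance parameters and
recover poorly.  At the real-study scale (n = 90 against ~47 features) the
regularized full-covariance likelihood is inflated by near-singular
components and full structures *do* win BIC — visible in the subtyping
example — which is plausibly the regime behind the published
four-cluster/full-covariance choice.  A four-component full-covariance
selection is therefore not an expected outcome of this generator at
calibration scale, and the corresponding end-to-end recovery check
documents that gap rather than asserting it away.

## Problem sizes and seeds

Default experiment sizes are chosen for desk-scale reproducibility: the
reference cohort is the published 581/90; calibration checks use 4000–5000
draws per group (≈ 3 standard errors of the printed means); recovery
experiments use 360 planted depressed cases over 10 seeds; the study runner
defaults to three base models and a three-member stack, with the full
nine-model registry available through its configuration.  One global seed
fans out to stage seeds via SHA-256 of `"{seed}:{stage}"` (first four
bytes, mod 2³¹), so any stage can be rerun in isolation.

## Known limitations

Marginal calibration cannot reproduce real item-level structure, so
selected item identities and stacked-model gains are not transferable
claims; the cascade's propagated fraction depends on how separable the
synthetic groups are; subtype recovery statements hold in the transformed
biomarker space of this generator; and no external validation harness
exists, mirroring the source study's own limitation.
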