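# Methods

## Model

Let x_j be subject j's vector of ordinal density scores (0..Z, Z = 4)
over R regions (R = 10 by default), with missing entries allowed. The
model treats disease progression as a sequence of *events*: region r
reaching level z, for z = 1..Z. A subtype is a total order S over all
K = R·Z events in which each region's levels appear in increasing order —
a linear extension of R chains of length Z. The number of such orders is
(RZ)!/(Z!)^R (≈ 1.3·10^34 for R = 10, Z = 4), so the ordering is inferred
by stochastic search rather than enumeration.

A subject at stage k ∈ {0..K} of subtype c has true regional levels
z_r(S_c, k) — the count of region r's events among the first k. The data
likelihood marginalises subtype and stage:

    P(x_j) = Σ_c f_c Σ_k P(k) Π_r p_j(r, z_r(S_c, k)),

with mixture fractions f_c and stage prior P(k).

**Evidence model.** The per-subject probabilities p_j(r, z) encode
measurement uncertainty of the ordinal grading: a Gaussian kernel of
width σ (default 0.5 score units) is evaluated at the integer levels
around the observed grade and normalised to sum to one; the Gaussian
normalising constant cancels. The kernel is evaluated at the levels, not
integrated over bins — the semi-quantitative grade is a point judgement,
not a binned continuous measurement, and the normalised point evaluation
is the convention for ordinal event models. A missing grade gets the
uniform vector 1/(Z+1) (20 % per level), so missing regions contribute a
constant factor to every stage and subtype likelihood and cannot tilt the
fit. Probabilities are floored at 1e-300 before logarithms; all
likelihood computation is in the log domain because 40-factor products
underflow linear double precision.

**Stage prior.** Uniform over the K+1 stages, including stage 0. Stage 0
must be in the support because subjects with (near-)zero pathology are
assigned stage 0 and excluded downstream rather than forced into stage 1.
The prior is exposed as a constructor argument (`stage_prior`) for
sensitivity analyses; the cross-validation experiment below shows why the
choice matters.

**Inclusion rules.** Before modelling, subjects are dropped if no
non-missing region scores ≥ 1 ("no-pathology" — such subjects carry no
ordering information) or if more than `max_missing` regions (default 3 of
10) are missing ("missingness"). A missing region counts as neither zero
nor positive for the pathology rule.

## Fitting

1. **Greedy ascent.** From `n_start_points` (default 25) uniformly random
   valid orderings, single events are relocated to their best improving
   position until a full pass yields no strict improvement (tolerance
   1e-9 on the log-likelihood). Because every valid ordering contains the
   same event set, the per-event log-likelihood increments are
   order-independent and are cached once per fit; scoring all insertion
   positions of one event costs a single O(N·K) sweep using prefix/suffix
   cumulative sums of the exponentiated stage terms.
2. **Hierarchical splitting + EM.** The C-subtype fit starts from the
   fitted (C−1)-model: each subtype in turn is split by randomly
   partitioning subjects in two (responsibility-weighted), refitting an
   ordering on each half, and EM-refining the candidate (fractional
   responsibilities → fraction update f_c = mean responsibility →
   weighted greedy re-optimisation of each ordering) until the
   log-likelihood gain falls below `em_tolerance` (default 1e-6) or
   `max_em_iterations` is reached. Both EM steps increase the standard
   EM lower bound, so the data log-likelihood is non-decreasing. The best
   split is kept; if no split beats the parent model, the largest subtype
   is duplicated with its fraction halved — a model whose likelihood
   equals the parent's — which guarantees the maximum likelihood is
   non-decreasing in C.
3. **MCMC.** Metropolis–Hastings over orderings (default 10,000
   iterations): per iteration and subtype, a uniformly chosen event is
   proposed to move to a uniformly chosen position; proposals that break
   a region chain are rejected, valid ones accepted by mixture-likelihood
   ratio with fractions fixed. The proposal is symmetric, so under a flat
   likelihood the chain's stationary law is uniform over the valid
   orderings (property-tested by chi-square on the 6 orderings of the
   R = 2, Z = 2 space). No burn-in is removed: point estimates come from
   maximum-likelihood tracking, for which burn-in is harmless, and the
   positional variance diagrams use all retained samples; thinning is
   available via `mcmc_thin`. After sampling, fractions are polished by
   fraction-only EM at the ML orderings.

Every stage of the fit is driven by one seeded generator, so the entire
fit is reproducible bit-for-bit from `FitConfig.seed`.

**Model selection.** 10-fold cross-validation with subject-level simple
randomisation (no stratification). CVIC(C) = −2 × Σ_folds held-out
mixture log-likelihood; the selected C minimises CVIC with exact ties
broken toward fewer subtypes. The held-out log-likelihood is the
*posterior predictive*: per subject, the mixture likelihood is averaged
over the training fit's retained MCMC draws before taking the log. A
plug-in evaluation at the ML orderings alone would bias selection upward
— a richer mixture then wins merely by hedging the ordering uncertainty
that a smaller model's point estimate ignores — and in replicate
experiments that bias flips roughly half of single-trajectory cohorts to
a two-subtype verdict.

## Subject assignment

The subtype posterior is proportional to f_c times the stage-marginal
likelihood, averaged over the retained MCMC samples (equal weights). The
stage is the argmax over k of the sample-averaged stage likelihood under
the assigned subtype — an integer 0..40 matching how stages are reported;
ties go to the smaller stage, so an all-zero subject lands at stage 0.
When subtype posteriors tie (typical at early stages where orderings
share a head), the subtype with the larger mixture fraction wins — the
dominant pattern is a priori more probable. A subject enters downstream
statistics only if stage ≥ 1 and the winning posterior exceeds the
confidence threshold (default 0.5).

## Downstream statistics

* **Stage correlations** are two-sided Spearman correlations on included
  subjects, pooled or per subtype; constant inputs are flagged as
  degenerate rather than returning silent NaN.
* **Subtype comparisons** fit a single model per outcome with subtype as
  a categorical predictor, adjusted for age, sex and stage: OLS for
  continuous outcomes, binomial GLM for binary, and one-vs-reference
  logits for nominal outcomes with the largest subtype (and the most
  common outcome category) as reference. Pairwise contrasts are Wald
  tests of coefficient differences from that one fit;
  Benjamini–Hochberg FDR is applied across the returned family on
  request. Suspiciously large logistic coefficients are flagged as
  possible separation.
* **Sliding windows** repeat the comparison on subjects inside the
  inclusive stage intervals [w, w+width−1], w = 1..(40−width+1) — 31
  windows at the default width 10, slide 1. Windows with fewer than
  `min_n` subjects or without two subtypes are reported with status
  `insufficient-n`, never silently dropped.
* **Peripheral trajectories** LOESS-smooth the total non-brain pathology
  score (0–28, the sum of seven spinal-cord/peripheral 0–4 scores) over
  stage per subtype, evaluated on stages 1..40 and clipped to [0, 28].
  The span defaults to 0.75 and is exposed; subtypes with fewer than 10
  observed totals are skipped with a warning.
* **USSLB stager** (simplified): stage I = olfactory-bulb pathology only;
  IV = any neocortical region ≥ 2; otherwise IIa / IIb by whether the
  brainstem or limbic score sum dominates, III when both are involved at
  comparable levels (|difference| ≤ 1, configurable). The published
  system's density thresholds live in its source staging papers; this
  operationalisation is deliberately simple and labelled as such.

## Synthetic cohorts

The generator draws each subject a subtype from the mixture fractions and
a stage from a uniform or mildly early-skewed (truncated geometric,
decay 0.05/stage) distribution, sets the true regional levels from the
subtype's ordering, and corrupts them with the same normalised Gaussian
kernel the analysis uses as evidence model (degenerate at noise 0). This
self-consistent generative/inference pair is deliberate: recovery
experiments then test the estimator, not an unknown noise mismatch. A
`noise_skew` option inflates the upward tail of the kernel to probe
robustness under a mismatched asymmetric noise law. Missingness is
MCAR at a configurable rate.

The bundled three-subtype preset emulates the qualitative Lewy-pathology
trajectories: S1 olfactory-bulb and limbic regions early (fraction
0.608), S2 olfactory-bulb then brainstem (0.211), S3 brainstem-first with
the olfactory bulb's first event after position 25 (0.181). Orderings are
built from per-region onset times (events sorted by onset + level gap),
which produces valid, plausibly interleaved chains.

Covariates carry the stated stage/subtype structure: age at death =
85 − 0.15·stage + N(0, 7), rounded and top-coded at 90 (cohort-level
Spearman ρ(stage, age) ≈ −0.2); total brain pathology is the observed
score sum for complete cases; the non-brain total is Poisson around a
subtype-specific piecewise-linear mean over stage (onset stage 12 for the
limbic-early preset, onset 0 for the brainstem-early presets; plateaus
near stages 25/20/18), capped at 28. Poisson noise — not clipped
Gaussian — keeps pre-onset totals exactly zero, matching the zero-inflated
character of sums of sparse ordinal scores. Plaque/tangle burdens and a
binary diagnosis label have configurable per-subtype means/log-odds;
`EffectSpec.null()` removes all structure for type-I-error experiments.

What the generator does **not** emulate: informative missingness
(real sampling loss correlates with tissue quality and site), rater drift
and batch effects in grading, correlated noise across regions, and any
biophysical spreading mechanism. Passing recovery tests therefore show
the estimator works under its assumed measurement model at realistic
noise, not that the assumptions hold in autopsy data.

## Problem sizes and numerical choices

Validation experiments use desk-scale sizes chosen to exercise the method
end to end: exhaustive-oracle checks on R = 3, Z = 2 (90 valid
orderings, agreement required to 1e-10); parameter recovery at N = 600,
C = 2, kernel noise 0.5, 2,000 MCMC iterations; model selection with
10-fold CV at N = 300 over 10 replicate seeds with 250 MCMC iterations
per fold; type-I error over 1,000 simulated null outcomes. Greedy-ascent
acceptance uses a strict-improvement tolerance of 1e-9; probability rows
are validated to sum to one within 1e-12; positional-variance rows to
within 1e-9.

The model-selection experiment draws stages uniformly so the generative
stage law matches the model's uniform stage prior and the experiment
isolates the subtype-count question; with the early-skewed law the
selection rate at C_true = 1 is only mildly lower. For real data whose
stage distribution is far from the assumed prior, refitting with an
adapted `stage_prior` is the available sensitivity analysis.

## Known limitations

* Total orders only; no partial-order or DAG event structures.
* MCAR missingness in the generator; the analysis tolerates (and is
  invariant to) missing entries but offers no imputation.
* The greedy/EM search is a local optimiser with random restarts; for
  C > 2 on weakly separated data, different seeds can land on different
  local optima (the CVIC experiment quantifies this only for C ≤ 2).
* The USSLB stager is a simplified operationalisation for
  cross-tabulation, not a reimplementation of the published criteria.
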