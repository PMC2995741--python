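# Methods

This note records the statistical model behind `ersig`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical choices that matter for reproducibility.

## Bimodality coefficient

For a sample of size n, with bias-corrected skewness g1 and excess
kurtosis g2 (the SAS definitions),

    b = (g1² + 1) / (g2 + 3(n−1)² / ((n−2)(n−3))).

In the large-sample limit b = 1/3 for a normal distribution, 5/9 ≈ 0.5556
for a uniform one, and approaches 1 for a well-separated two-point mixture.
The screening threshold 0.555 is the uniform benchmark: a gene must look
"flatter than uniform" before we treat it as bimodal. The statistic is
invariant to affine transforms of the data, so it is insensitive to
platform-specific scaling of log2 intensities. It requires n ≥ 4 and a
non-degenerate sample; both preconditions raise errors rather than return
NaN, because silent NaNs would propagate into the gene screens.

Caveat: b is a necessary-condition screen, not a test. A heavily skewed
unimodal gene can exceed 0.555; the downstream error-rate screen against
IHC labels is what removes such genes from the signature.

## Two-component Gaussian mixture

Expression of an informative gene across a cohort is modelled as
π_low·N(μ_low, σ_low²) + π_high·N(μ_high, σ_high²). Fitting is plain EM:

* initialisation from the empirical 25th/75th percentiles (means) with half
  the pooled SD (both component SDs) and equal proportions, plus
  `n_starts = 5` restarts whose means are random pairs of observations;
  the best final log-likelihood wins. The quantile start alone is already
  reliable for separated modes; the restarts guard against the rare
  degenerate basin.
* convergence when the log-likelihood improves by less than `tol = 1e-6`,
  capped at `max_iter = 500`;
* a variance floor of `1e-4` (log2 units²) so a component cannot collapse
  onto a single point and blow up the likelihood;
* components relabelled so μ_low ≤ μ_high; the fit is therefore invariant
  to label order by construction.

A fit whose mean separation is below 2·max(σ) is flagged as overlapping:
the "two components" are then a description of a unimodal shape, not of two
expression states, and classifiers treat such genes through a fallback (see
below). Requires n ≥ 10.

## Cutoff and error rates

The classification cutoff between the components is the equal
1-D-Mahalanobis-distance point

    c = (μ_low σ_high + μ_high σ_low) / (σ_low + σ_high),

the unique x between the means with (x−μ_low)/σ_low = (μ_high−x)/σ_high.
Model-based error rates at a cutoff c are the per-component conditional
tail masses FPR = 1 − Φ((c−μ_low)/σ_low), FNR = Φ((c−μ_high)/σ_high); with
equal variances c minimises their sum (verified against a grid-search
oracle in the tests). The rates are deliberately unweighted by the mixing
proportions — they are conditional error rates of each expression state,
matching the FPR/FNR reading. The proportion-weighted Bayes boundary
(solving π_low f_low(c) = π_high f_high(c)) is available as
`cutoff_rule="bayes"`; the two coincide for equal variances and priors. The
equal-distance rule is the default because it is prevalence-free: a cutoff
derived in a 70%-ER+ cohort transfers more sensibly to a cohort with a
different case mix.

## Signature derivation

Stages, in order, each consuming the previous stage's gene list:

1. **Present-call filter** — keep genes detected in strictly more than
   `min_fraction = 0.5` of samples (detection mask is an input; computing
   detection calls from raw arrays is out of scope).
2. **Stromal exclusion** — on paired epithelium/stroma profiles, per gene,
   a linear mixed model `expression ~ compartment` with a per-patient
   random intercept; one-sided test for stroma > epithelium;
   Benjamini–Hochberg at `alpha = 0.05` across genes. The Wald statistic is
   referred to a t distribution with (patients − 1) degrees of freedom: the
   asymptotic normal is visibly anti-conservative with ~10 donors and
   produced false exclusions in calibration runs.
3. **Dispersion/bimodality screen** — sample SD > 1 (log2 scale) and
   b > 0.555.
4. **Error-rate screen** — per gene: mixture fit, cutoff, orientation by
   the sign of the point-biserial correlation with the binary IHC label
   (weight +1 if high expression marks ER+, −1 otherwise; zero correlation
   drops the gene), then empirical FPR (IHC− samples called positive) and
   FNR (IHC+ called negative); retain when both < `max_rate = 0.05`.

The vote threshold is the strict majority `floor(k/2) + 1` of the k
retained genes — 12 when k = 23. An alternative orientation reference
(`weight_reference="esr1"`: sign of the Pearson correlation with the ESR1
row) is provided; on coherent cohorts the two coincide, and the IHC-label
orientation is the default because it does not presume a trustworthy ESR1
probe.

Feasibility constraint worth stating explicitly: the error-rate screen
compares gene calls to IHC labels, so the label error of the *reference*
cohort bounds what any gene can achieve. At ER prevalence 0.7, an IHC
false-negative rate f contaminates the IHC-negative group with a fraction
0.7f / (0.7f + 0.3(1−f_p)) of true-ER+ samples; keeping that comfortably
below the 0.05 screen requires f ≲ 0.02. Derivation therefore presumes a
curated reference cohort (the simulator's `reference_cohort()` preset uses
1% label noise), while validation cohorts may be far noisier.

## Classification

* **ESR1 classifier**: fit the mixture to the ESR1 row of the *target*
  cohort, call positive above the cutoff. If ESR1 is not bimodal there
  (b ≤ 0.555 — e.g. a series containing only ER-negative tumours), the
  cutoff is meaningless: a warning is raised, or in `strict` mode the
  cohort is refused.
* **Signature classifier**: per signature gene, re-derive the cutoff in
  the target cohort (absolute log2 levels are not portable across
  platforms; the bimodal split is). Gene g votes a sample positive when
  `w_g (x − c_g) > 0`; exact equality is a negative vote ("exceed" is
  strict). A gene that is not bimodal in the target cohort falls back to
  the cohort median as its cutoff (default), to the reference-cohort
  cutoff (`"reference"`), or is dropped with the vote threshold rescaled
  to the strict majority of the genes used (`"drop"`). The median default
  assumes only that the cohort is mixed; the reference cutoff assumes
  comparable normalisation, which is the stronger assumption. Missing
  values make a gene abstain for that sample; abstentions count toward
  neither side and the threshold is unchanged, so a sample with many
  missing genes is biased toward a negative call — documented, configurable
  only by imputing upstream.
* **Concordance** between call sets: agreement fraction, 2×2 table, and a
  two-sided Fisher exact test on the shared samples.

## Survival evaluation

* **2-year cap.** The excess hazard of ER-negative disease is
  front-loaded; all ER hazard ratios are computed with follow-up
  administratively censored at `cap_years = 2` (capping is idempotent and
  never adds events). Proliferation analyses use a 5-year horizon.
* **Cox fits** use lifelines (Efron ties). ER coding: ER− = 1, so HR > 1
  means worse outcome for ER-negative patients. MKI67 enters as a
  within-cohort z-score, continuous (no dichotomisation).
* **Meta-analysis**: fixed-effect inverse-variance pooling with Cochran's
  Q; with the typical four cohorts a random-effects variance estimate
  would be unstable, so fixed-effect is the default.
* **Flip-null test**: with d = #(expression call ≠ IHC call), flip d
  random IHC calls B times, recompute the capped HR each time, and report
  the add-one permutation p, (1 + #{HR_null ≥ HR_obs}) / (B + 1) — never
  exactly zero. Replicates with divergent Cox fits (separation) count as
  exceeding, which is conservative.
* **Resampling comparison**: patients are bootstrapped with replacement
  within each cohort; each replicate recomputes the pooled HR under both
  classifications of the same resampled patients; the reported one-sided p
  is the fraction of replicates where the challenger's HR is no larger
  than the incumbent's, ties counted half (so identical classifications
  give p = 0.5). This is one concrete reading of "resampling the reference
  data sets"; it compares classifiers on identical bootstrap draws, which
  removes the shared sampling noise from the comparison.
* The resampling loops use an internal Newton solver for the
  single-binary-covariate Efron partial likelihood, vectorised across
  replicates (a calibration experiment needs ~250,000 Cox fits). It is
  validated against lifelines to 1e-3 in the tests and is not part of the
  public API.
* **KM export**: product-limit estimates with Greenwood CIs per group plus
  a log-rank p, written as a tab-delimited step-function table.

## Synthetic cohorts

`simulate_cohort` draws: latent ER+ ~ Bernoulli(0.7); 23 signature genes
(ESR1 first, 30% of the rest oriented −1) as N(6,1) / N(11,1) mixtures
conditioned on the latent state (5σ separation); MKI67 as a continuous
proliferation z-score; 30 stromal genes that are ER-correlated and bimodal
in the tumour cohort — indistinguishable from signature genes by every
in-cohort screen — but elevated by 3 log2 units in stroma in the paired
compartment dataset, so that only the stromal-exclusion stage removes
them; background genes N(8, 0.5²), 15% of them poorly detected to exercise
the present-call filter; IHC labels = latent state corrupted at
`ihc_fnr = 0.15` / `ihc_fpr = 0.05` (the false-negative regime the method
targets; the `reference_cohort()` preset uses 1% — see the feasibility
constraint above); survival exponential with hazard
0.08 · 2^[ER−] · 3^(z·[ER+]) per year, exponential censoring at rate 0.05
plus a 10-year administrative cap. Compartment data: 10 donors × 2
compartments, patient random intercept SD 0.5, residual SD 0.5.

What the generator does **not** emulate: probe-level noise and
cross-hybridisation, batch and platform effects, correlated gene modules
(genes are conditionally independent given the latent state), intra-tumour
heterogeneity, non-proportional hazards, and informative censoring.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under its own assumptions, not clinical performance on real
cohorts.

A consequence of the survival model worth flagging: with the proliferation
effect active, the *marginal* ER hazard ratio is attenuated below the
conditional `hr_er_negative = 2.0` (the ER+ group contains high-z
fast-progressing tumours). Experiments whose estimand is the pure ER
effect — CI coverage of HR 2.0, flip-null power — therefore switch the
proliferation effect off (`hr_mki67_within_erpos = 1`), while the
MKI67-stratification and interaction analyses use the full model.

## Problem sizes used in the automated experiments

Chosen as the smallest sizes at which each property is a stable,
interpretable statement: cohorts of n = 600 (n = 300 for the 500-replicate
flip-null calibration, n = 800–1200 where per-stratum event counts or
power demand it); 60-gene matrices for survival-only experiments where the
expression content is irrelevant; the full 2000-gene, 600-sample reference
cohort for the planted-signature recovery run. Mixture-recovery and
cutoff-oracle checks use 50–100 replicates; CI coverage uses 200; flip-null
calibration uses 500 replicates of B = 500.

## Known limitations

* The EM fit assumes exactly two Gaussian components; k > 2 and
  non-Gaussian shapes are out of scope.
* The stromal mixed model assumes one shared random intercept per patient;
  compartment-specific variances are not modelled.
* The flip-null and bootstrap procedures condition on the observed
  discordance count d; they do not propagate classifier-training
  uncertainty.
* `classify_signature` re-fits mixtures per target cohort, so calls on very
  small cohorts (n < ~50) inherit unstable cutoffs; the median fallback
  mitigates but does not remove this.
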