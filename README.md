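# ersig

Expression-based classification of oestrogen receptor (ER) status in breast
cancer, with a survival-based evaluation framework.

## The problem

ER status decides whether a breast-cancer patient is offered endocrine
therapy. The clinical standard — immunohistochemistry (IHC) — is
semi-quantitative and subjectively thresholded, and a false negative call
denies a patient an effective treatment. On microarray data, however, the
log2 expression of *ESR1* (and of a broader set of epithelial,
ER-state-dependent genes) is strongly **bimodal** across a cohort: the two
modes track the underlying receptor status. `ersig` exploits that
bimodality to build two classifiers and to ask, via survival analysis,
whether their calls are clinically more homogeneous than IHC's.

## Methods in brief

**Bimodality screen.** A gene's coefficient of bimodality is
`b = (g1² + 1) / (g2 + 3(n−1)²/((n−2)(n−3)))` with bias-corrected sample
skewness `g1` and excess kurtosis `g2`. For a uniform distribution
`b → 5/9 ≈ 0.556`; genes with `b > 0.555` are considered bimodal.

**Mixture threshold.** A gene's expression is decomposed by EM into two
Gaussian components `N(μ_low, σ_low²)` and `N(μ_high, σ_high²)`. The
cohort-specific cutoff is the point of equal one-dimensional Mahalanobis
distance to both components,

```
c = (μ_low·σ_high + μ_high·σ_low) / (σ_low + σ_high),
```

which for equal variances minimises the summed model-based false positive
and false negative rates (the tail masses `1 − Φ((c−μ_low)/σ_low)` and
`Φ((c−μ_high)/σ_high)`).

**Single-gene classifier.** A sample is ER+ iff its *ESR1* expression
exceeds the cohort's mixture cutoff.

**Voting signature.** From a reference cohort with IHC labels, genes are
filtered (present in >50% of samples), purged of stromally expressed genes
(mixed-effects model on paired epithelium/stroma profiles), screened for
dispersion and bimodality (SD > 1, b > 0.555), and kept only if their
oriented empirical FPR and FNR against IHC are both < 0.05. Each retained
gene gets weight w = ±1 (the sign of its correlation with ER status). In a
target cohort every gene re-derives its own cutoff `c_g`; gene g votes a
sample positive when `w_g·(x_gs − c_g) > 0`, and the sample is called ER+
when a strict majority (12 of 23) votes positive.

**Evaluation.** ER-negative vs ER-positive Cox hazard ratios on follow-up
capped at 2 years, pooled across cohorts by fixed-effect inverse-variance
meta-analysis; a flip-null test (is the classifier's HR larger than HRs from
flipping the same number of random IHC calls?); a stratified patient
bootstrap comparing two classifications; proliferation (*MKI67*) hazard
ratios within ER strata and an ER×MKI67 interaction model; Kaplan–Meier
export.

Because real microarray cohorts cannot ship with the package, a synthetic
generator (`ersig.simulate`) produces expression + clinical cohorts with a
known latent ER state, noisy IHC labels, planted signature and stromal
genes, and survival driven by ER state and proliferation.

## Worked example

```python
from ersig import *

# derive the signature on a simulated reference cohort (curated labels)
cfg = SimulationConfig.reference_cohort(seed=11)
matrix, clinical, truth = simulate_cohort(cfg)
compartments, _ = simulate_compartment_data(cfg)
signature = derive_signature(matrix, clinical.df["ihc_er"], compartments, seed=3)
print(len(signature), signature.vote_threshold)
print(signature.provenance["stage_counts"])

# classify an independent validation cohort (15% IHC false-negative rate)
m_val, clin_val, _ = simulate_cohort(SimulationConfig(seed=99))
calls_sig = classify_signature(m_val, signature, seed=4)
calls_esr1 = classify_esr1(m_val, "ESR1", seed=4)
frac, table, p = concordance(calls_sig, calls_esr1)
ihc = ERCallSet.from_labels(clin_val.df["ihc_er"])
est = cox_hr(clin_val, 1 - calls_sig.as_binary(), cap_years=2.0)
```

This prints (seeds as above):

```
23 12
{'input': 2000, 'present_call': 1708, 'after_stromal_exclusion': 1678,
 'bimodal_screen': 23, 'error_rate_screen': 23}
```

and the downstream comparisons report a 99.5% signature-vs-ESR1 concordance
(Fisher exact p ≈ 3e-157), a 90.7% signature-vs-IHC concordance — the
discordant tenth being dominated by the simulated IHC label noise — and a
2-year hazard ratio for signature-based ER-negative disease of
HR = 1.55 (95% CI 1.12–2.14). All 23 planted signature genes were
recovered with no off-target entries, and the vote threshold is the strict
majority 12.

The same workflow is available from the shell:

```bash
ersig simulate --seed 7 --reference --out cohort/
ersig derive-signature --expression cohort/expression.tsv \
    --mask cohort/present_calls.tsv --clinical cohort/clinical.tsv \
    --compartment-expression cohort/compartment_expression.tsv \
    --compartment-annotation cohort/compartment_annotation.tsv \
    --seed 1 --out signature.tsv
ersig classify --expression cohort/expression.tsv --signature signature.tsv \
    --seed 2 --out calls.tsv
```

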