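# connsig

Connectome predictive modeling of reduced sleep: train a brain-wide
neurosignature of a latent sleep-duration factor from functional
connectomes, transport it to new cohorts as an expression score, and test
whether independently derived signatures agree spatially.

## The problem

Short sleep in adolescence is associated with widespread changes in the
brain's intrinsic functional architecture, but two questions are hard to
answer from a single cross-sectional sample: do *changes* in sleep track
changes in the brain signature over years, and is the signature a
*consequence* of reduced sleep rather than a cause? `connsig` implements a
complete analysis pipeline for this design:

1. **Signature training.** Parcellated resting-state BOLD runs are censored
   at framewise displacement (FD) > 0.5 mm, runs with < 4 min of retained
   data are excluded, and nuisance signals (linear trend, motion and
   physiological regressors, a 0.008 Hz discrete-cosine high-pass basis,
   and spike regressors for censored volumes) are removed in a single
   regression. Per-run Pearson correlation matrices are Fisher r-to-z
   transformed and averaged into one connectome per subject; the upper
   triangle (edges x = (z_e)) is the feature vector. A latent
   sleep-duration factor η is fit to three noisy duration indicators
   (parent-report, child-report, wearable device) — a just-identified
   one-factor model with closed-form triad loadings λ₁ = √(r₁₂r₁₃/r₂₃) —
   and regression-method factor scores (negated: "reduced sleep") are the
   prediction target. Principal component regression (PCR) maps edges to
   the target: ŷ = (x − x̄)ᵀ w + b with w = V_K β, where V_K are the top-K
   PCA loadings and β the component betas. K is chosen by the 1-SE rule in
   nested cross-validation; generalization is summarized as r_cv, the mean
   held-out correlation under leave-one-site-out CV, controlling sex, age,
   age², mean FD and mean FD². For interpretation the decoding weights are
   converted to an activation pattern by the Haufe transform,
   a = Cov(x) w / Var(ŷ).
2. **Permutation inference.** Significance of the multivariate association
   uses Freedman–Lane permutation of reduced-model residuals, restricted
   by exchangeability blocks (twins within families within sites), with
   p = (b + 1)/(B + 1).
3. **Signature transport.** The signature is a single edge-weight map;
   its dot product with any connectome (identical edge ordering, enforced
   by hash) is an expression score. Longitudinal change in expression is
   regressed on change in sleep duration in a linear mixed model with a
   site random intercept (standardized coefficients); in a within-subject
   sleep-deprivation cohort, the deprived-minus-typical expression
   difference is tested with a covariate-adjusted intercept t-test.
4. **Spatial correspondence.** The deprivation cohort yields its own
   contrast signature (PCA of residualized connectomes, mean session
   difference in the first 21 component scores mapped back to edges). The
   Pearson correlation across edges between the two signatures is tested
   against a dual-permutation null that shuffles the phenotype in the large
   cohort and flips session labels in the small one.

Because the motivating datasets are access-restricted, the package ships a
synthetic-cohort generator (`connsig.simulate`) producing multisite,
family-structured cohorts with a planted effect — per SD of reduced sleep,
within-somatomotor connectivity rises and within-visual connectivity falls
— plus motion confounds, a two-timepoint cohort, and a paired deprivation
cohort. Every stage of the pipeline is exercised and tested against this
generator.

## Worked example

Run the packaged end-to-end workflow (300 synthetic subjects, 30 parcels,
4 sites) and print the four stage results:

```bash
connsig all --outdir out --seed 11
```

```json
{
  "correspondence_p": 0.004975124378109453,
  "correspondence_r": 0.901944954867885,
  "deprivation_mean_difference": 0.9540934326467443,
  "deprivation_t": 29.813507155672575,
  "longitudinal_p": 0.3620201835152823,
  "longitudinal_standardized_beta": -0.07978981666769736,
  "r_cv": 0.7845913566454632,
  "r_cv_permutation_p": 0.004975124378109453
}
```

Reading the output: `r_cv` is the mean held-out correlation between
predicted and observed reduced-sleep scores across sites (strongly positive
because the planted effect is deliberately large), with its Freedman–Lane
permutation p-value at B = 200. `longitudinal_standardized_beta` is the
standardized coefficient of expression change on sleep-duration change —
negative, i.e. less sleep, more expression of the reduced-sleep signature
(the fixture's longitudinal sample of 300 is small, hence the modest
p-value). `deprivation_t` is the covariate-adjusted t statistic for the
within-subject expression increase after sleep deprivation, and
`correspondence_r`/`correspondence_p` quantify the spatial agreement of the
cross-sectional and deprivation signatures against the dual-permutation
null. Individual stages (`simulate`, `connectome`, `factor`, `train`,
`express`, `longitudinal`, `deprivation`, `correspond`) can be run
separately against a YAML config; artifacts are plain TSV/JSON and are
byte-identical across reruns of the same config and seed.

As a library:

```python
from connsig import SimConfig, simulate_cross_sectional, train_neurosignature
```

builds the same objects programmatically; estimators
(`SleepFactorAnalysis`, `PCRSignature`, `CovariateResidualizer`) follow
scikit-learn fit/transform conventions.

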