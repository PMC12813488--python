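# Methods

## Connectome construction

A subject's connectome is built from parcellated BOLD run time series in
four steps. (1) Volumes with framewise displacement strictly above 0.5 mm
are marked censored; the boundary value is retained. (2) A run is eligible
only if its retained volumes span at least 4 minutes (retained · TR ≥
240 s). (3) Nuisance removal is a single multiple regression per parcel
whose design contains an intercept, a linear trend, the run's nuisance
columns (motion and physiological regressors, consumed as given), a
discrete-cosine basis spanning fluctuations slower than 0.008 Hz (K =
⌊2·n·TR·f_c⌋ columns, implementing high-pass filtering inside the same
regression), and one spike regressor per censored volume. Spike regressors
force the censored rows to zero residual; those rows are additionally
excluded from the correlation. Both mechanisms are applied by default
because either alone can leave censoring leakage; `subject_connectome`
exposes `exclude_censored_from_corr` for the regression-only variant.
(4) Per-run Pearson correlations over retained volumes are Fisher
r-to-z transformed (|r| clipped to 1 − 1e−7 with a warning if an edge is
degenerate) and averaged across eligible runs. Edges are vectorized in
row-major upper-triangle order (i < j); every persisted artifact carries a
hash of the parcel count and labels, and cross-dataset dot products refuse
mismatched hashes rather than reorder silently. Global signal regression
is deliberately absent.

## Latent sleep factor

Three duration indicators (parent-report, child-report, device) feed a
single-factor model. With three indicators the model is just-identified:
zero degrees of freedom, exact reproduction of the observed 3×3
correlation matrix, and closed-form standardized loadings
λ₁ = √(r₁₂·r₁₃/r₂₃) (cyclic for λ₂, λ₃). All three pairwise correlations
must be positive (the loadings are sign-fixed positive); an implied
loading ≥ 1 raises a Heywood error naming the offending triad. Scores use
the regression (Thurstone) method, w = R⁻¹λ on indicators standardized
with training means/SDs, whose correlation with the true factor is bounded
by the determinacy √(λᵀR⁻¹λ) — the parameter-recovery tests check the
estimated scores approach this bound. The prediction target of the
neurosignature is the *negated* score ("reduced sleep"), so that positive
signature expression corresponds to shorter sleep. Where a weighted mean
of school-day and free-day durations is needed, the 5:2 weekly weighting
(5·weekday + 2·weekend)/7 is used. Subjects missing any indicator receive
NaN scores and are dropped by downstream stages (complete-case analysis).

## Signature training

Edges are centered but not per-edge scaled before PCA — all edges share
the Fisher-z scale, and per-edge scaling would inflate noisy edges. The
component count is selected in nested cross-validation by the 1-SE rule:
over a roughly geometric grid capped at min(n/10, 250) and always
containing 21 (the fixed count used for small-sample parity, below), pick
the smallest K whose mean inner-CV squared error is within one standard
error (computed at the argmin) of the minimum. Inner folds (5 by default)
are grouped by site when at least that many training sites exist,
otherwise plain shuffled K-fold with the configured seed. Outer evaluation
is leave-one-site-out: covariates (sex, age, age², mean FD, mean FD²) are
residualized out of the phenotype — and, by default, the edges — with
coefficients fit on the training sites only and applied to the held-out
site; whether to residualize the edge features is exposed as a flag
(`residualize_X`) since either convention is defensible, and the default
keeps features and target in the same covariate-free space. The summary
r_cv is the mean held-out Pearson correlation across sites; sites with
fewer than two subjects, or degenerate (zero-variance) data, yield NaN
with a warning and are excluded from the mean.

The final signature refits the whole sample with the rounded mean of the
per-fold K (ties round upward) and collapses loadings against betas into
one edge map w = V_Kᵀβ, with intercept bookkeeping such that the training
mean connectome predicts the training mean score. The Haufe transform
a = Cov(X)·w / Var(ŷ) — equivalently the per-edge covariance with the
predicted score, rescaled — converts decoding weights into an activation
pattern; a is the display/comparison map, w the prediction map.

## Permutation inference

Significance uses the Freedman–Lane scheme: fit the reduced
(covariates-only) model, permute its residuals, add them back to the
reduced fit, recompute the statistic. Permutations respect a nested block
tree: subjects never cross sites; families exchange as intact units with
same-size families within their site; within a family, twin pairs exchange
as units against same-size units and twins permute within their pair. A
twin whose co-twin was excluded upstream is treated as a singleton.
Permutations are sampled with replacement from the valid set; p-values use
(b + 1)/(B + 1), so a statistic exceeding all B = 10,000 draws reports
p ≈ 0.0001. The statistic is a user-supplied callable; the provided
default is the in-sample multiple correlation between the (residualized)
outcome and its projection onto a fixed number of principal components,
with the PCA basis precomputed once — the basis does not depend on the
outcome, so each permutation costs only a small least-squares refit.
Re-running the full nested-CV selection per permutation is intentionally
not done; the calibration simulations show the cheap statistic holds the
nominal type-I rate.

## Expression models

An expression score is the dot product of signature weights with a
connectome edge vector — linear, and comparable only across identical edge
orderings. The longitudinal model regresses the change in expression
across two timepoints on the change in sleep duration with a random site
intercept, controlling sex, age difference (linear and quadratic), and
mean motion at each timepoint (linear and quadratic). Outcome, predictor
and covariates are z-scored on the analysis sample before fitting, so the
reported coefficient is a standardized beta, invariant to affine
rescaling of the raw sleep units. If the mixed fit fails or is singular,
the model falls back to OLS with cluster-robust (by site) standard errors
and flags the method in its output. A change-score formulation is used
rather than a two-timepoint random-slope model: the change in expression
is the scientific outcome, and the simpler model is exactly identified by
it. The deprivation contrast regresses the per-subject
(deprived − typical) expression difference on an intercept plus
mean-centered covariates (sex, age group, motion on each scan); centering
makes the intercept the covariate-adjusted mean difference, and its t-test
is the reported statistic.

## Spatial correspondence

The deprivation cohort's own signature is built by residualizing both
sessions' connectomes against sex, age group and per-scan motion (one
joint fit over the stacked data), running PCA on the stacked residuals,
averaging each subject's deprived-minus-typical difference in the first
21 component scores, and mapping the mean difference back to edges through
the loadings. The fixed count 21 matches the large-sample signature's
component scale so the two maps live in comparable subspaces.
Correspondence is the Pearson correlation across edges between the
large-sample Haufe pattern and the contrast map (both are
covariance-scale patterns; correlating the raw prediction weights instead
is available via `use_haufe=False`). Its null distribution comes from a
dual permutation: per iteration the large-sample phenotype is shuffled
across subjects and the signature rebuilt with the same fixed K (the PCA
basis is phenotype-independent and reused), while each deprivation pair's
session labels are flipped by a fair coin — algebraically, a flip negates
that subject's score-difference contribution. The default p-value is
one-sided (positive correspondence is the scientific hypothesis);
two-sided on |r| is available. Degenerate zero-variance null maps are
redrawn and counted.

## Synthetic cohorts

The generator emulates the assumed data structure, not its surface
realism. Parcel time series are drawn from a network-block correlation
matrix (within-network r = 0.35, between-network r = 0.05, per-subject
block jitter SD 0.03, eigenvalue-clipped to the nearest valid correlation
matrix), so connectomes must be *estimated* through the full
censor/clean/correlate path rather than sampled directly. The planted
effect shifts within-somatomotor edges by +0.10 and within-visual edges by
−0.08 correlation units per SD of reduced sleep — large enough that a
few-hundred-subject cohort recovers it clearly, which is the point of the
recovery tests. The latent sleep factor has site (5%), family (15%) and
individual (80%) variance components; twin pairs sit inside families
inside sites. Indicators load 0.8/0.6/0.5 on the latent factor and are
reported in hours. Motion is lognormal per subject, mildly anti-correlated
with sleep, with per-volume spikes that trigger censoring; a
motion-tracking common signal is injected into all parcels (and into the
first nuisance column), so correlations are inflated for high-motion
subjects unless the nuisance regression is applied — this is what makes
covariate and nuisance control testable. Nuisance columns also leak
directly into the parcel series.

The longitudinal cohort reuses the cross-sectional background for
baseline connectomes but constructs the timepoint-2 *change* directly at
the edge level: a pattern-direction component whose standardized
correlation with the observed sleep change equals the requested coupling
exactly (default 0.10, oriented so decreased sleep increases expression),
plus pattern-orthogonal edge noise. Building the change through finite
time series would attenuate the planted coupling by an edge-estimation
factor that depends on run length, making "recover the planted value" an
ill-posed target; the edge-level construction keeps the ground truth
exact while the expression and mixed-model machinery is still exercised
end to end. The deprivation cohort generates both sessions as time series
from target correlation matrices differing by `deprivation_shift` (default
1.5 SD-equivalents of the planted map — acute total deprivation is
modeled as a large manipulation) with independent session sampling noise.

What passing tests show — and do not. The recovery tests demonstrate that
the pipeline's estimators are consistent and correctly signed under the
assumed generative model (block covariance, linear effects, Gaussian
noise, one-factor indicators). They do not establish effect sizes,
power, or robustness on real imaging data, where hemodynamics, spatial
autocorrelation, non-Gaussian motion artifacts and site scanner
differences are far richer than the generator's idealizations. Reported
synthetic r_cv values are far higher than plausible real-data values
because the planted effect is deliberately strong.

## Numerical choices and problem sizes

Rank-deficient nuisance designs drop collinear columns (pivoted QR) with a
warning; rank-deficient covariate designs raise, naming the columns. PCA
uses dense SVD with a 1e−12 relative singular-value cutoff. Permutation
p-values never report zero by construction. Fisher-z clipping margin is
1e−7. Mean-K rounding is nearest-integer, ties upward. Edge tables are
written with 17 significant digits (lossless float64 round trip) and all
artifacts are timestamp-free, so identical configs and seeds produce
byte-identical files. Test and acceptance runs use scaled-down cohorts
chosen as the package's standard problem sizes: signature recovery at
n = 600 subjects, 30 parcels, 6 sites, two 130-volume runs (TR 2.5 s);
longitudinal recovery at n = 1500; deprivation at n = 76 with two
150-volume runs (TR 2.4 s); calibration simulations at 100–400 replicates
with B = 200 permutations. Larger cohorts change runtimes, not code paths.

## Known limitations

The generator's motion confound is a single global component; real motion
artifacts are spatially structured. The exchangeability-block sampler
exchanges only same-size units, which for very unbalanced family
structures explores a subset of the full valid permutation group (the
standard whole-block convention). The mixed model estimates a single site
variance component; site-by-slope heterogeneity is not modeled. The
contrast-signature K is fixed rather than selected, by design, for
cross-dataset parity.
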