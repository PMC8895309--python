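# Methods

## PLSC model and conventions

For one tract, the predictor block X holds the six tract-averaged
diffusion parameters (left/right x FA/RD/AD, fixed column order left FA,
left RD, left AD, right FA, right RD, right AD) and the behavior block Y
holds either the three CVLT-c recall scores or age. Both blocks are
z-scored per column with the n−1 denominator, so

    R = Yzᵀ Xz / (n − 1)

is exactly the q x p Pearson cross-correlation matrix (behavior rows,
predictor columns). The SVD R = U diag(S) Vᵀ is truncated at
k = min(p, q); U holds behavior saliences, V predictor saliences, and the
latent scores are Lx = Xz V, Ly = Yz U. Standardization makes every
downstream quantity invariant to positive rescaling of any raw column, so
diffusivities may be supplied in mm²/s or 10⁻³ mm²/s as long as each
column is internally consistent; no unit conversion is applied.

The first LV maximizes the bilinear form bᵀRa over unit vectors — the
cross-block *covariance* of unit-weighted projections. (Maximizing the
*correlation* of projections is canonical correlation, a different
estimator; the test suite checks the covariance optimum by grid search.)

SVD signs are arbitrary. Internally each V column is oriented so its
largest-magnitude element is positive (ties break on the first index),
with the paired U column flipped jointly; this makes decompositions
reproducible across runs and platforms. Maturity scores are additionally
re-aligned against age (below), which is the only orientation with
scientific content.

## Inference

**Permutation test.** Rows of Y are permuted uniformly at random (X
fixed) and the full decomposition is recomputed; the observed singular
value of the tested LV is compared with the null at the same index, with
p = (#{null ≥ observed} + 1)/(P + 1). The add-one rule never returns 0
and is standard for Monte-Carlo tests. No Procrustes rotation is applied:
only the dominant LV of each model is tested, and for a fixed index the
singular value is rotation-free. Since z-scoring is permutation-invariant,
permuting the standardized Y rows *is* the full recomputation; the
implementation exploits this for speed without changing the statistic.
Default P = 5,000.

**Bootstrap ratios.** Subjects are resampled with replacement jointly in
X and Y; each resample is re-standardized (the estimator is defined on
correlations, so the whole pipeline is resampled) and decomposed; the
resampled V column is sign-aligned to the original by the sign of their
dot product — without alignment, arbitrary SVD sign flips would inflate
the spread. The bootstrap SE is the SD (ddof = 1) of the aligned
saliences, the ratio is original salience / SE, and |ratio| > 1.96 flags
a conventionally reliable contributor. Resamples with a constant column
(possible at small n) cannot be standardized and are redrawn, with the
count reported. Default 5,000 resamples. With p = 1 every aligned
resample salience is identically 1, the SE is 0 and the ratio is reported
as infinite.

**Behavior weights.** Each Y variable is correlated (Pearson, two-sided
t-based p) with the predictor-side latent score Lx. Lx rather than Ly is
the default because the saliences under study describe the diffusion
block; the choice is switchable and only changes interpretation, not the
fitted model.

## Tract maturity scores

With Y = age (q = 1) the decomposition has a closed form: V₁ is the
vector of metric-age correlations scaled to unit norm and S₁ is its
Euclidean norm (the implementation still goes through the SVD; the closed
form is a test oracle). The subject's score is Lx₁. If corr(score, age)
< 0, score and salience are negated together and the flip is recorded —
RD typically dominates the age pattern and falls with age, so the raw
projection usually tracks immaturity. After alignment corr(score, age) ≥
0 by construction.

Maturity scores are only delivered when the age-LV passes permutation
significance (default α = 0.05); non-significant tracts are reported and
excluded from the maturity-memory stage, though `allow_insignificant=True`
computes flagged scores for exploration.

## Association stage

Maturity x recall correlations form one BH-FDR family across all
tract x score pairs by default (configurable to per-tract families; the
family composition is a genuinely open choice and is recorded in the
report provenance). The discrimination specificity panel is adjusted as
its own family. Bayes factors are attached to pairs surviving FDR.

**Bayes factor for a correlation.** Two default-prior routes are
implemented. The package default (`method="jzs"`) converts r to its t
statistic, t = r√(n−2)/√(1−r²), and evaluates the default
Jeffreys–Zellner–Siow Bayesian t-test (Cauchy prior on the standardized
effect, scale √2/2), which is what the common point-and-click Bayesian
tools report when handed a correlation and what reproduces the worked
examples this package documents (BF10 ≈ 9.0 for r = 0.46, n = 37; 22.7
for 0.51, n = 36; 14.7 for 0.49, n = 36). The exact two-sided
stretched-beta correlation BF (`method="stretched-beta"`, width κ
configurable, κ = 1 = uniform prior on (−1, 1)) is also provided and
checked against a numerical-integration oracle of the marginal likelihood
ratio; it runs noticeably higher (10.6 for r = 0.46, n = 37). Both are
symmetric in sign(r) and monotone in |r| and n.

**Age-group interactions.** OLS of a recall score on maturity, an age
group indicator (0 = younger than 7, 1 = 7 or older; the boundary age of
exactly 7.0 joins the older group) and their product. Maturity is not
re-standardized within group so the two slopes are directly comparable.
Each group must have n ≥ 3.

**Univariate panels.** Recall ~ age fits are OLS; without covariates the
identities F = (n−2)R²/(1−R²) and β_std² = R² hold to numerical
precision and are asserted in tests. The 24-cell metric-age correlation
panel forms a single BH-FDR family.

## Synthetic cohorts

The generator emulates a cross-sectional developmental cohort in
standardized space. Ages are uniform on [4, 12] (mean 8, SD 2.31 — the
distributional shape is not otherwise constrained, and the uniform gives
the intended mean with good leverage across the range); A denotes
population-standardized age. Each tract t has one latent maturation
factor F_t = ρ_t A + √(1−ρ_t²) G_t with G_t ~ N(0,1): a single
age-linked factor per tract is the simplest structure that makes maturity
scores informative beyond age alone. Metrics are
m = ℓ_m A + γ_m G_t + σ_m ε with σ_m² = 1 − ℓ_m² − γ_m², so the
population corr(m, age) equals the target loading ℓ_m exactly
(configurations implying σ² ≤ 0 are rejected). Recall scores are
e_j = √r2_j A + Σ_t κ_{t,j} G_t + σ_j ε, giving population age-R² of
r2_j and a planted maturity-memory coupling κ beyond age. Standardized
draws are mapped to physical units (FA ≈ 0.42 ± 0.035, RD ≈ 6.5·10⁻⁴,
AD ≈ 1.15·10⁻³ mm²/s; recall counts ≈ 8–9.5 ± 2.6–2.9 of 15).

Defaults are the study conditions: n = 37; age loadings per
tract/hemisphere/metric matching the documented correlation panel (right
uncinate RD −0.61, dorsal cingulum RD −0.61/−0.56, near-zero fornix AD);
recall age-R² of 0.251/0.239/0.35; factor-age correlation 0.65 for the
uncinate and dorsal cingulum, 0.35/0.30 for ventral cingulum and fornix;
coupling planted for uncinate x {LDFR 0.45, LDCR 0.42} and dorsal
cingulum x SDFR 0.45, none for discrimination (age-R² 0.15); one subject
loses the uncinate and fornix reconstructions. Scores are continuous by
default — rounding to integer counts distorts calibrated R² at small n —
with a `discrete` flag that rounds and clips to [0, 15].

The planted population maturity-age correlation has the closed form
‖ℓ‖/√(vᵀΣv) with v = ℓ/‖ℓ‖ and Σ = ℓℓᵀ + γγᵀ + diag(σ²)
(`planted_maturity_age_corr`); `calibrate_maturity_corr` rescales one
tract's loadings to hit an exact target, which the recovery studies use
to plant 0.6. Randomness uses one root seed with child streams spawned
per block (ages, sex, factors, metric noise, memory noise,
discrimination, failed-reconstruction choice), so identical configs give
byte-identical cohorts.

What the generator does *not* emulate: measurement floor/ceiling effects
in real CVLT-c counts, non-Gaussian metric noise, spatially varying
along-tract profiles, site/scanner effects, and any nonlinearity in
age — passing recovery tests therefore demonstrate correctness of the
estimators under the stated linear-Gaussian conditions, not robustness to
real-data pathologies.

## Problem sizes in the checked studies

The calibration and recovery suites use 500 null replicates at 500
permutations each for the type-I-error study, 100 replicates at 200
bootstrap resamples for the salience-reliability study, n = 1,000 for
maturity recovery, and 20 pipeline replicates at 500 permutations for the
pattern-reproduction study — sizes at which the Monte-Carlo error is
comfortably inside each documented tolerance.

## Known limitations

* Only the first LV is tested per model; multi-LV testing would need
  Procrustes alignment, which is out of scope.
* The permutation test is calibrated for whole-row exchangeability;
  clustered or longitudinal designs would violate it.
* Listwise deletion per tract (no imputation) mirrors the
  failed-reconstruction handling of the motivating design but discards
  partially observed subjects.
* The discrimination score is treated as an unconstrained real (its scale
  is not documented); only the recall scores are range-validated.
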