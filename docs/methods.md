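# Methods

## Measurement-error model

A replicated reflectance spectrum is modelled as a true sample spectrum plus
a multivariate measurement error. With replicates grouped so that each
group's mean is the best available estimate of the true value, the error
matrix **E** stacks the deviations x_i − x̄_{g(i)}. Columns of **E** sum to
zero within each group by construction, so **E** has rank at most
n − g and the pooled covariance

    Σ = EᵀE / (n − g)

is the unbiased estimate of the within-group error covariance (each group
mean consumes one degree of freedom; dividing by n would bias Σ low by a
factor (n − g)/n). The grouping choice decides which physical variance
sources count as "error": per-session grouping removes between-session and
background-timing shifts; pooling everything includes them. The residual
matrix **Ê** (deviations from the grand mean) is kept distinct from **E**
because its PCA variance profile is the comparison partner for Σ's.

Assumptions: the arithmetic group mean is the reference value (no robust
center — replicate sets here are small and screened for outliers first);
errors are treated as additive on the percent-reflectance scale; channels
are analysed jointly but sessions are assumed exchangeable within a
grouping cell.

## Bilinear decomposition and the variance-comparison table

Σ is decomposed by an *uncentered* eigendecomposition: Σ is a second-moment
object, not a data matrix, so centering it first would destroy the
correspondence between its eigenpairs and the noise components. Two
variance-fraction conventions are reported:

* λᵢ/Σλ (linear) — the explained-variance fractions for the PCA of **Ê**;
* λᵢ²/Σλᵢ² (squared) — used for the Σ column of the comparison table. When
  Σ = ÊᵀÊ/ν the squared fractions of Σ equal the squared-and-renormalised
  linear fractions of **Ê** exactly; this algebraic identity is enforced in
  the test suite by a brute-force oracle on random matrices.

The table's interpretive quantity is the gap at component 1 (Σ-column minus
Ê-column, percentage points). Purely correlated (low-rank) error gives a gap
near zero; independent noise spreads **Ê** variance over many components
while barely moving the squared-convention Σ column, so the gap grows
monotonically with the independent-noise share. Variance percentages are
printed to 3 decimals.

Component count for interpretation is left to the user, guided by the
log₁₀-eigenvalue curve and the cumulative variance (both are computed; no
automatic selection rule is imposed).

## K redundancy index and the imbedded correlation

K is computed from the eigenvalue fractions φⱼ of the p×p correlation
matrix of the error data:

    K = Σⱼ |φⱼ − 1/p| / (2 (p − 1)/p).

Zero eigenvalues remain in the sum (each contributes 1/p to the numerator);
this convention is what makes the rank-forced floor come out right. For an
n×p error matrix with n < p the correlation matrix has rank ≤ n, and the
minimal-K configuration spreads the trace evenly over min(n, p)
eigenvalues, giving

    K_min = (p − n) / (p − 1),   0 when n ≥ p.

The closed form is cross-checked against the brute-force evaluation of the
uniform configuration for every 2 ≤ n < p ≤ 50. Practical reading: with 15
replicates, K cannot fall below 0.94 at 236 channels or 0.81 at 74 channels,
so only the excess of K over the floor is evidence about the noise itself.
K is scale-invariant (computed on the correlation matrix) and is reported at
full precision internally, 2 decimals in tables. Channels excluded as
zero-variance by the correlation step shrink p for both K and its floor.

## T²/Q screening

PCA is fitted to mean-centered spectra (autoscaling available but off by
default — reflectance channels share a physical scale). Loadings signs are
fixed (largest-magnitude element positive) so repeated runs are identical.
Hotelling's T² uses the retained score variances; its 1−α limit is
k(n−1)/(n−k)·F_{1−α}(k, n−k). Q is the squared off-plane residual norm; its
limit uses the Jackson–Mudholkar approximation on the residual eigenvalues
(h₀ clipped at 10⁻³ to keep the formula finite for pathological eigenvalue
spectra; Q limit defined as 0 when the residual space is empty). The default
outlier rule flags a replicate only when it exceeds *both* limits; removal is
opt-in in the pipeline, and when enabled it precedes the error-covariance
stage. T² contributions use the loadings-weighted score decomposition
Σₐ(tₐ/λₐ)P_jₐ·x̃ⱼ, which sums exactly to T²; Q contributions are squared
per-channel residuals.

A caveat the test suite documents explicitly: a purely constant (offset-like)
shift of a replicate lies almost entirely inside the retained subspace of
offset-dominated spectra — it is a T²-only detection. An outlier flagged on
both statistics needs an off-plane shape anomaly as well; and an extreme
outlier present in the training set can rotate the loadings toward itself
(masking), so screening is done at moderate k on raw replicate sets.

## Synthetic-data generator

The generator emulates a two-sample, two-instrument replicate study: for
each sample, 3 sessions under background mode A (background before each
sample) and 3 under mode B (background at session start), 15 replicates per
session — 90 replicates per sample — on either a 236-channel (972–1701 nm)
or a 74-channel (1351–2559 nm) instrument profile. Base spectra are sums of
Gaussian bands on a baseline; they stand in for real mean spectra (which are
not publicly deposited) and make no claim to spectroscopic accuracy.

Generative model per replicate:

    x_ij = μⱼ(1 + m_i) + o_i + s_sess + b_mode + σ_shot √μⱼ η_ij + ε_ij

with all draws Gaussian: gain m ~ N(0, σ_mult²) and offset
o ~ N(0, σ_offset²) per replicate; a session shift s ~ N(0, σ_session²) and,
for mode-B sessions only, an extra background-drift offset
b ~ N(0, δ_background²), each drawn once per session. Shot noise is
implemented as variance ∝ μⱼ — a detector-count analogy carried onto the
percent-reflectance scale, a modelling choice rather than detector physics.
Default magnitudes (σ_offset 1.0, σ_mult 0.04, σ_shot 0.12, σ_iid 0.05,
σ_session 0.8, δ_background 0.6, all in %R except σ_mult) were chosen so
the descriptive statistics of simulated data land in the ranges reported
for real miniaturized-sensor sugar spectra (SNR roughly 3–40, RSD roughly
3–40%) without attempting to reproduce any specific published entry. The
drift magnitude δ_background has no published anchor at all and is a free
parameter.

The closed-form error covariance is

    Σ = σ_offset²·J + σ_mult²·μμᵀ + σ_shot²·diag(μ) + σ_iid²·I

for per-session grouping (J the all-ones matrix). Groupings that pool across
sessions add σ_session²·J, plus δ_background²·J for a pure mode-B pool or
the mode-B fraction of it when modes are mixed. The mixed-mode term is an
approximation: with finitely many sessions the pooled sample covariance
picks up session variance with a factor (n − r)/(n − 1) (r replicates per
session), so convergence checks against the closed form are run on
single-session-per-mode designs with per-session grouping, where the
formula is exact.

What the generator does *not* emulate: wavelength-calibration drift,
scattering physics (no Kubelka–Munk or light-path model), non-Gaussian
detector noise, and any chemically meaningful band structure. Passing tests
therefore demonstrate that the estimators recover the error structure the
generative model encodes — not that real sensor data obey that model.

## Problem sizes and numerical choices

Validation simulations use 15–120 replicates for behavioural checks and
2,000–20,000 replicates (74-channel profile) for convergence of the sample
Σ to the closed form (Frobenius relative error below 15% and 5%
respectively, fixed seeds). Screening calibration uses 500 samples from a
2-component Gaussian model, where both 95% limits are exceeded by 5 ± 2% of
the training set.

Zero-variance channels are excluded from correlation matrices at a relative
tolerance of 10⁻¹² × max diagonal and reported, never silently dropped.
Symmetric matrices are symmetrised ((M + Mᵀ)/2) before eigendecomposition
and eigenvalues clipped at zero; asymmetry beyond 10⁻⁸ (relative) is an
error. Reflectance values outside [0, 100] %R warn but do not fail — real
detectors can exceed the nominal range. Missing values are rejected at
validation; there is no imputation.

## Known limitations

* The RMS reproducibility statistic exists in several conventions; the
  deviation-from-mean form normalised by p inside the root is used here. It
  is 0 for perfect repeatability and satisfies
  mean(RMS²)·n/(n−1) = mean over channels of s², which the suite asserts.
* The Q-limit approximation (Jackson–Mudholkar) is one of several in use;
  results near the limit can differ between software by a few percent.
* No shrinkage or structured covariance estimation: at p ≫ n the sample Σ
  is rank-deficient by construction, and all downstream interpretation
  (decomposition fractions, K) is rank-aware rather than regularised.
* Cross-sample loading-shape comparison is provided as plot overlays; no
  numerical similarity score is promoted to a headline output.
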