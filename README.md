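# specerr

Multivariate measurement-error analysis for replicated NIR reflectance
spectra from miniaturized sensors.

Low-cost handheld NIR spectrometers are increasingly used for food and
material screening, but the structure of their raw-data measurement error is
rarely examined. Replicate spectra of the same sample carry that information:
the deviation of each replicate from the replicate mean is an estimate of the
measurement error vector, and the collection of those deviations
characterises the noise — its magnitude per wavelength, its correlation
across wavelengths, and the physical noise types (offset, multiplicative,
shot, independent) that produce the observed patterns. `specerr` implements
that analysis chain for anyone running replicate studies on such
instruments: analytical chemists comparing sensors, and chemometricians who
need an error covariance for model diagnostics or preprocessing design.

## The method

Given an *n* × *p* matrix **X** of replicate spectra (percent reflectance,
*p* wavelength channels) and a grouping of replicates (all, per analytical
session, per background-timing mode), the package computes:

* **Error matrix** **E**: each replicate minus its group mean, and the
  **residual matrix Ê**: each spectrum minus the grand mean.
* **Error covariance** **Σ** = **E**ᵀ**E** / (n − g) with g groups (pooled,
  unbiased), and the **error correlation matrix** **R**. The diagonal of
  **Σ** is the per-channel error variance — flat for homoscedastic noise,
  tracking μ for shot noise and μ² for multiplicative noise; an all-positive,
  nearly flat **R** signals dominant offset noise.
* **Bilinear decomposition**: uncentered PCA of **Σ**, compared with the PCA
  of **Ê**. Per-component variance fractions use λᵢ/Σλ for **Ê** and
  λᵢ²/Σλᵢ² for **Σ** (a covariance is a second-moment object; the squared
  convention makes the two columns comparable). A small gap between the two
  first-component percentages means the error is dominated by correlated,
  low-rank structure — little independent noise.
* **K redundancy index** of the error matrix,
  K = Σⱼ |φⱼ − 1/p| / (2(p−1)/p) over the eigenvalue fractions φⱼ of the
  correlation matrix (0 = uncorrelated, 1 = rank one), together with the
  **imbedded correlation** (p − n)/(p − 1): the floor forced on K whenever
  n < p, e.g. 0.94 for 15 replicates × 236 channels and 0.81 for 15 × 74.
* **T²/Q outlier screening**: PCA on mean-centered spectra with Hotelling T²
  and Q-residual statistics, F-distribution and Jackson–Mudholkar 95%
  limits, per-wavelength contribution vectors, and a "flag only if both
  limits are exceeded" removal rule.
* **Reproducibility descriptives**: per-wavelength SD and RSD, per-replicate
  RMS, per-wavelength SNR, summarised in a six-row table per sample.

A synthetic-data module generates replicated datasets from a generative
noise model (offset + multiplicative + shot + independent components, with
session and background-timing effects) whose theoretical **Σ** is available
in closed form, emulating a two-sample, two-instrument, 6-session × 15-replicate
study design (90 replicates per sample per instrument; 236-channel and
74-channel instrument profiles).

## Worked example

```python
import specerr as se

ds = se.simulate_dataset(seed=42)                     # 2 samples × 90 replicates, 236 channels
lump = ds.subset(sample_id="sugar_lump")
fit = se.MeasurementErrorModel(lump, grouping="all", n_components=3).fit()
print(fit.summary())
```

```
Multivariate Measurement Error Results
======================================================
replicates            90
channels              236
grouping              all (1 group(s), dof=89)
mean error variance   4.02335 (%R)^2
K correlation index   0.9013
imbedded correlation  0.6213
uncorrelated gap      10.271 points

Variance accounted for (%):
                           % Variance in Original Residuals (E-hat)  % Variance in the Error Covariance Matrix (Sigma)
# of Principal Components
1                                                            89.702                                             99.973
2                                                             0.855                                              0.009
3                                                             0.276                                              0.001
```

Reading the output: the mean error variance is the average Σ diagonal; one
component carries ~90% of the residual variance and >99.9% of Σ, so the
error is dominated by a single correlated (offset-like) structure; the
10.3-point gap between the two first-component percentages is the footprint
of the independent (shot + iid) noise in the generative model; K = 0.90
against a rank floor of 0.62 (90 replicates × 236 channels) confirms heavy
error correlation. Per-session error matrices (15 × 236) have floor 0.94:

```python
for sess in ("1A", "2A", "3A"):
    E = se.error_matrix(lump.subset(session_id=sess), "all")
    print(sess, round(se.k_index(E).K, 2), round(se.imbedded_correlation(E.n, E.p), 2))
# 1A 0.94 0.94
# 2A 0.94 0.94
# 3A 0.94 0.94
```

The full pipeline — descriptives, outlier screen, Σ/R heatmaps, diagonal
overlays by session and background mode, variance-comparison and K tables,
and a reproducibility manifest — runs from the shell:

```sh
specerr report --simulate design.yaml --seed 42 --grouping all --out report/
```

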