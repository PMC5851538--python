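# Methods

## Data model

Measurements enter as three CSV layouts (UTF-8, comma-separated, dot
decimals, one header row): a *diameters* table (one row per specimen, six
canal-axis diameters in mm, log₁₀ body mass in grams, and a flag for masses
that are themselves regression estimates), and *lumen* / *angles* tables of
replicate panels (specimen, variable, rep1…rep5). Readers validate every
cell and report the row/column of any malformed numeric; major/minor axes
entered in the wrong order are reordered on read. The packaged tables hold
the published measurements for three *Endothiodon* cf. *bathystoma*
specimens, one *Niassodon*, and 32 extant mammals.

Calibration sets keep only records with a weighed (not regression-derived)
body mass and all three canals. Uniqueness is enforced on the
(taxon, specimen) pair because published voucher numbers are reused across
taxa in the source table.

## Geometric scores

**Eccentricity.** Each canal outline is an ellipse with major/minor axis
diameters *a* ≥ *b* > 0 and `e = sqrt(1 − (b/a)²)`. The specimen-level
score averages the two vertical canals (anterior, posterior), the
convention of the source dataset; per-canal values including the horizontal
canal are also reported. `e` is scale-invariant and strictly increasing in
the axis ratio.

**Radius of curvature.** `R = (a + b)/4` mm — half the mean semi-diameter,
the convention of the extant-mammal inner-ear literature this calibration
follows. The body-mass predictor is the arithmetic mean of the three
per-canal radii.

**Orthogonality deviation.** `Σ (θ̄ − 90°)²` over the *per-specimen mean*
inter-canal angles (nine values for three specimens × three angle pairs).
Feeding raw replicates or per-angle grand means instead changes the score;
per-specimen means are the definition used here, and for the packaged
tables give 7.8 deg².

## Replicated-measurement statistics

Lumen panels are summarised linearly: mean, sample SD (Bessel), SE = sd/√n,
and a two-sided t interval with n−1 df (α = 0.05 by default). The published
table's "σ" row is reproduced by the sample SD, not the variance.

Angle panels use circular statistics: circular mean = direction of the mean
unit vector (atan2 of mean sine/cosine, mapped to [0, 360)), circular SD =
`sqrt(−2 ln R̄)` with R̄ the mean resultant length, and a linearised
interval `mean ± t·(circ_sd/√n)`. For dispersions under ~5° the circular
and arithmetic means agree within 0.01°, which is the regime of all real
panels here; the circular forms exist so that angle data near 0°/360°
wrap correctly. A zero resultant raises an error rather than returning an
arbitrary direction. Cross-specimen aggregates average per-specimen means
recomputed from raw replicates (each specimen weighted once); the pooled
mean treats all 45 raw replicates as one sample.

## Measurement error

The classical TEM is defined for two sessions; with k = 5 sessions we
compute `sqrt(Σ_s (x_si − x_sj)² / 2n)` for each of the 10 unordered
session pairs, pooling the n = 3 specimens in the denominator, and average.
Relative TEM divides by the grand mean of all n·k values (percent). This
pooled-pairwise reading exactly reproduces the published 0.88% and 0.82%
for the anterior–horizontal and posterior–horizontal angles (the third
panel computes to 1.10% against a published 1.08%, a discrepancy we report
but do not chase). TEM assumes homologous remeasurement, which holds for
angles but not for lumen diameters taken at different loci; lumen TEM
therefore warns unless forced.

Note the pairwise-averaged TEM is a biased-low estimator of the noise SD at
these sample sizes (expectation ≈ 0.92 σ for n = 3, k = 5, by Jensen's
inequality on the square root); the test suite checks the estimator against
its simulated sampling distribution rather than against σ itself.

Session effects are tested with a one-way within-subject ANOVA (subjects =
specimens, within factor = session; F with (k−1, (n−1)(k−1)) df, no
sphericity correction — with n = 3 and k = 5 the df budget does not support
estimating one). The fit is delegated to statsmodels' `AnovaRM`; tests
verify it against a hand sums-of-squares decomposition and against the
exact noncentral-F power for an injected session bias.

## Allometry

Ordinary least squares of log₁₀ body mass (grams) on log₁₀ radius (mm).
Body mass is carried in log₁₀ grams throughout (the calibration's small
taxa are only plausible on that scale) and converted to kg at the reporting
boundary. For a single predictor, r is the signed Pearson correlation and
the p-value the two-sided slope t-test; for multiple predictors, r = √R²
and the overall F p-value. Candidate predictor sets (mean radius, each
single canal, pairs, all three) are ranked by APC = (RSS/n)(n+p)/(n−p),
p counting all coefficients including the intercept; ties prefer fewer
predictors, then declaration order. APC is used only for ranking, where the
published variants of the criterion are rank-equivalent at fixed n.

Predictions carry a t prediction interval
`point ± t(1−α/2, n−p−1) · s · sqrt(1 + x₀ᵀ(XᵀX)⁻¹x₀)` with
s = sqrt(RSS/(n−p−1)). Predictors outside the calibration range set an
`extrapolated` flag (logged, not fatal) — relevant because the fossil
specimens sit near the top of the calibrated radius range.

**Known calibration discrepancy.** Fitting the packaged 32-taxon table with
R = (a+b)/4 gives slope 5.78, r = 0.843 and fossil predictions of
5.28/5.20/5.40 log₁₀ g (≈ 158–252 kg), uniformly ≈ 0.13 log₁₀ units above
the originally published predictions (r = 0.787, ≈ 116–182 kg). The
original fit drew on a larger calibration set that is not recoverable from
the packaged table alone. Between-specimen differences agree to < 0.01
log₁₀ units, i.e. the slope is consistent and the offset reflects the
calibration data, not the method; tests assert the closed-form fit on the
packaged data and the between-specimen spread, and treat the published
absolute values as documented context. Consistently, an adjusted R² formed
from the published r (0.787, n = 32, p = 1) gives 0.6067 against the
published 0.606 — agreement at the precision of the printed r.

## Synthetic data

`gen_labyrinth_dataset` draws each replicate as truth + independent
Gaussian noise. Defaults mirror the real panels: three specimens, five
replicates, true angles (91.2°, 90.3°, 89.3°) with 0.8° session noise,
true lumen diameters (0.72, 0.41, 0.69) mm with 0.08 mm noise, and fixed
*Endothiodon*-like canal ellipses. `gen_allometric_dataset` draws log₁₀
radii uniform on [−0.6, 0.31] (the extant calibration's span) and log₁₀
mass as 4.18 + 5.78·x + N(0, 1.0), which yields R² mostly in the 0.5–0.7
band of the real fit; per-canal radii are jittered (log-normal σ = 0.05)
but rescaled so the three-canal mean reproduces each drawn radius exactly,
and diameters are split major/minor at a configurable eccentricity (0.6)
so the eccentricity scorer is exercised too. Both generators are
deterministic given their integer seed.

What the simulations do not emulate: phylogenetic autocorrelation among
calibration taxa, heteroscedastic or asymmetric measurement error,
canal-shape covariation, and missing data. Passing recovery tests on these
generators therefore demonstrates estimator correctness under the assumed
error model, not robustness to those real-data features.

## Numerical choices and problem sizes

Rounding happens only at report time ("as published" mode renders 2
decimals, 1 for the orthogonality sum, for direct string comparison with
the source tables; full precision is the default). Degenerate inputs fail
loudly: zero resultant (circular mean), zero error variance (ANOVA),
collinear predictors, n ≤ p fits. Monte-Carlo checks in the test suite use
2000 panels (CI coverage), 1000 calibrations (slope-CI coverage, expected
93–97%), 500 replicate datasets (TEM sampling distribution, ANOVA power)
and 200 selection runs (APC vs its closed-form selection probability) —
sizes at which the binomial error of each empirical rate is several times
smaller than the asserted tolerance.
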