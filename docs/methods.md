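# Methods

This note records the models implemented in `isoniche`, the defaults and
why, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want to know about.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and time conventions

Segment positions are measured in mm from the facial (proximal) end of the
whisker, which holds the most recently grown keratin; the distal tip is the
earliest growth.  Ages therefore decrease strictly with position.  Years are
365.25 days throughout.  Ingest drops a configurable proximal root length
(default 5 mm, roughly the follicle-embedded root) and rebases positions to
zero.

## Whisker chronology

**Model.** Migratory seals imprint approximately one δ13C oscillation per
year of whisker growth.  If the dominant spatial period of the δ13C series
is λ mm, the growth rate is r = λ/365.25 mm/day and the age of the segment
at position x follows by back-tracking from an anchor.

**Wavelet machinery.** The continuous wavelet transform uses a Morlet mother
wavelet with central frequency ω₀ = 6 (the conventional choice balancing
period and position resolution; configurable).  The period grid is
log-spaced, default 60 periods over 10–100 mm.  Implementation details that
matter:

- The series is linearly detrended before transforming; the ontogenetic
  δ13C decline otherwise leaks power into long periods.
- Padding uses Burg autoregressive extrapolation (order 8) of the detrended
  series rather than reflection or zeros: AR forecasting continues an
  oscillation with the correct phase, which keeps coefficients inside the
  cone of influence honest and is what lets band-limited reconstruction
  track the signal to the whisker ends.
- Significance per (period, position) cell is exceedance of the per-period
  95th percentile of power under a white-noise null of equal length and
  variance, estimated by Monte-Carlo (default 100 simulations).  By
  construction ~5% of cells light up on pure noise.
- The dominant period maximises position-averaged power among periods with
  at least 20% significant cells; if no period qualifies the whisker is
  declared to have no clear periodicity and receives the mean wavelet rate
  of its sex cohort (the cohort-fallback rule).
- Denoised series come from the inverse transform restricted to significant
  period rows (Torrence–Compo reconstruction, C_δ = 0.776 for ω₀ = 6).
  Band truncation deflates amplitude, so the reconstructed residual is
  rescaled to the detrended series' standard deviation, as wavelet
  denoising tools conventionally do.  The growth rate itself is taken from
  the dominant period, not from peak counting in the reconstruction — the
  period is deterministic and matches the annual-oscillation assumption; a
  peak-spacing estimator is provided as a cross-check utility.

**Age anchors.** Males are anchored at the facial end with the modal tooth
age: age(x) = age − x/(r·365.25); a negative age at any segment is an error
(rate and tooth age inconsistent), and the pipeline falls back to span-based
minimum ages with a warning when that happens.  Females lack tooth ages.  A
female whisker whose δ15N shows a suckling peak at the tip (a local maximum
in the distal 20% exceeding the series median by 1.5‰, both configurable)
is anchored at the tip with a weaning age of 0.3 yr — the nursing period is
roughly four months and the anchor is configurable because no observational
constraint pins it.  Females without a tip peak have worn or broken tips, so
the tip is treated as an age-0 proxy and all ages are minima
(`is_minimum_age`).

## Isotopic niche ellipses

The maximum-likelihood standard ellipse of a bivariate point cloud is the
Mahalanobis-radius-1 contour of the fitted normal; its area is
SEA = π√(det Σ̂) ‰² with Σ̂ the unbiased sample covariance, and it contains
1 − e^(−1/2) ≈ 39.35% of the distribution.  SEAc multiplies by
(n−1)/(n−2).  The 95% prediction ellipse (χ²₂ 0.95 quantile radius) exists
for plotting only.

**SEA_B.** The posterior over (μ, Σ) is conjugate normal–inverse-Wishart
with a vague prior: prior mean at the sample mean, prior precision
κ₀ = 10⁻³, scale matrix identity, ν₀ = 3 degrees of freedom.  SEA is
computed per posterior covariance draw (default 100,000 draws); the
reported mode is the argmax of a Gaussian kernel density (Silverman
bandwidth) over the draws on a 512-point grid, and the interval is the
2.5–97.5 percentile range.

**Overlap.** Ellipses are polygonised with 1024 vertices and clipped with
shapely; at that vertex count the polygon area error is ~10⁻⁴ relative.
The overlap proportion uses the union denominator,
overlap/(A + B − overlap) — symmetric and bounded in [0, 1]; the
"fraction of the smaller ellipse" convention is selectable and the choice
is recorded in `proportion_def`, since published overlap percentages rarely
state their denominator.  The Bayesian overlap repeats the geometry for a
subsample of posterior (μ, Σ) pairs — default 1,000, because every pair
costs a polygon intersection — and reports the kernel-density mode and 95%
interval of the proportion.

**Ontogenetic windows.** Male segments are pooled by estimated age into
annual windows starting at 0.5–1 yr (younger growth is suckling-dominated);
windows with fewer than 3 points are skipped with a warning.  Each window's
ellipse is compared against the full-record ellipses of the two female
groups.

## Polar-Front classification

threshold = mean prey δ13C at the front + TDF.  The default TDF for whisker
keratin is 2.06‰ (configurable; its published uncertainty of ±1.79‰ is
propagated only through an explicit sensitivity sweep, since the headline
classification uses the point value).  A segment is north iff δ13C strictly
exceeds the threshold — ties classify south, following the ordinary reading
of "exceeds" — and the proportion of time north is the proportion of
segments north, which is exact under uniform growth.  Females are assigned
to group 1 (≤ threshold) or group 2 (> threshold) by whole-whisker mean
δ13C; prey values are pooled across species by default (per-species
weighting is possible by passing species means).

## Mixed models and specialisation

Long-format segment data (response, group, age, seal) are fitted by
REML/ML `MixedLM` with per-seal random intercepts and age slopes.  Because
the slope variance often sits on the parameter-space boundary, each fit
runs a small multi-start (lbfgs, powell, nm as last resort) and also fits
the random-intercept submodel, keeping whichever likelihood is higher —
the boundary MLE.  Fixed-effect intervals use t quantiles with
(individuals − 1) degrees of freedom; Wald-normal intervals undercover
noticeably at a few dozen seals.

**AR(2) residuals.** Serial correlation along the whisker is handled by
iterated feasible GLS: fit, estimate AR(2) coefficients from within-whisker
(BLUP-subtracted) residuals by pooled Yule-Walker, whiten the response and
both design matrices within each whisker (conditional least-squares
convention: the first two rows pass unfiltered), refit.  The reported
within-individual variance is converted from innovation scale back to the
marginal stationary variance.  Two guards: an estimated filter with any
root of modulus > 0.95 triggers fallback to independent residuals (near-
unit-root whitening would difference away the between-individual signal),
as does any failure in the AR stage; the fallback is flagged on the fit.
This is an approximation to a joint corARMA likelihood, which the underlying
library does not provide.

**Backward selection** drops, at each step, the least-supported droppable
term when its ML likelihood-ratio p ≥ 0.05, testing interactions before
main effects; with an AR structure the whitening filter is estimated once
under the global model and held fixed across nested fits so likelihoods
remain comparable.  The final model is refit by REML.  At very small
per-group replication (≲10 individuals per group) the χ² reference for the
interaction test is anticonservative — a known property of ML LR tests in
mixed models, visible in the test suite's type-I checks, which therefore
run at the design's actual replication.

**Conditional R²** = (var(Xβ̂) + σ²_between)/(var(Xβ̂) + σ²_between +
σ²_within).  With a random slope, σ²_between is the variance of individual-
level predictions evaluated at the mean age of the data (wᵀĜw with
w = (1, mean age)); how slope variance should enter a scalar "between"
component is genuinely open, and the mean-age evaluation is the least
surprising convention.  **WIC/TNW** uses the same components:
index = σ²_within/(σ²_within + σ²_between), 0 for complete individual
specialists, 1 for fully generalised individuals.

**Proportions north** are compared between groups by a logit-link beta
regression after boundary shrinkage (p·(n−1) + 0.5)/n — male proportions
near zero make shrinkage unavoidable — with an LR test of the group effect.
Only one proportion exists per seal, so an individual random effect would
be unidentifiable; the model is deliberately fixed-effects only.

**Morphometrics**: PCA of standardised mass/length/span/girth, Welch's
t-tests between the female groups on PC1 and PC2 scores.

## The synthetic colony

Defaults state the world the analysis targets: 20 males and 20 females,
5 mm segments, female group 2 drawn at probability 6/20; growth rates
normal-truncated at sex means 0.096 ± 0.026 (M) and 0.063 ± 0.013 (F)
mm/day; whisker lengths 257.5 ± 69.5 (M) and 162.9 ± 45.3 (F) mm; male ages
8.70 ± 0.73 yr from tooth ridges read by 3 readers with 0.7 yr error;
δ13C(x) = baseline + slope·age(x) + A·sin(2πx/(r·365.25) + φ) + noise with
slope −0.30 ‰/yr, δ15N slope +0.15 ‰/yr, amplitude 1‰ (read qualitatively
from published whisker traces; no numeric amplitude is reported anywhere),
phase uniform per seal.  Group means (δ13C, δ15N): males (−21.68, 8.98),
female group 1 (−19.71, 8.96), female group 2 (−17.89, 10.89).  Prey δ13C
is normal around −20.98‰.

Two derived calibrations deserve note:

- **Between-individual scatter** (0.45‰ δ13C, 0.60‰ δ15N) follows from the
  specialisation indices the analysis is designed to estimate: an index of
  ~0.85–0.9 with total δ13C SD ~1.4‰ implies a between-individual SD near
  0.45‰.  It is a structural constant of the stated world, not a tuning
  knob.
- **Segment noise** is calibrated per individual so the pooled group SD
  matches the stated group SDs (1.20/1.44/1.13‰ for δ13C): noise² =
  target² − between² − A²/2 − slope²·var(age), floored at (0.3‰)² —
  measurement-scale noise.  Passing an explicit `noise_sd` overrides the
  calibration (the test suite's chronology and classification checks fix
  noise at 0.3 and 0.5‰ respectively).

Baselines are anchored per individual so that the expected whisker mean
equals the group mean plus the individual effect regardless of the seal's
age span.  Six of twenty females (in expectation) carry a +3‰ δ15N tip
peak over ages < 0.35 yr (no published magnitude exists; 3‰ is comfortably
above segment noise and below trophic-shift implausibility).  Female true
age is whisker duration plus an unobservable wear offset (uniform 0.05–2
yr; ~0 for tip-peak females, whose tips survived).  Morphometrics are drawn
group-wise with a +10% offset for female group 2 — only score-level
differences are reported anywhere, so the raw offset is a free choice
documented here.

**What the generator does not emulate:** spatial movement (latitude exists
only through δ13C), isoscape/baseline variability, within-year foraging
structure beyond a single sinusoid, measurement drift, segment-mass
variation, or whisker growth-rate changes with age.  A green test therefore
establishes that the pipeline recovers the stated statistical structure —
periods, thresholds, variance components, group labels — not that it would
reproduce any particular field dataset.

## Determinism

Every stochastic step takes an explicit seed; population generation spawns
per-seal child seeds from a `SeedSequence`, so identical configs produce
byte-identical CSVs and summary JSON.  The summary embeds a SHA-1 digest of
the config for provenance.

## Known limitations

- The AR(2) stage is feasible-GLS whitening, not a joint likelihood; its
  coefficients are method-of-moments quality and standard errors do not
  account for estimating them.
- Wald/χ² inference in the mixed models has no Satterthwaite/Kenward-Roger
  correction; interval coverage is handled with the coarse t-(individuals−1)
  rule.
- Bayesian overlap subsamples posterior pairs (default 1,000 of the
  100,000 SEA draws) for tractability.
- The ellipse machinery is strictly bivariate; no community metrics or
  higher-dimensional hypervolumes.
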