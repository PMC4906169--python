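# Methods

This note documents the models, estimators and numerical choices behind
`golgiring`, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable option existed.

## Imaging model

All image generators share one optical model: an isotropic Gaussian PSF of
FWHM 266 nm (the resolution limit of the emulated spinning-disc system;
σ = FWHM/2.3548 ≈ 113 nm) sampled on a 133 nm pixel grid (Nyquist for that
PSF). Noise is Poisson shot noise on (signal + background) scaled by
`photon_scale` (counts per intensity unit) plus additive Gaussian read
noise — the standard EMCCD approximation. Defaults (background 10 a.u.,
amplitude 100 a.u., `photon_scale` 1, read noise 2 a.u.) give peak SNR ≈ 10,
a moderate-noise confocal regime. The acquisition system being emulated did
not publish pixel size, exposure or noise levels, so these are emulations of
plausible conditions, not reconstructions. Setting `photon_scale = 0` and
`read_noise_sd = 0` disables noise exactly; every generator draws structure
and noise from two independent child streams of its seed, so toggling noise
never alters the ground truth.

## Ring/solid morphometry

A Golgi body whose cargo occupies the cisternal rim produces two intensity
peaks on a transect through its centre; cargo confined below the resolution
limit produces one. Profiles are sampled at half-pixel steps (66.5 nm) over
a 2.66 μm window. Peak finding runs on a lightly smoothed copy (Gaussian,
σ = 1 sample ≈ 0.6× the PSF σ — narrow enough to leave genuine peaks
intact) and requires prominence ≥ 0.2 × (max − baseline) and ≥ 200 nm
separation, with the baseline estimated as the mean of the outer 10% of
samples. One peak → solid, two → ring; zero or ≥ 3 peaks → rejected and
excluded from the class fractions, which are therefore reported over scored
objects only (the original percentages were likewise fractions of scored
Golgi).

The two-Gaussian fit minimizes squared residuals by bounded
trust-region-reflective least squares (`scipy.optimize.least_squares`,
ftol/xtol/gtol 1e-12, ≤ 2000 function evaluations). Free mode has 7
parameters; fixed mode is reparameterized by the midpoint c with
μ₁,₂ = c ∓ R/2, which enforces μ2 − μ1 = R *exactly* rather than via a
penalty. Initialization: μ from the two most prominent detected peaks (or
the centroid ± R/2 when fewer), amplitudes from peak heights minus
baseline, σ from the PSF, baseline from the outer-sample mean; bounds keep
μ inside the window, σ ∈ [step/2, window/2] and A ≥ 0. Amplitudes are not
constrained equal — real rings are asymmetric. A baseline term is included
although the textual model description omits it, because real profiles sit
on cytoplasmic background. Non-convergence is returned as a flag, never
silently dropped, and diameter computation refuses non-converged fits.

"Width of each Gaussian" is interpreted as FWHM by default (the
conventional peak width), with `two_sigma` selectable; on the generator's
own rings (two PSF-width Gaussians at ±D/2) the expected recovered diameter
is the generative D plus 2 × 266 nm of PSF broadening, and tests assert
recovery of that expectation within 5% at SNR ≈ 10.

Ring diameters are drawn from N(800 nm, 150 nm) truncated below at
2 × PSF FWHM: sub-resolution "rings" are physically indistinguishable from
solids, and the population invariant requires rings resolvable by
construction. The rendered 2D ring is a circle of sub-pixel point sources
convolved with the PSF at constant total flux (flux conservation across
diameters to < 1%); note rim convolution pulls the apparent peaks inward by
~σ²/D, whereas the 1D profile generator places Gaussians at ±D/2 exactly.

## Group comparison

`compare_groups` reproduces the published testing scheme: a two-sided
F-test on the variance ratio (p = 2·min(CDF, SF) at (n₁−1, n₂−1) df)
selects pooled Student's t (p ≥ 0.05) or Welch's t (p < 0.05); the
two-tailed t p-value is returned. Tests validate both branches against the
closed-form formulas to 1e-10.

## FRAP delivery rate

The generator inserts events as a homogeneous Poisson process of intensity
rate × area, uniformly in space and time; each focus appears in the next
acquired frame, then translates at `track_speed` for `track_lifetime`
(default 40 s), emulating delivered CSCs drifting out of the shallow
focal volume; decoy flashes (default 1 μm⁻²h⁻¹) last exactly one frame so
the persistence criterion is what rejects them. Truth lists true events
only.

Scoring follows the two published criteria, operationalized as: (i) no
detection within r_excl = 500 nm during the k_before = 2 preceding frames,
and (ii) linkage into a track persisting ≥ k_after = 4 frames with steps
≤ 400 nm; only appearances inside the central subregion (20% margin per
side) count. The original description gives no radius, persistence length
or subregion geometry, so these defaults are declared assumptions, all
configurable. A kymograph-linearity check is not implemented; persistence +
bounded steps proved sufficient on the simulated conditions.

Two denominator corrections make the rate estimator unbiased rather than
systematically low:

1. **Scoreable window** — appearances can only be scored in frames
   [k_before, T−1−k_after], so the duration is (T − k_before − k_after)
   intervals, not the full movie.
2. **Occlusion (dead-exposure) correction** — criterion (i) can never fire
   within r_excl of an existing focus, so that area is dead exposure. Each
   scoreable frame contributes its unblocked fraction of the subregion,
   rasterized at pixel resolution from the actual detections, mirroring the
   scoring rule exactly. Without this, ~4% of events are lost at the
   wild-type rate and the rate-vs-truth slope falls to ~0.92 across rates
   1–8 μm⁻²h⁻¹; with it, recovery is centred and the slope is ~1.

`delivery_rate(n, area, duration)` keeps the plain arithmetic contract
(rate = n/(area × duration)); `score_movie` feeds it the corrected
effective duration.

Foci detection thresholds the scale-normalized LoG response at
median + 6 × 1.4826 × MAD of the first (post-bleach, essentially empty)
frame — robust statistics reflect the noise floor, making the threshold
content-independent; at 6σ false positives are negligible on a 150² field.

## Tracking and speeds

Detection: negative LoG at the PSF scale, 3×3 local maxima above threshold,
sub-pixel refinement by per-axis quadratic interpolation (< 0.25 px error on
noiseless spots). Linking: greedy nearest-neighbour assignment in ascending
distance order with deterministic tie-breaks (distance, then track id),
gating at 400 nm and gap closing ≤ 1 frame — global assignment is
unnecessary at the densities simulated (tracks on a 5 μm grid; recovery
≥ 95% without identity swaps is a tested invariant).

Speed: the default **slope** method projects a track onto its principal
axis (leading singular vector of the centred coordinates) and fits
projected position against time. Isotropic localization noise averages out
of the slope, so the estimate is unbiased for directed motion; the
**stepwise** alternative (mean step / interval) adds the noise in
quadrature per step — at 50 nm noise and 5 s frames it overestimates a
250 nm/min track about fourfold, which the tests demonstrate. Both are
provided because the original Imaris speed definition is unspecified.

Track speeds are drawn from a normal truncated at zero whose underlying
(μ, σ) are solved (scipy `fsolve` on `truncnorm` moments) so the realized
population mean and SD equal the published values exactly; naive truncation
of N(255, 128) would inflate the mean by ~3% and bias recovery tests.

## Manders and immuno-gold

M1 = ΣA over pixels with B > T_B divided by ΣA over pixels with A > T_A
(M2 symmetric). Thresholds default to per-channel Otsu because manually
chosen thresholds are irreproducible; manual override is available.
Undefined coefficients (no above-threshold signal) are reported as missing
with a warning, never as 0. On a noiseless zero-background pair with equal
objects, M1 = M2 = overlap fraction up to ~1% pixelation scatter; with
nonzero background the numerator additionally collects background intensity
under the other channel's objects — an inherent property of the
coefficient, worth remembering when comparing absolute values.

The gold statistic projects each particle onto the Golgi long axis (given
endpoints, or the principal axis of an outline point set — the "centre of
the Golgi" is taken as the axis midpoint, since TEM sections show elongated
stacks) and reports |s − L/2|/L ∈ [0, 0.5]. Particles projecting outside
[−0.05, 1.05]·L raise an error, as that indicates a wrong outline.
Summaries use type-7 (linear-interpolation) percentiles, 1.5×IQR whiskers
and a Gaussian KDE, matching the violin-plot conventions; zero-variance
samples are flagged degenerate instead of producing a spurious density.
Central/peripheral gold simulations use symmetric Beta densities about the
midpoint: Beta(1+c, 1+c) for central, Beta(1/(1+c), 1/(1+c)) for
peripheral, with c = 0 recovering uniform.

## Problem sizes and limitations

Recovery experiments run at the published sample sizes (820/870 profiles,
121-frame 400 μm² movies averaged over 10 seeds, 500 tracks); property
suites use smaller fields (10–20 μm) and 50–120 s movies, which keeps the
whole test suite under a minute on one CPU while leaving event counts large
enough for the stated statistical tolerances.

The generators emulate PSF blur, shot/read noise, Poisson event timing,
linear motility and controlled overlap — they do not emulate photobleaching
kinetics, z-drift, non-Gaussian PSF tails (Airy rings), heterogeneous
backgrounds, track curvature/pausing, or segmentation of touching Golgi.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated imaging model, not robustness to every
artefact of real data. 3D morphometry, deconvolution, Costes/Pearson
co-localization and bleach-recovery curve fitting are out of scope.
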