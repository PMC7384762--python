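# Methods

This note documents the models, estimators, numerical choices and known
limitations of `qusradiomics`, in the order data flows through the
package.

## Acquisition model and conventions

RF frames are 2-D arrays (axial sample × scan line). Axial index 0 is
the transducer face and depth is `index · c/(2 fs)` (two-way travel).
The default acquisition emulates a 6 MHz-class linear array: 40 MHz
sampling, 6.3 MHz center frequency, 3.0–8.5 MHz nominal (−6 dB) band,
speed of sound 1540 m/s, 60 mm aperture. ROIs live on the RF grid;
polygon ROIs are given in millimetres and rasterized by the
pixel-center-inside rule (strict interior), so boundary-touching pixel
centers are excluded deterministically.

## Sliding-window spectra

Windows are 2 × 2 mm (about 10 wavelengths at 6 MHz) with 92 % overlap
in both axes; the physical step (0.16 mm) is rounded to whole
samples/lines with a floor of one. Only windows fully inside the ROI
are used — partial windows would mix tumour and background spectra.
Each window's spectrum is the across-line average of per-line
Hann-tapered periodograms (FFT zero-padded to the next power of two
≥ 2× the gate). The Hann taper controls spectral leakage; its exact
shape cancels in phantom normalization because the reference spectra
use the same gating.

The reference spectrum at each depth is the phantom's power spectrum
averaged over all scan lines and frames at the same axial gate, so the
sample/reference ratio is depth-matched exactly when both share a
sampling rate (enforced). One consequence worth knowing: the per-window
*log* of an L-line-averaged periodogram lies slightly below the log of
the many-line phantom average (about −0.25 dB for L ≈ 17, the
digamma-vs-log gap), so a phantom imaged against itself gives per-window
MBF/SI a few tenths of a dB below zero rather than exactly zero. The
bias is depth- and frequency-flat and therefore cancels in SS, in ACE
and in all week-minus-baseline features.

## Analysis band

By default the band is the contiguous −6 dB region of the reference
(system) spectrum at the ROI's mean depth, with linearly interpolated
edges; it is invariant to overall gain. A fixed band can be configured
(`band_mode: fixed`). At least 3 bins are required.

## ACE and attenuation compensation

The attenuation model is linear in frequency (dB·cm⁻¹·MHz⁻¹). For each
frequency bin, the normalized spectrum is regressed against window
depth; the slope m(f) (dB/cm) gives the local sample-minus-reference
attenuation difference −m(f)/2 (two-way). A least-squares line through
the origin against f (MHz) gives the difference slope β, and
ACE = β + α_ref. The per-ROI value is the median over per-lateral-column
estimates (each column needs ≥ 3 depths spanning ≥ 0.5 cm; pooled
windows are the fallback). Compensation is applied per window as
`+2 (ACE − α_ref) f z`, i.e. only the sample–reference *difference* is
compensated — internally consistent with normalization, which already
removed the reference's attenuation. All three spectral-fit parameters
(MBF/SS/SI) are computed on compensated spectra.

## Backscatter model

The spherical Gaussian form factor is used with decay constant 0.827:

    BSC(f) = C₀ · k⁴ a⁶ · conc · exp(−0.827 k² a²),  k = 2πf/c  [1/cm]

with `a` the effective scatterer radius (cm), `conc = n z̄²` the acoustic
concentration (cm⁻³) and C₀ = 1/36 an amplitude convention. Absolute
AAC values are convention-dependent (the amplitude constant and the
effective elevation of the 2-D simulation both enter additively in dB);
differences — including the week-minus-baseline ΔAAC features — are
convention-free. The fit is linear: regress ln(BSC/k⁴) on k²; slope →
a, intercept → conc after dividing out C₀a⁶. Windows with non-negative
slope carry no size information and are excluded from map means rather
than clamped (clamping would bias ROI averages); their fraction is
reported as QA. Because the excluded set is one tail of the slope-noise
distribution, ROI-mean ASD acquires a small upward bias when the
per-window slope SNR is low (small scatterers, few lines per window);
at the package's default simulation geometry the median error stays
within 15 %.

## SAS

Mean scatterer spacing uses the raw (un-normalized) gated RF:
normalization cancels in ripple spacing, and the raw data keeps usable
bandwidth past the −6 dB edges, so the SAS band is the nominal band
widened to the pulse's ≈ −20 dB span. Per line, a Burg autoregressive
spectrum (statsmodels' Burg recursion; order 64 by default) is evaluated
on a dense grid; dB spectra are averaged across the window's lines
(line-averaging suppresses speckle ripples but preserves
lattice-position ripples, whose frequencies are phase-independent), a
cubic baseline removes the pulse envelope, and the ripple period Δf is
the first prominent peak of the unbiased autocorrelation within the lag
range implied by `sas_range_mm` (default 0.15–0.8 mm), refined by
parabolic interpolation; SAS = c/(2Δf). The first-prominent-peak rule
(earliest peak ≥ 0.6× the tallest) rejects harmonics of the fundamental.
Coherence is the normalized autocorrelation at the peak, in [0, 1]; it
separates quasi-periodic from Poisson media. The AR order must exceed
roughly twice the ripple time-lag (8–42 samples at 40 MHz for these
spacings), which is why the default is 64, not a small order; windows
shorter than 4× the order are extended axially (centered) before
fitting. In parametric maps, per-(gate, line) Burg spectra are cached
and shared between overlapping windows.

## Texture

Maps are min–max quantized over valid windows into 16 levels (shift- and
gain-invariant by construction). GLCMs accumulate pairs only when both
pixels are valid (ROI maps are irregular; padding would fabricate
texture), pool the four distance-1 offsets, symmetrize and normalize.
CON/COR/HOM/ENE follow the Haralick definitions with COR := 0 for
zero-variance maps. Per-offset averaging is available
(`glcm_pooling: averaged`); pooled is the default.

## Features and labels

A scan yields exactly 31 named features: MBF (dB), SS (dB/MHz), SI (dB),
ACE (dB/cm/MHz), ASD (µm), AAC (dB/cm³), SAS (mm), plus `<PARAM>-<TEX>`
for the 6 maps × 4 statistics. Subject-week vectors hold 62 values:
`<name>_W0` and `Δ<name>` (week minus baseline; both scans required).
Response labelling: R on pCR, "very low" cellularity, or a size decrease
strictly greater than 30 %; monotone in post-treatment size. Cellularity
is an enumerated pathology input, not computed.

The univariate screen applies Shapiro–Wilk to each group at α = 0.05;
one-way ANOVA when both pass, Mann–Whitney U otherwise (the conventional
normality gate). SEM = sd/√n.

## Classifier protocol

FLD and SVM-RBF run balanced, K-NN unbalanced. Balancing semantics:
within each leave-one-out fold the *training remainder* has its majority
class randomly under-sampled to the minority size, so every subject is
still scored; the under-sampling iteration seeds which majority subjects
are dropped, and metrics are averaged over iterations (default 20;
pooled-over-iterations metrics available behind a flag). Inside every
training fold, features are z-scored with training statistics, selected
by greedy sequential forward selection (at least 1, at most 4; ties
break toward the canonical feature order; stop when no candidate
strictly improves), and hyperparameters tuned (K ∈ {1,3,5,7} for K-NN;
C ∈ {0.1,1,10,100}, γ ∈ {0.01,0.1,1}/d for SVM-RBF) — the held-out
subject never influences any of it.

SFS inner criterion: leave-one-out accuracy within the training fold,
computed in closed form for FLD (rank-one downdates of class means and
within-class scatter, batched across candidates) and K-NN (incremental
squared-distance matrices). For SVM-RBF the inner criterion is a
stratified 3-fold CV accuracy on precomputed RBF kernels built
incrementally from per-feature squared-difference matrices: an inner
LOO with a libsvm refit per candidate per fold would cost ~10⁶ fits per
evaluation for no statistical benefit at n ≈ 47. During the greedy
search the SVM uses C = 1, γ = 1/d; the grid is tuned once on the
selected subset.

FLD uses a ridge-stabilized within-class scatter and a unit-norm Fisher
direction with midpoint threshold, so pooled LOO decision scores are
commensurable across folds (signed distances in z-scored space). K-NN
emits an inverse-rank-weighted vote as its continuous score; SVM-RBF
the margin decision value. ROC curves are computed by score
thresholding; AUC by the trapezoid rule (equal to the Mann–Whitney
pair-counting statistic, which the tests assert). The responder class
is positive throughout.

## Synthetic data

*RF.* Line-by-line 1-D physics: each scan line is synthesized in the
frequency domain as a sum of point-scatterer echoes at exact sub-sample
two-way delays, shaped by a Gaussian pulse (−6 dB band configurable),
an amplitude form factor whose square follows the spherical Gaussian
BSC shape at the true effective radius, and the two-way linear
attenuation law. White noise is added at 35 dB SNR by default.
Scatterer fields are Poisson (density default 24 mm⁻², several per
resolution cell — fully developed speckle) or jittered axial lattices
(independent phase per line, 5 % jitter). The default lateral pitch is
60 mm/512 lines (0.117 mm): ~17 lines per 2-mm window keeps the
per-window spectral variance at the level the linearized BSC fit is
designed for; at half the line density the one-sided exclusion of
non-physical fits visibly biases ROI-mean ASD for small scatterers.
What the simulator does *not* model: diffraction and beam formation,
elevational averaging, multiple scattering, nonlinear propagation, and
electronic-noise coloration. Passing recovery tests therefore shows the
estimators are correct under their own model assumptions, not that
clinical accuracy would match.

*Phantom.* A homogeneous field (default 20 µm effective radius, the
agar-embedded glass-bead regime) with its tabulated BSC computed from
the same generative model, so normalization is exact in expectation,
and a recorded attenuation slope (default 0.5 dB/cm/MHz).

*Cohorts.* Two-class tables (default 35 R / 24 NR) whose week-change
group means and SEMs for the informative features follow the magnitudes
reported for this protocol (week-1 ΔACE −3.00 ± 0.18 vs −3.70 ± 0.20;
week-4 ΔAAC 5.52 ± 0.93 vs 2.58 ± 0.54; per-group SD reconstructed as
SEM·√n), with all other features label-independent noise. Baseline
distributions per feature family are fixed plausible values (they are
irrelevant to classification after z-scoring). Clinical size/cellularity
fields are generated consistently with the labels.

## Numerical choices and degenerate inputs

- All readers reject malformed inputs (schema mismatch, missing
  metadata, empty masks) rather than repairing them.
- Log guards: a floor of 1e−300 inside dB conversions; all-zero RF
  segments are errors.
- Degenerate statistics return conventions, not NaN: COR = 0 for
  zero-variance maps, p = 1 for identical constant groups.
- Every stochastic component takes an explicit seed or Generator;
  generators are bit-reproducible under a fixed seed.

## Known limitations

- Absolute AAC depends on the amplitude convention (C₀, elevation);
  only differences are convention-free.
- The self-normalization nullity is exact at the operation level but
  speckle-scale (≲ 0.5 dB) at the ROI level, see above.
- With the spec's leakage-free wrapper, mean LOO AUC on cohorts at the
  default planted effect sizes is ≈ 0.64 — clearly above chance
  (null ≈ 0.50) but well below the ≈ 0.74 of an oracle given the true
  features, because the informative features win a given fold's SFS only
  about half the time. This is the honest cost of doing selection inside
  the cross-validation loop at n = 59.
- Multiple-testing correction across the 31 features is deliberately
  not applied in the univariate screen (nominal p-values only).
- Problem sizes in tests and in the acceptance script (2.5 cm × 8 mm
  simulated planes, 20-seed Monte Carlo) are chosen to keep full runs in
  the minutes range while leaving every estimator in its operating
  regime.
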