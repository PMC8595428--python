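# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `hyperbold`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The generative model

The simulator is the substrate every estimator is validated against.  Each
in-mask voxel v of each subject evolves as

    y(v, t) = B · (1 + d(t)) + c(v) · g(t) + β(v) · x(t) + ε(v, t)

with the following components.

**Baseline and drift.**  B is the mean intensity (default 100 arbitrary
units).  d(t) is a polynomial on time normalized to [−1, 1] (default
coefficients (0, 0.01, 0.005), i.e. a ~1% slow excursion).  The drift
multiplies the baseline, mimicking slow scanner/thermal gain changes.
Polynomial drift was chosen deliberately to lie exactly in the span of the
detrending basis, so noise-free recovery tests are exact rather than
approximate.

**Inter-brain coupling.**  g(t) is a latent signal shared by spatially
analogous voxels of the two subjects within a designated region.  It is
white Gaussian noise masked in the frequency domain to 0.01–0.1 Hz (the
band the preprocessing filter passes) and standardized exactly to mean 0 /
SD 1 **per run**.  The amplitude

    c = σ · sqrt(ρ / (1 − ρ))

makes two voxels sharing g over independent noise of SD σ correlate at
exactly ρ, because c²/(c² + σ²) = ρ.  Per-run standardization of g removes
the ‖g‖ sampling term from the correlation estimator, which makes
ρ-recovery tests sharp; g is drawn independently per run (runs are
independent acquisitions), and all randomness derives from one master seed
via named `numpy.random.SeedSequence` spawns, so outputs are bit-reproducible.

**Task response.**  x(t) is the block indicator of the stimulus condition
convolved with the HRF (below); β(v) is the response amplitude (default 2
intensity units on baseline 100, a 2% signal change — a typical block-design
effect size).

**Noise.**  ε is stationary AR(1) with marginal SD σ (default 2.2, chosen so
B/σ ≈ 45 matches the whole-brain temporal SNR the hardware delivers) and
lag-1 coefficient φ = 0.3, a typical short-TR BOLD autocorrelation.
Innovation variance is scaled by (1 − φ²) so the *marginal* SD equals σ
regardless of φ — this keeps the coupling formula valid.  The first sample
is drawn from the stationary distribution, so there is no burn-in
transient.  Out-of-mask voxels carry small independent noise (SD = σ/100)
rather than zeros, so division-by-zero paths (tSNR, normalization) are
exercised instead of avoided.

**Motion.**  Traces are smoothed Gaussian random walks per axis (3
translations in mm, 3 rotations in degrees), referenced to the first
volume and rescaled to a random 60–95% of the configured bound.  The
default bounds (140 µm, 0.6°) are the restraint rig's specification; traces
simulated at the specification therefore always pass a QC check at the same
specification — this validates the bookkeeping (units, referencing,
maxima), not the rig.

**Receiver noise.**  Noise-only channel samples are multivariate normal
with a two-coil block covariance: 5 channels per coil, a common intra-coil
correlation (0.10/0.11 per coil) plus one worst-coupled neighbour pair per
coil (0.28/0.29), one worst inter-coil pair at 0.023 over a 0.01
background, and a 1.102 SD ratio between coils (a 9.7% symmetric
noise-level difference).  These values reproduce the scale of an in-vivo
dual-coil noise matrix: intra-coil mean ≈ 12%, max ≈ 28–29%, inter-coil
max ≈ 2.3%.

### What the simulator does *not* emulate

Physiological noise (cardiac/respiratory peaks), EPI geometric distortion
and its phase-encode dependence, k-space/GRAPPA reconstruction effects,
motion-induced *signal* changes (motion traces are metadata, not applied to
the images), hemodynamic nonlinearity, and spatial noise correlations.
Passing tests therefore demonstrate that the estimators are correct under
the stated model, not that the pipeline is robust to every artifact of real
data; the AR(1) noise form in particular is a stand-in, and no test depends
on its exact spectrum beyond the stated tolerances.

## Preprocessing

- **Detrending** uses an orthogonal Legendre basis on [−1, 1], numerically
  stable to the fifth order the task GLM requires.
- **Band-pass** is a zero-phase frequency-domain mask with raised-cosine
  transitions of fractional width 0.2 around each edge (gain reaches 0 at
  0.8·f_low and 1.2·f_high), chosen over an IIR filter for zero phase
  distortion and direct FFT-oracle testability.  Attenuation one octave
  beyond either edge is total (the gain is identically 0 there), comfortably
  beyond a 20 dB requirement; DC is always removed.
- **Order of stages.**  The pipeline runs smooth → detrend → band-pass →
  (normalize inside the synchrony pipeline).  Detrending *before* the FFT
  mask matters: an FFT filter assumes periodicity, so an unremoved monotone
  drift leaks across the whole spectrum, and since the simulated drift is
  common to both subjects it would masquerade as inter-brain synchrony
  (mask-wide spurious r ≈ 0.3 in early experiments).  The task pipeline
  smooths at 2.0 mm FWHM, the resting/synchrony pipeline at 1.5 mm.
- **Smoothing** renormalizes the Gaussian kernel within the brain mask
  (smooth(y·m)/smooth(m)): constants are reproduced exactly in-mask and no
  intensity bleeds in from the background.  This operator has unit row sums,
  not unit column sums, so the in-mask mean of a non-constant field is
  conserved only approximately (drift ≪ field SD); the exact-conservation
  property holds for constants and is tested as such.
- **Normalization** divides by the population SD (ddof = 0); zero-variance
  voxels are set to zero and flagged in `meta['degenerate_voxels']` rather
  than raising, because background voxels are expected.  The convention is
  recorded in provenance.

## Inter-brain synchrony

The statistic is the Pearson correlation between spatially analogous voxels
of the per-run-normalized, concatenated series, transformed as

    z = atanh(r) · √(n − 3).

A fixed threshold of 3.1 is only meaningful on a standard-normal scale —
plain atanh(r) = 3.1 would require r ≈ 0.9996 at any n, implausible for
BOLD — so the variance-stabilized z-score is the default and plain atanh is
available behind a flag.  r is clipped to ±(1 − 10⁻¹²) before atanh so
degenerate identical-series voxels stay finite.  Thresholding is one-sided
at +3.1 by default (positive synchrony is the effect of interest) with a
two-sided option.

**Effective degrees of freedom.**  n is the raw concatenated timepoint
count with no autocorrelation correction.  Under temporally autocorrelated
noise (AR(1) with φ_A, φ_B) the null SD of z inflates to roughly
√((1 + φ_Aφ_B)/(1 − φ_Aφ_B)) ≈ 1.09 at φ = 0.3, so nominal tail
probabilities are mildly optimistic.  The null-calibration tests therefore
evaluate the statistic under its nominal assumption (serially independent
noise), which is also the regime in which the 3.1 threshold has its stated
meaning; the caveat applies equally to any analysis that feeds filtered
data into the same transform.

A related, intended property of detrending: removing p + 1 basis functions
takes a slightly larger fraction of variance from broadband noise than from
the band-limited latent, so recovered ROI correlations sit a few
thousandths *above* ρ (well within the ±0.02 recovery tolerance).

## Task GLM

- **HRF**: the fixed-shape gamma h(t) = t⁴e^(−t)/(4⁴e^(−4)), unit peak at
  t = 4 s, truncated where h < 10⁻⁴ of peak (≈ 20 s).  A parameter-free
  shape keeps simulated-beta recovery exact in the noise-free limit; HRF
  estimation is out of scope.
- **Design**: one convolved indicator per condition, Legendre polynomials to
  order 5 (including the intercept), cosine drift regressors for
  frequencies below 0.01 Hz (DCT-II columns with k/(2·N·TR) < 0.01), and 6
  demeaned motion columns (near-constant columns dropped with a warning).
  The matrix is rank-checked and offending columns are named on failure.
- **Identifiability.**  With two conditions tiling the whole run, the two
  convolved indicators sum to a nearly constant course: each condition
  coefficient alone is poorly identified (partial correlation ≈ −0.997
  against the other), while their *difference* — the stimulus-vs-baseline
  contrast the paired test evaluates — is precise (per-run contrast SE
  ≈ 0.16 intensity units at σ = 2.2).  Recovery tests therefore target the
  contrast, which is also the scientific estimand.
- **Contrasts**: the paired test is the voxel-wise one-sample t on per-run
  (stimulus − baseline) coefficient differences, df = n_runs − 1 (10 runs
  → df 9 → two-sided 5% critical value 2.26).  The between-paradigm test is
  the pooled-variance two-sample t on the paradigms' stimulus effects
  (Welch available behind a flag), converted to z via
  z = Φ⁻¹(F_t(t; df)) evaluated on the far tail for numerical stability and
  thresholded two-sided at 1.96.  Because run-level effect estimates are
  independent across runs, both tests are exact under within-run noise of
  any temporal autocorrelation.  No multiple-comparison correction is
  applied (maps are reported uncorrected, with configurable thresholds).

## Quality control

- **tSNR** = mean of the raw time course / SD of the detrended time course,
  per voxel.  The detrend order defaults to 2 — enough to remove slow drift
  without absorbing signal — and is configurable.
- **Between-subject and between-coil differences** use the symmetric form
  |a − b| / ((a + b)/2) × 100.  For whole-brain tSNR means of 46.4 and 44.5
  this gives ≈ 4.2%; the convention is logged rather than silently matched
  to any rounded figure.
- **Noise correlation** is the Pearson matrix of noise-only channel samples
  (×100), with intra-coil mean/max, inter-coil max, per-coil mean noise
  level (mean channel SD) and the symmetric level difference reported.
- **Motion** maxima are absolute displacements relative to the first row of
  the trace; PASS requires every per-axis maximum within its bound, and the
  check is monotone (enlarging any excursion can never turn FAIL into PASS).

## Geometry conventions

Voxel boxes are 0-based, inclusive-exclusive.  The canonical orientation
for cross-subject comparison is the radiological-display triplet (L, A, S),
fixed in the config rather than inferred; any of the 48 signed axis
permutations is accepted on input and reoriented by axis flips/permutations
(no resampling).  A subject rotated 180° about the scanner y-axis carries
the opposite effective phase-encode polarity after splitting, which is
recorded so distortion-matched comparisons remain possible downstream.
3-D files are promoted to single-volume series so masks share the reader.

## Problem sizes and determinism

Simulated acceptance checks use grids of 10×10×8 to 22×22×21 voxels with
the study's run structure (4 × 400 volumes at TR 1.5 s for synchrony,
10 × 172 volumes for the task), which keeps the full suite under a minute
of compute while leaving Monte-Carlo error well inside every stated
tolerance band.  All randomness flows from one master seed through named
`SeedSequence` spawns; the pipeline writes uncompressed NIfTI and sorted
JSON so identical config + seed yields byte-identical summaries.

## Known limitations

- No despiking, motion correction, distortion correction or ICA estimation:
  in a real deployment those are performed by external tools, and this
  package implements only the downstream statistics (nuisance *regression*
  is implemented; component *estimation* is not).
- The synchrony transform ignores temporal autocorrelation (documented
  above); no time-lagged or frequency-domain coupling is computed.
- Group/atlas-space analysis is out of scope; contrasts are computed on the
  subject grid.
- The motion simulator bounds excursions by construction, so it cannot
  generate the failing traces needed to study QC sensitivity beyond the
  threshold arithmetic (failing cases are constructed directly in tests).
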