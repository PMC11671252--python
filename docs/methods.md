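# Methods

`ecognet` implements an analysis chain for binary category information
(animate vs. inanimate) in trial-epoched multichannel field potentials, and
a synthetic-session generator with known ground truth against which every
stage is validated. This note records the models, the parameter choices
that matter, the numerical conventions, and what the synthetic validation
does and does not establish.

## Data model and geometry

Epochs are a `(trials, channels, samples)` voltage array with a uniform
time axis relative to stimulus onset. The emulated recording layout is two
subdural arrays at 2.5 mm pitch — 8 × 16 contacts over temporal cortex
(TC) and 8 × 8 over dorsomedial prefrontal cortex (dmPFC), 192 channels in
all — with epochs spanning [−0.7 s, 4.0 s) at 500 Hz (2350 samples,
half-open convention). Row 0 of each array is "dorsal" by convention; the
grid metadata lets users with a different physical layout flip rows before
analysis. Global channel ids concatenate the arrays in order.

## Synthetic sessions

The generator superposes, on an i.i.d. Gaussian noise floor (default
variance 1):

- **Category effects** — band-limited Gaussian noise (windowed-sinc FIR
  bandpass, kernel normalized to unit variance gain), multiplied by a
  raised-cosine envelope with 10 ms ramps over the effect window, with
  amplitude scaled per trial by the square root of a per-category power
  gain. `shared=True` gives all effect channels one waveform per trial (a
  coherent source, the configuration ICA is meant to find); `shared=False`
  draws independent waveforms per channel (the configuration in which a
  classifier can average estimator noise across channels).
- **Directed couplings** — a stable MVAR process (companion spectral
  radius < 1 enforced) added to selected channels; innovations Gaussian.
  Per-category scaling of the off-diagonal (coupling) coefficients is
  available but off by default.
- Optional sinusoidal line noise with random per-trial phase.

All randomness derives from a single integer seed; identical configurations
produce bit-identical sessions.

**Effect-size calibration.** A multiplicative band-power contrast is
bounded in discriminability by the spectral estimator's own variance: with
K tapers the per-bin power estimate has std/mean ≈ √(2/2K) (≈ 0.41 at
K = 6), so a ×1.5 power gain on a shared waveform caps single-bin accuracy
near 0.84 regardless of amplitude. The canonical "strong planted effect"
used in validation therefore uses independent per-channel waveforms with a
×2.5 power gain, which yields ≥ 0.95 accuracy at every in-band
time–frequency point of the effect window; the monotonicity checks sweep
effect sizes down to zero.

**Closed-form oracle.** For a known VAR, the spectral matrix is
S(f) = H(f) Σ H(f)\* with H(f) = (I − Σₘ Aₘ e^(−2πifm/fs))⁻¹. Two-channel
systems get Geweke's spectral Granger causality (GC) directly from H and
Σ; marginal and conditional spectra of larger systems have no finite-order
VAR representation, so the exact S(f) is factorized (see below) — still no
data simulation. The bivariate direct formula and the factorization route
agree to ~1e−15, which is the package's guard against a factorization bug
contaminating the oracle.

## Spectral perturbation

Multitaper power uses DPSS tapers over a moving window; per window the
segment is demeaned, tapered, FFT'd (length = next power of two of the
window length by default), and squared magnitudes are averaged over tapers.
Time stamps are window centers and the first window starts at the epoch
start. Stock parameterizations:

| name | window | step | tapers (NW) | frequencies | grid on stock epoch |
|---|---|---|---|---|---|
| high-res | 400 ms | 50 ms | 6 (4) | 1.5–150 Hz | 87 × 76 |
| low-res | 500 ms | 250 ms | 6 (4) | 3, 8, 12, 16, 58, 89 Hz (nearest bins) | 17 × 6 |
| band-decoding | 500 ms | 350 ms | 6 (4) | 1.5–150 Hz | 13 × 76 |

The next-pow2 FFT (200 → 256 samples) gives ≈ 1.953 Hz bin spacing and
exactly 76 bins inside [1.5, 150] Hz; this is the only convention that
reproduces all three printed grid sizes simultaneously, and it is
switchable (`fft_mode="exact"`). Power units are arbitrary — everything
downstream is either ratio-normalized or scale-invariant.

ERSP: per trial, channel and frequency, each time point is divided by the
mean power over baseline windows (centers within [−0.7, 0] s by default),
the ratio is averaged across trials, and 10·log₁₀ converts to dB. Note
that windows whose centers lie just before onset can overlap post-stimulus
samples; analyses needing a strictly pre-stimulus baseline should end the
baseline window half a window early.

## Decoding and inference

The classifier everywhere is a linear SVM with default regularization
(C = 1), trained on non-normalized power features (an optional z-scoring
flag exists, off by default) and scored by stratified 5-fold
cross-validation with seeded fold assignment. Chance is fixed at 0.5
(balanced two-class design); class imbalance triggers a warning, not
reweighting. The implementation is liblinear-based: SMO-based solvers have
unbounded iteration counts and effectively stall on inseparable
permuted-label draws with unscaled power features, which would make the
permutation and bootstrap nulls intractable; liblinear's bounded
coordinate descent behaves identically on the data of interest.

- **Time–frequency map** — one classifier per time–frequency point on the
  per-channel powers; the map has the TFR grid's shape.
- **Band decoding** — on the 13-point decomposition, two fixed analysis
  windows (transient −98–602 ms, sustained 1652–2352 ms; each spans three
  window centers on this grid) supply the features per frequency point
  (channels × window time points); the band accuracy is the median across
  the band's frequency points. Band definitions: delta 2–4, theta 5–8,
  alpha 9–13, beta 14–30, low gamma 31–70, high gamma 71–200 Hz. With ±8 Hz
  multitaper smoothing at the 500 ms window, narrow-band effects bleed into
  adjacent bands; band attribution is only sharp for effects wider than the
  smoothing bandwidth.
- **Bootstrap significance** — one stratified 80/20 train/test split; each
  of n_boot iterations resamples the training trials with replacement,
  fits, and records held-out-test accuracy (the cross-validated-accuracy
  variant is available via `statistic="cv"`). p is the fraction of the
  bootstrap distribution below 0.5; the CI is the 2.5–97.5 percentile
  range. Resampled draws that lose a class are redrawn.
- **FDR** — Benjamini–Hochberg step-up (via statsmodels), validated in the
  test suite against a brute-force implementation of the step-up rule.

## Searchlight

ROIs are all contiguous 2 × 2 electrode blocks per array (stride 1, never
straddling arrays): 105 + 49 = 154 on the stock layout. Features are the
raw voltages of the four member channels over [−0.1, 2.0] s with inclusive
endpoints — 4 × 1051 = 4204 features per trial at 500 Hz. Each ROI gets
the standard decoder and, optionally, bootstrap significance; FDR pools
all ROIs of all arrays. A per-array mask marks ROIs at or above the 95th
percentile of that array's accuracies (linear interpolation between order
statistics; ties at the threshold are included).

## ICA subnetwork identification

Trials are concatenated to a channels × time matrix, centered, whitened,
and decomposed into as many independent components as channels (square
mixing). The implementation uses FastICA, whose contrast separates both
sub- and super-Gaussian sources; the decomposition contract is defined by
recovery tests (Amari index < 0.1 on known 4-source mixtures, inverse
consistency M·U = I, source decorrelation) rather than by a specific
algorithm. Sign and scale are fixed per component by unit-norm topography
with positive maximal element.

Components are scored by category decoding of their low-resolution power:
the decoding value is the mean accuracy over 300–2050 ms across the six
target frequencies. A label-permutation null (shuffling before training)
gives per-component p-values, Bonferroni-corrected across components by
default (FDR available); `informative` means adjusted p < 0.05. An
automated artifact screen (`flag_noise_components`) flags extreme-kurtosis
or single-trial-dominated components, replacing manual visual screening,
plus a manual override list.

Connectivity sites come from the most informative component's topography:
channels strictly above the 95th percentile of all channels jointly,
thinned to 4-neighbor local maxima on the grid, strongest four by default.
A planted coherent source produces near-tied topography weights on its
channels; ties at the percentile make fewer candidates survive the strict
inequality, which the function reports with a warning.

## Conditional Granger causality

Sites are first re-expressed as vertical bipolar derivations (site minus
its same-column neighbor, dorsal by default, ventral for dorsal-edge
sites), which cancels common-mode reference signals exactly.

The cross-spectral density (CSD) matrix is the taper- and epoch-averaged
cross-periodogram over the 0–1 s window with 15 Slepian tapers (NW = 8),
on the full uniform grid from 0 to Nyquist — the factorization needs the
whole half-circle even though GC is reported to 150 Hz.

**Wilson factorization.** S(f) = H(f) Σ H(f)\* with H minimum-phase and
H(∞) = I, computed by Wilson's iteration (plus-operator with halved,
upper-triangularized zero lag; initialization from the Cholesky factor of
the lag-0 covariance; tolerance 1e−9 on the relative iterate change, cap
1000). Analytic/smooth spectra converge to reconstruction residuals
~1e−10. Estimated spectra with sharp peaks stall at a grid-limited floor
(~1e−4 relative) because the exact factor's impulse response outruns the
half-circle lag support; the iteration detects the stall and stops, and an
error is raised only if the reconstruction residual exceeds 1e−2. GC
values are insensitive at the stall level.

**Geweke spectral GC.** Unconditional, source x → target y:
f(ω) = ln[S_yy / (S_yy − Σ̃_xx |H_yx|²)] with Σ̃_xx the source innovation
variance partialized against the target's. Conditional on sites Z: the
reduced set {y} ∪ Z is factorized separately; its minimum-phase transfer
G is embedded with identity at the source position and Q = G̃⁻¹H maps full
innovations onto the reduced-model residual; then
f(ω) = ln[(QΣQ*)_yy / ((QΣQ*)_yy − Σ̃_xx |Q_yx|²)], with Σ̃_xx partialized
against all other innovations. This reduces exactly to the unconditional
formula when Z is empty and yields exact zero for chain-mediated influence
on analytic spectra. Spectra are clipped at zero against roundoff.

**Permutation threshold.** Epoch indices are shuffled independently per
site (preserving marginal spectra, destroying cross-site alignment); per
permutation the maximum GC over frequencies ≤ 150 Hz is recorded per
ordered pair. Two thresholds are reported: the 99th percentile of the null
maxima, and a family-wise-corrected threshold at the 1 − α/n_tests
quantile (default α = 0.05 over 24 band-wise connections — 6 pooled
connections × 4 bands; a stricter per-direction family is just
n_tests = 48). Significance decisions use the corrected threshold. For
unconditional pairs the permutation null is computed in a batched path
(tapered FFTs computed once; only cross-site pairings change per
permutation; Wilson iterations vectorized over permutations).

**dGC.** Per band (theta 5–8, alpha 9–13, beta 14–30, gamma 31–70 Hz —
the low-gamma range adopted for the connectivity gamma band, configurable):
a direction is significant if its spectrum exceeds its threshold anywhere
in the band. If both directions are significant, the dominant one (larger
band value) is compared to the other at the dominant spectrum's in-band
peak — a local maximum of the 3-bin-smoothed spectrum strictly above both
neighbors — or via band means when no peak exists; if only one direction
is significant, its own band value is taken; dGC ≥ 0 by construction and
a band with neither direction significant is marked `None`.

**Site pooling.** The 4-site design with 3 subregion labels (one doubled)
yields C(4,2) = 6 site pairs — 5 inter- and 1 intra-subregional — and,
after averaging ordered-pair spectra over the doubled subregion, 6 directed
subregion-level connections.

## Validation scales and what they show

The test suite and the acceptance script run everything at desk scale:
structural counts on the full 192-channel geometry but few trials; oracle
agreement on 10⁵-sample VAR realizations (estimated conditional GC within
10% of the closed form at the coupling peak); calibration on 200 null
replicates with 200 bootstrap/permutation iterations; end-to-end recovery
over 20 seeded replicates of a 16-channel session with a planted coherent
subnetwork and an alpha-resonant directed coupling. These sizes were
chosen so the full validation runs on a laptop-class machine in minutes
while keeping binomial error on calibration rates below ~2 percentage
points.

Passing on synthetic data shows the machinery is correct and calibrated
under its own model: Gaussian noise floor, stationary band-limited
effects, linear mixing, Gaussian MVAR couplings. It does not establish
performance under real-recording phenomena the generator deliberately
omits: 1/f background spectra, volume conduction and spatially correlated
noise, nonstationary artifacts, eye-movement or reward-locked components,
imperfect line-noise removal, or effect waveforms that differ between
trials in ways other than amplitude. Filter responses are idealized
(zero-phase FIR throughout precisely so that no phase distortion enters
the directed-connectivity stage).

## Known limitations

- The bipolar derivation requires a same-column neighbor; single-row
  arrays are rejected rather than falling back to horizontal pairs.
- Conditional GC inherits the factorization's grid-limited accuracy on
  sharply peaked estimated spectra; very long epochs (finer grids) reduce
  the floor.
- The IC permutation test retrains the classifier for every component ×
  permutation; at the full 192-component, 1000-permutation scale this is
  compute-heavy and intended for batch execution.
- Multitaper smoothing (±8 Hz at 500 ms windows) limits band attribution
  of narrow-band effects to bands wider than the smoothing bandwidth.
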