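# Methods

`usvdyad` reconstructs, as one tested pipeline, the analysis chain used to
study sex differences in mouse ultrasonic vocalizations (USVs) during free
male-female interaction: an 8-microphone array records 250 kHz audio while
an overhead camera tracks both animals at 30 frames/s; every vocal signal
is detected in the time-frequency plane, localized, probabilistically
assigned to one mouse, quantified acoustically, placed in a behavioral
context, and fed into nonparametric sex-difference statistics.

## Signal detection (segmentation)

Each channel is bandpass filtered to 30-110 kHz (4th-order Butterworth;
the zero-phase forward-backward |H|² response is applied in the frequency
domain, which is equivalent up to negligible circular edge effects).
Short segments (NFFT = 64, 128, 256 samples, 50% overlap) are transformed
under K = 5 Slepian tapers with time-bandwidth product NW = 3, and
Thomson's harmonic F statistic — F(2, 2K−2) under locally white noise —
scores every bin for a sinusoidal line component.  Because the F statistic
is scale invariant, bins whose power is below 10⁻⁹ of the spectrogram's
peak (float round-off, not a physical noise floor) are treated as silence.

The 24 per-channel-per-scale masks are fused onto a common grid (time step
= hop of NFFT 64, i.e. 0.128 ms; frequency step = bin width of NFFT 256,
i.e. ~977 Hz).  Two deliberate choices depart from a naive OR:

* **Šidák-corrected per-mask level.**  An OR of 24 masks each at p < 0.05
  would mark ~71% of all bins on pure noise.  Each mask is therefore cut
  at 1−(1−α)^(1/24) so the *fused* grid keeps the nominal 5% false-alarm
  rate — the level at which the detector's noise calibration is stated.
* **Count-thresholded box convolution.**  The fused mask is convolved with
  the 11 (frequency) × 15 (time) ones kernel; a bin is retained when at
  least 20 significant pixels fall under the kernel (`box_count_min`,
  configurable; 1 reproduces plain gap-filling dilation).  At the fused 5%
  rate the expected noise count under the kernel is ~8, so isolated
  exceedances cannot seed a region, while a vocalization contour sweeping
  through the kernel contributes 60+ pixels.  Without this threshold the
  dilation of a 5%-density mask percolates and the minimum-size filter
  below loses all power against noise.

8-connected components with ≥ 1500 pixels become vocal signals.  The pixel
count is defined on this grid and is therefore a calibrated, grid-dependent
parameter (exposed in configuration).  On this grid the 1500-pixel floor
corresponds to a detection limit near 12 ms for typical chirp bandwidths.
Overlapping components whose temporal overlap exceeds 90% of the shorter
one and whose median frequencies sit at an integer ratio ≥ 2 (tolerance
0.1) are collapsed onto the lowest (fundamental) component, which is
flagged as a harmonic stack.

**Frequency contours.**  Detection and contouring are decoupled.  Contour
time columns come from a permissive consensus mask (significant at the
nominal level in ≥ 4 of the 24 masks) inside the component's bounding box
expanded by half the kernel — the count threshold erodes region edges, and
this recovers the full support there.  Within each column the frequency is
the power-weighted mean, with weight equal to the *product* of the
channel-maxed powers of the two finest frequency scales (NFFT 128 × 256):
demanding cross-scale agreement sharpens the spectral peak and suppresses
the inward bias of long windows straddling a signal edge.  Columns whose
total weight is below 0.3% of the loudest column are dropped as stray
noise.  On noise-free synthetic linear chirps this recovers slope to <1%,
bandwidth to ~4% (median), and duration to within 1.4 ms (the temporal
support uncertainty of the longest window); these figures are reproduced
by the test suite and the acceptance script rather than asserted here.

## Localization and assignment

For each signal, every microphone is left out once and a planar source
estimate is computed from the remaining seven channels.  The single-subset
estimator is GCC-PHAT pairwise time-differences-of-arrival (parabolic
sub-sample peak interpolation) followed by nonlinear least squares on the
TDOA residuals (speed of sound 343 m/s, 2-D geometry, estimates clamped to
the arena).  This estimator is a documented substitution: the jackknife
and assignment layers are estimator-agnostic, and this choice is testable
against the forward simulator (noise-free planted sources recover to well
under 2 cm).

The eight leave-one-out estimates are averaged into the overall source
location; their scatter sets the covariance of a bivariate normal density
over the cage via the jackknife variance (m−1)/m · Σ dᵢdᵢᵀ, with
eigenvalues floored at (1 cm)² so coincident estimates still define a
density.  Each mouse receives the density value Dₙ at its nose (nose =
centroid + half the tracked major axis along the heading, one shared
definition across modules), and the mouse probability index is

    MPIₙ = Dₙ / Σᵢ Dᵢ .

A signal is assigned only when one mouse's MPI *strictly* exceeds 0.95;
ties and sub-threshold maxima stay unassigned.  Densities are evaluated in
log space so a distant nose underflows to an unassigned signal rather than
a NaN.

## Acoustic features

Seven features per signal: bandwidth (high − low contour frequency),
duration (contour extent), high and low frequency, mean fundamental
frequency (power-weighted contour mean), slope, and amplitude.  Slope is
the time coefficient of an iteratively reweighted least-squares line
(Tukey bisquare, tuning constant 4.685, ≤ 50 iterations) fitted to the
contour — "robust fit" is interpreted as a single-predictor robust linear
model since the contour is one-dimensional.  Amplitude fits a sine
(amplitude, frequency, phase, offset) to each channel's raw voltage trace
over the signal interval, seeded by a linear solve at the signal's mean
frequency, and reports the largest fitted amplitude across the eight
channels.  Amplitude units follow the audio file's voltage scale; no
absolute calibration is attempted.

## Behavioral context

Per-frame kinematics come from central-difference centroid velocities
smoothed with a 5-frame moving average (raw 30 Hz differencing is too
noisy; the window is configurable); movement direction is undefined below
1 cm/s.  "B follows A" requires, simultaneously: B behind A (the vector
from B to A projects positively onto A's movement direction and the
reverse test fails), movement directions aligned within 25°, centroid
distance < 5 cm, and both speeds > 20 cm/s.  "Not close" requires centroid
distance ≥ 15 cm.  Either state must persist ≥ 10 consecutive frames to
form a bout; every following bout for one mouse has an identically framed
followed bout for the partner.  Centroids are used for all distance
criteria (one definition everywhere), and "front/behind" uses movement
direction rather than body heading, for consistency with the alignment
criterion.  A vocalization inherits the context of the emitter's bout
containing its *onset* frame (the emission decision point; midpoint is a
configurable alternative); signals outside every bout are "other".

## Statistics

All contrasts are Mann-Whitney U tests, two-tailed at α = 0.05, with
medians and 25th-75th percentile IQRs (linear interpolation).  The U test
uses exact enumeration of group assignments (ties included) when
min(n₁, n₂) ≤ 8 and the tie-corrected, continuity-corrected normal
approximation otherwise.  The normal approximation agrees with exact
enumeration to ≤ 0.02 for equal group sizes of 5-8; below that the exact
distribution is too coarse for any approximation to track it uniformly
(worst case 0.09 at n = 2), though α = 0.05 decisions agree everywhere
except the knife-edge exact p = 0.0499 at n = 8.  Kolmogorov-Smirnov tests
against a moment-matched normal justify the nonparametric battery; Pearson
correlation (t transform, n−2 d.f.) is used for paired per-session counts.
No multiple-testing correction is applied — each feature is reported at
α = 0.05, matching the original analysis design.

The Monte-Carlo sex-difference index controls for the male/female signal
imbalance: 1000 independent samples of 500 male and 500 female signals are
drawn uniformly *without replacement* (within a sample; independently
across samples, unstratified by session), and each sample contributes

    index = (male median − female median) / (male median + female median).

For slope — the only signed feature — all slopes are first shifted by the
absolute value of the most negative slope over all assigned signals pooled
globally, making values nonnegative while preserving differences and
rank order.  Per-animal analyses collapse each (session, emitter) to its
median, giving 13 male and 13 female points for a 13-dyad study.  The
high/low vocalizer split labels a male "high" when he emitted strictly
more than 2200 signals in a session; his partner female inherits the
label.

## Synthetic data: what it emulates and what it does not

The generator produces the three inputs the analysis consumes, with known
ground truth:

* **Trajectories.**  Both mice run a circle (radius 25 cm, 25 cm/s) inside
  the 76.2 × 76.2 cm arena; scripted bouts switch the angular gap between
  them instantaneously at bout boundaries, with the trailing edge always
  jumping forward so movement direction never reverses.  Distance — the
  one criterion computed from raw positions without smoothing — is then
  the only state that changes, so the classifier recovers scripted bouts
  frame-exactly.  Chord gaps: 4 cm during pursuit, 16 cm during not-close,
  7.5 cm otherwise (between the 5 and 15 cm thresholds).
* **Audio.**  USVs are linear-FM chirps (durations drawn from 15-30 ms,
  the upper part of the typical 10-30 ms range — the 1500-pixel grid
  floor sits near 12 ms; low frequencies 55-70 kHz, bandwidths 8-25 kHz,
  0.5 ms raised-cosine ramps) emitted from the mouse's nose, rendered
  per channel with exact fractional free-field delays (straight line at
  343 m/s) and 1/r gain, plus optional white Gaussian noise.  Linear
  chirps make the slope statistic's ground truth exact.  Not modelled:
  echoes (the recordings this emulates were made in an anechoic chamber),
  microphone directivity, Doppler, vocal-fold mechanics, or amplitude
  calibration.  The male emits 84.5% of the chirps by default.
* **Feature tables.**  Positive features are log-normal per sex (medians
  set to the pooled values reported for real dyads — male bandwidth
  7.9 kHz vs female 6.1 kHz, male duration 17.2 ms vs female 17.9 ms —
  with log-sds matched to the reported IQRs); high frequency is derived
  as low + bandwidth and mean frequency as a Beta(2,2) position inside
  the band so per-row invariants hold exactly.  Slope is plain normal,
  male median negative and female positive; the printed slope magnitudes
  are typographically ambiguous in the source, so the scales are chosen
  such that a 500-signal sample median resolves the sex difference, as
  observed in the original data (1000/1000 negative slope indices).
  Per-session counts are correlated log-normals (medians 3318 male / 477
  female, log-correlation 0.9).  Context labels are drawn per sex at the
  observed per-context rates but features are not context-modulated —
  context-conditioned median *differences*, as opposed to counts, are
  therefore not a reproduction target on synthetic data.

Because the generator and the analysis share the nose-position rule and a
free-field model with no reverberation, passing the recovery tests shows
the pipeline's internal consistency and its noise behavior — not that it
would match the original system bin-for-bin on real recordings, whose
fusion grid and localization internals are not fully recoverable from the
published description.

## Numerical choices and problem sizes

Spectrogram arithmetic runs in float32 (the F statistic is a ratio, so
scale is irrelevant); eigencoefficient accumulation avoids materialising
per-taper spectrograms.  Default validation sizes keep the full chain
comfortable on one CPU: 20 s dyads with 50 chirps for end-to-end recovery,
5 s with 8 chirps for unit fixtures, 13 sessions (~70k signals) for the
statistical study.  All randomness flows through explicit integer seeds;
identical seeds give byte-identical artifacts.

## Known limitations

* The localization point estimator is a substitution, not a reproduction;
  its published error statistics are out of scope.
* Estimates falling outside the arena are clamped to its boundary; how
  the original system treated them is unstated.
* The 1500-pixel threshold cannot be made numerically equivalent to the
  original detector's, because the original fusion grid is undocumented.
* Harmonic resolution uses median contour frequencies; strongly
  frequency-modulated stacks with crossing components would need a more
  careful ratio test.
* The S1-style reader accepts the published per-vocalization table layout
  (CSV or XLSX), but the deposited file itself ships separately; tests
  exercise the reader and the downstream statistics on synthetic tables
  of the same shape.
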