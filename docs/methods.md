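# Methods

This note records the models and procedures the package implements, the
defaults and why they hold, the numerical conventions, and what the
synthetic data can and cannot show.

## Frame features (MFCC, HTK dialect)

The audio chain follows the HTK conventions wherever the textbook recipe is
underspecified, because the classifiers downstream were designed around
HTK-style features:

* pre-emphasis y[n] = x[n] − α·x[n−1] with α = 0.97 and y[0] = (1−α)·x[0];
* framing by `floor(ms·fs/1000)` samples — 1102-sample windows and
  441-sample hops at 44.1 kHz — with the trailing partial frame dropped, so
  a signal of N samples yields `floor((N − win)/hop) + 1` frames;
* a symmetric Hamming window;
* the energy spectral density is the squared magnitude (power, not
  magnitude) of the one-sided FFT, zero-padded to the next power of two
  (2048 for 1102-sample frames);
* 20 unnormalized triangular filters with edges equally spaced on the Mel
  scale mel(f) = 2595·log10(1 + f/700) between 300 and 3700 Hz, the band
  where these vocalizations concentrate their energy;
* natural-log filter energies, floored at 1e-12 so silent frames stay
  finite (`log_floor = 0` disables the floor, used by the gain-covariance
  tests);
* an orthonormal DCT-II; "the first 13 coefficients" is read as c₁..c₁₃
  with c₀ (overall level) excluded, again the HTK reading;
* sine lifter c′ₙ = (1 + (L/2)·sin(πn/L))·cₙ with L = 22.

A gain g > 0 on the waveform shifts every log filter energy by 2·ln g; the
shift lives entirely in c₀, so the retained coefficients are
gain-invariant (up to the floor).  Deltas, cepstral mean normalization and
voice-activity detection are deliberately out of scope.

## Frame classifiers

Features are z-scored per dimension with training-set mean and population
standard deviation (σ floored at 1e-8 to tolerate constant features in tiny
synthetic sets).  The minimum-distance classifier stores per-class centroids
of the normalized features and assigns each frame to the nearest centroid in
Euclidean distance, ties to the lowest class index.  Its score row is
softmax(−d): ranking-preserving, rows summing to one, so the score-series
stage can treat all families uniformly.  Maximum likelihood fits one
Gaussian mixture per class (two full-covariance components by default,
reduced when a class has fewer samples; a single-exemplar class becomes a
degenerate Gaussian at that point) and normalizes the class likelihoods in
the log domain.  The other six families are scikit-learn adapters with
library defaults except where a specific default is part of the method:
kNN uses k = 1, the neural network one hidden layer of 10 neurons.  Training
is unweighted — no class reweighting despite the imbalance.  A training set
containing a single class short-circuits to scoring that class with
probability one.  Labels always equal the argmax of the emitted score row.

## Score series and LFCC

The C call-class score columns (silence is excluded — rows sum to one, so
its column is redundant) are each transformed as a whole, with no windowing:
a 5–10 s recording yields 500–1000 frames, the same order of magnitude as
the samples in one audio frame, which is why whole-series treatment is
proportionate.  The FFT length is the next power of two at or above the
series length.  The filterbank uses 20 triangular filters with edges equally
spaced from 0 Hz to the score-series Nyquist frequency 1/(2·hop) — 50 Hz at
a 10 ms hop.  A score series that is identically zero (a class never
scored) has zero energy in every filter and would give −∞ log energies; log
filter energies are floored at log(1e-12) before the DCT so every recording
yields 13·C finite features.  No pre-emphasis, band limiting, Mel warping or
liftering is applied: those steps encode vocal-production assumptions that
score series do not satisfy.  Second-stage features are z-scored with
training-set statistics, mirroring the frame stage, and classified by the
same eight families.

Truncating the cepstral representation to n < 20 coefficients reconstructs
the log filterbank vector with an RMSE that is non-increasing in n (an
orthonormal-projection argument, verified by sweep in the tests).

## Metrics

Per class, the one-vs-rest collapse gives SNS, SPC, PRC, NPV, F1,
GM = √(SNS·SPC), BM = SNS+SPC−1 and MK = PRC+NPV−1; global values are
macro averages, ACC is trace/total, and the multiclass MCC is the Gorodkin
R_K statistic.  MCC, BM and MK are reported normalized to [0,1] via
(μ+1)/2.  Zero-division conventions (never triggered on well-populated
data): classes with no true instance are excluded from the SNS/F1/GM/BM
macro averages, an empty predicted column gives PRC = 0, PRC+SNS = 0 gives
F1 = 0, and an undefined R_K denominator gives MCC = 0.  Published
row-percentage confusion matrices are inverted to integer counts by
largest-remainder rounding against the known class totals; the round trip
counts → percentages → counts is the identity even at two printed decimals
for the table sizes involved.

## Cross-validation and the joint grid

Recordings are permuted once and dealt into k = 7 near-equal folds
(unstratified, matching the randomized design; a balanced fixture is used
where a test requires every class in every role).  Iteration t tests on fold
t, holds out fold t+1 for validation and trains on the rest, so each
recording is used k−2 times for training, once for validation, once for
testing.  The normalizer, frame classifier and second stage are fit strictly
on training folds (the result object records the fitted recording ids so
leakage is assertable).  The validation fold is passed to adapters that can
use one; none of the current families do.  Overall performance is the mean
of per-iteration metric vectors; pooled per-recording predictions (each
recording tested exactly once) feed the bootstrap.  A recording that is
all-silence under counting is unclassifiable and is scored as an error
against every class by tallying it as a deterministic wrong label.  The
joint grid sweeps the 8 frame families × (counting + 8 score families),
reusing each fitted frame stage across its nine score methods; cell
failures are recorded and skipped, not fatal.

## Bootstrap

The resampling unit is the recording.  Nb = 10 000 resamples of size S with
replacement, metric vector recomputed per resample (vectorized over
resamples), percentile interval at (1−γ)/2 and 1−(1−γ)/2 with γ = 0.95.
Both the original-sample metrics and the bootstrap means are reported.
Method comparison is paired — identical resample indices for both methods —
and the outperformance probability counts strictly positive differences, so
a method compared with itself scores 0, not 0.5.

## Synthetic data

Calls are rendered as a(t)·sin(2πf_c·t) with a raised-cosine envelope at the
class pulse rate; class templates fix carrier, pulse rate, call duration and
calls per recording.  Noise is additive white Gaussian (optionally
1/f-shaped), scaled so that the mean in-call signal power over the noise
power matches the configured SNR; `inf` disables noise, leaving exact
silence outside ROIs.  ROIs mark exactly the rendered call intervals; frame
ground truth assigns a frame to the recording's class iff at least half the
frame span overlaps an ROI.  A master seed is split into one stream for the
class-label draw and one per recording, so recording i is identical
regardless of how many recordings are generated.  Default class proportions
are 43/7/48/2 %, the imbalance typical of such monitoring datasets.

What the generator does not emulate: real anuran vocal production (formant
structure, frequency modulation), reverberation and propagation,
nonstationary field noise, microphone response.  Tests passing on this
generator therefore demonstrate the correctness and the qualitative
behaviour of the pipeline, not field-recording accuracy levels.

## The short-minority-call benchmark

The benchmark freezes the regime where counting is known to fail: 400
recordings of 2 s at 44.1 kHz, 43/7/48/2 % class mix, in-call SNR 3 dB, and
a 250 ms minority call whose carrier sits 20 Hz from the majority carrier
(1480 vs 1500 Hz) while its pulse rate differs strongly (40 vs 15 Hz).  The
adjacency is the point of the construction: frame-level MFCCs cannot
reliably separate the two carriers at this SNR, so the few minority call
frames are partly absorbed by the majority class and counting mislabels
most minority recordings — the same confusion pattern reported for real
release calls — while the score series retain the temporal signature
(burst length, pulse rate) that the LFCC features expose to the second
stage.  Problem sizes throughout the tests (recording counts, durations,
sample rates, resample counts) are chosen as the smallest that exercise the
statistical behaviour being verified.

## Known limitations

* Exact replication of MATLAB default classifiers is a non-goal; the
  adapters match family and stated hyperparameters, not numerics.
* The second-stage training set is produced by the already-fit frame
  classifier on its own training folds (single-pass, in-sample); nested
  cross-validation is out of scope.
* Counting's unclassifiable-recording policy (error against every class) is
  the conservative choice among several defensible ones.
* The bootstrap uses plain percentile intervals (no BCa) and no
  multiple-comparison correction.
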