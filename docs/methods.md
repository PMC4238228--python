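# Methods

This note documents the models, parameter choices and numerical decisions
behind `semgkit`, and what the synthetic benchmark can and cannot show.

## Signal model of the synthetic generator

A session is a sequence of repetitions: 3 s of rest followed by a 2 s
activity burst, cycling through the four gesture classes until each has 60
repetitions (240 bursts, the standard session size studied). Background
activity is stationary white Gaussian noise (RMS 1, arbitrary units) on
all four channels.

A burst is synthesised directly in the wavelet-packet domain: for each
terminal node of the same Symlet-5 level-3 tree the analyser uses
(periodised, so the basis is orthonormal), independent Gaussian
coefficients are drawn with variance proportional to the target energy of
that (channel, band) cell, and the tree is inverse-transformed. Target
energies factor as

    E[channel i, band r] ∝ spectrum[r] · profile[i, r]

* `spectrum` (class-independent) concentrates energy in the lower bands —
  `(0.38, 0.34, 0.12, 0.06, 0.04, 0.03, 0.02, 0.01)` over the eight
  93.75 Hz-wide bands at 1500 Hz — approximating the typical surface-EMG
  spectrum (20–500 Hz, bulk near 50–150 Hz).
* `profile` (the class signature) gives each band's cross-channel energy
  shares. The default profiles use per-class channel *gains*: class `c`
  drives channel `c` with amplitude gain 2.0 and channel `c+1` with 1.45
  over a unit baseline, the same in every band. Columns sum to 1.

Because the share pattern is constant across bands, every class has the
same per-channel spectral *shape*: features that normalise within a
channel (RWPE) are blind to class by construction, while features that
normalise across channels per band (RFBE) see the signature directly.
This isolates exactly the signal structure the RFBE is designed for.

Each burst is shaped by a trapezoidal envelope with 50 ms linear ramps
(realistic gradual onsets that stress the detector), multiplied by a
per-burst, per-channel log-normal gain jitter (σ = 0.14) emulating
trial-to-trial variability of muscle activation, and scaled so the pooled
burst RMS is `amplitude_snr` (default 8) times the rest-noise RMS. The
dominant/secondary gains and the jitter were set once so that the default
benchmark lands in the accuracy regime typical of able-bodied four-gesture
SEMG studies — roughly 93% at 100 ms rising to 99% at 600 ms — rather
than saturating at 100%.

**What the generator does not model:** motor-unit action-potential trains
(the signal is Gaussian within bands), electrode crosstalk and shift,
fatigue (spectra are stationary within and across bursts), movement
artifact, and power-line interference. Passing tests therefore show that
the pipeline recovers cross-channel band-energy structure under realistic
noise, envelopes and trial variability — not that it handles every
pathology of real recordings.

## Preprocessing

4th-order Butterworth band-pass, 5–200 Hz, designed in second-order
sections (stable at this order/bandwidth) and applied with `sosfiltfilt`.
Zero-phase filtering is chosen because analysis is offline and group delay
would bias onset timing; the effective magnitude response is the squared
design response. The first and last ~100 ms of a filtered recording
contain an edge transient (energies up to several times the rest mean) and
are excluded from threshold calibration and detection.

## Onset detection

Window energy is the sum of squared samples over a 21-sample window,
pooled over all four channels; pooling yields a single onset per movement
rather than four per-channel onsets. The calibration threshold is the
mean energy of 25 abutting rest windows. Detection slides the window one
sample at a time (maximal timing resolution); 20 consecutive strictly
supra-threshold windows mark an onset at the centre sample of the last
window. With stride 1 the k-th consecutive window's centre is the first
centre plus k−1.

The raw mean-of-rest threshold is not usable as-is on stationary rest
noise: rest window energies exceed their mean about half the time and,
being strongly correlated between overlapping windows, make sustained
excursions (measured up to ~3× the mean over a full session), so chance
runs of 20 supra-threshold windows occur routinely. The high-level
pipeline therefore multiplies the calibrated threshold by a safety margin
(default 4×), the multiplicative analogue of the conventional
"mean + h·SD" guard in EMG onset detection. The margin must sit above the
rest excursions and below the in-band burst-to-rest energy ratio
(≈ 1 + SNR², further raised by band-pass filtering, which removes more
noise than signal); 4 satisfies both with wide slack for the default
SNR 8, and detection latency stays under ~50 samples (33 ms), within a
window-plus-ramp of the true onset. Low-level `detect_onset` /
`compute_threshold` take and return thresholds verbatim so the margin is
always explicit.

After each detection, scanning re-arms only once 20 consecutive windows
fall below threshold, so one burst yields one onset. Detections are
labelled with the class of the nearest annotated burst; segments that
would overrun the recording are skipped with a logged warning.

## Features

Full wavelet-packet tree per channel, Symlet-5, level 3. Level 3 balances
frequency resolution against coefficient count per band; Symlet-5 is the
standard choice for SEMG subband features. Energies use only the 8
terminal nodes, giving 4 × 8 = 32 features. Nodes are reported in natural
(Paley) order with an explicit frequency-order map; the generator and all
band-frequency reasoning use the frequency order, which prevents silent
band mislabeling (Paley and frequency order differ from level 2 up).

Boundary handling: `symmetric` extension is the user-facing default;
`periodization` makes the transform orthonormal so total subband energy
equals time-domain energy (Parseval) — exactly only when the segment
length is divisible by 2³, since odd-length levels are otherwise padded
and the boundary coefficient counted twice.

Degenerate cells: a band with zero total energy gets the uniform RFBE
share 1/4 per channel (keeps each band on the probability simplex while
carrying no information); a channel with zero energy gets uniform RWPE
shares 1/8.

## Feature selection

PCA with centring only — RFBE/RWPE features are already commensurate
(simplex-valued shares), so per-feature rescaling would only amplify
noise. The Davies-Bouldin index uses Euclidean scatter (mean distance to
class centroid) and Euclidean centroid separation; it is dimensionless and
invariant to rotation, translation and uniform scaling. Coincident
centroids return +∞ with a warning rather than raising.

The retained dimensionality minimises DB over **all** candidates
k = 1..32 whose cumulative explained variance reaches 90% (feasibility
filter first, then global minimisation — DB is not monotone in k, so no
early stopping; the full trace is recorded). If no k reaches the variance
threshold, all components are kept with a warning. Ties take the smallest
k. Selection is refit inside every cross-validation training fold; held
out data is centred with the training mean.

## Classification and evaluation

One binary RBF-SVM per class; prediction is the class with the largest
decision value, ties resolved by sorted class order. No canonical
hyperparameters exist for this task, so each outer training fold runs an
inner 3-fold grid search over C ∈ {0.1, 1, 10, 100} and
γ ∈ {0.01, 0.1, 1, 10}; both can be fixed to constants to skip the
search. Cross-validation is stratified five-fold (with 60 samples per
class, stratification guarantees every class in every fold; data with
fewer samples per class than folds falls back to unstratified splitting
with a warning). Fold accuracies are summarised as mean ± sample standard
deviation (n−1). Method comparisons use one-way fixed-effects ANOVA on
groups of per-run accuracies.

## Reproducibility and problem sizes

All randomness flows from one master seed: the generator seed and each
(length, method) cross-validation seed are derived from it via seed
sequences, and every run can emit a provenance block (full configuration
plus derived seeds) sufficient to reproduce it bit for bit. The default
benchmark — one session of 240 bursts, six segment lengths, two feature
methods — runs in well under a minute on one CPU, so the test suite and
the acceptance script use it at full scale.

## Known limitations

* The onset threshold margin is calibrated for stationary Gaussian rest
  noise; spiky real baselines may need a different margin.
* The generator's class structure lives entirely in cross-channel energy
  ratios, the regime RFBE targets; it cannot measure how RFBE compares to
  RWPE when classes also differ in per-channel spectral shape.
* Band-pass filtering before wavelet decomposition empties the upper
  subbands (> 200 Hz); their RFBE entries are then shares of residual
  noise and contribute little signal.
* Single-session analysis only; no pooling across subjects or sessions.
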