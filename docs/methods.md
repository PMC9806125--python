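# Methods

This note documents the models and procedures `pgesdetect` implements,
the parameter defaults and why they hold, and what the synthetic
validation experiments do and do not demonstrate.

## Problem

After a generalized tonic-clonic seizure the scalp EEG may show
postictal generalized suppression: diffuse background attenuation below
10 μV.  The quantity of clinical interest is when suppression *ends* —
operationally, the time of the first intermittent slow wave (ISW), a
0.5–5 Hz burst over the returning background.  The detector therefore
reduces to a per-epoch binary classification (suppression vs
non-suppression) on 1-second epochs, followed by a change-point read-out,
and is scored by how far the predicted end time lands from the annotated
one — not by per-epoch accuracy, which says little about the clinical
read-out.

Conventions used throughout: 18-channel longitudinal bipolar montage
(Fp1-F7, F7-T7, T7-P7, P7-O1, Fp2-F8, F8-T8, T8-P8, P8-O2, Fp1-F3,
F3-C3, C3-P3, P3-O1, Fp2-F4, F4-C4, C4-P4, P4-O2, Fz-Cz, Cz-Pz); 200 Hz
sampling (recordings at other rates are resampled on read); amplitudes
in μV; times in seconds after seizure end; epochs are half-open [i, i+1)
with predictions reported on the epoch grid.  The postictal analysis
window is 5 minutes.

## Preprocessing

Two zero-phase 4th-order Butterworth band-passes (applied
forward-backward with reflective padding, so no group delay shifts epoch
timing): 0.5–30 Hz for the EMD/Hilbert features, 0.5–5 Hz for the
baseline features — the narrow band focuses on where ISWs (and the
artifacts that mimic them) live.  Epochs are non-overlapping 1-second
segments; a trailing partial second is discarded.

## Empirical mode decomposition

EMD writes x(t) = Σᵢ IMFᵢ(t) + r_N(t).  One mode is extracted by
sifting: build upper/lower cubic-spline envelopes s₊, s₋ through the
local maxima/minima, subtract their mean m = (s₊+s₋)/2, and repeat on
the result until the intrinsic-mode requirements hold: (1) extrema and
zero-crossing counts equal or differing by one, and (2) near-zero
envelope mean.  Successive modes are sifted from the running residual
until it has fewer than two interior extrema (a trend) or a cap of 10
modes is reached.  Numerical choices, made where the procedure is
underdetermined:

* **Envelopes**: natural cubic splines through the extrema, with the two
  outermost extrema mirrored past each boundary; when a side has fewer
  than two extrema of one kind the signal endpoints serve as knots, so
  sifting can continue until the residual is a genuine trend.
* **Stopping**: a sift iterate is accepted as soon as it satisfies the
  count rule *and* its envelope mean is ≤ 0.05 × signal RMS (mean
  absolute value), with a 50-iteration cap.  Noisy modes can plateau
  above the envelope tolerance while the count rule flickers between
  iterates; the kernel therefore remembers the last count-satisfying
  iterate and returns it at the cap, and in the rare case none occurred
  (slowly decaying riding waves at the boundary) extends sifting —
  bounded at 3× the cap — until the first such iterate.  This makes the
  countable IMF requirement hold for every returned mode by
  construction; reconstruction Σ IMF + residual is exact to round-off by
  construction since each mode is subtracted from the residual.
* The sifting inner loop (extrema scan, tridiagonal natural-spline
  solve, envelope mean) is numba-compiled: a feature pass decomposes
  ~10⁵ one-second epochs per dataset, at ≈0.1 ms each.

Instantaneous amplitude/frequency come from the analytic signal
(`scipy.signal.hilbert`): amplitude = modulus, frequency = d(unwrapped
phase)/dt / 2π clipped to [0, fs/2].

Two EMD-derived features:

* **Per-epoch Hilbert feature** — per channel, the amplitude of the
  Hilbert spectrum summed over all modes and samples of the epoch.  All
  modes are included (the spectrum is not band-restricted here); the
  feature is near-linear in signal amplitude.
* **Artifact feature map** — per channel, EMD over the whole recording;
  each mode's Hilbert amplitude is accumulated into 1-second bins only
  where the instantaneous frequency falls in 0.5–5 Hz, giving an
  18 × 300 map of where slow high-amplitude activity occurred.  The map
  is computed on the signal decimated to 20 Hz (FIR anti-alias,
  zero-phase): only content far below the decimated Nyquist survives the
  0.5–5 Hz gate, and whole-recording EMD cost drops ~30×.  Maps are
  normalized per recording by the 95th percentile of the *covered*
  seconds (zero padding of short recordings is excluded from the
  statistic), so clustering compares spatiotemporal pattern rather than
  absolute gain.  Recordings shorter than 300 s yield zero-padded,
  flagged maps.

## Baseline feature bank

On the 0.5–5 Hz epochs, per channel: mean, excess kurtosis, skewness
(biased moment estimators), Hjorth activity (variance), mobility
(√(var Δx / var x)) and complexity (mobility of Δx over mobility of x),
with zero-variance epochs imputing the ratios to 0; periodogram powers
in the slow (0.5–1 Hz), delta (1–4 Hz) and 4–5 Hz bands (bands above
5 Hz are deliberately dropped — on a 0.5–5 Hz filtered signal they would
measure stop-band leakage); Daubechies-4 wavelet energies.  Three
decomposition levels are used rather than a deeper tree: on 200-sample
epochs the periodized transform stays orthogonal through three even
halvings (200→100→50→25), so coefficient energy equals signal energy
exactly, while a fourth level would halve an odd-length array and break
that invariant.  Across channels: the 153 pairwise Pearson correlations
in canonical pair order, with zero-variance pairs scoring 0.  Total: 18
× 14 + 153 = 405 features per epoch, plus recording id, epoch index and
label.  Epoch i is labelled suppression iff i < T_end (the annotated
first-ISW time); recordings without PGES are all non-suppression.

## Clustering and the sample-weighted forests

K-means (k-means++, 10 restarts, best inertia kept, fixed seed) on the
flattened normalized maps; no further standardization — maps are already
commensurate.  Default K = 7, configurable (the method is insensitive in
the 7–100 range; K > n is an error).  Unseen recordings route to the
nearest centroid (Euclidean; ties to the lowest index).

One random forest per non-empty cluster (default 100 trees, unlimited
depth, √p features per split, fixed seed).  Forest *i* trains on every
epoch of every training recording with sample weight = boost (default 2)
for epochs whose recording belongs to cluster *i* and 1 elsewhere: the
specialist keeps the full training distribution but tilts its impurity
decisions toward its own artifact regime.  The boost value is a free
parameter the source method leaves unquantified; 2 is a deliberately
mild default, exposed in the config.  With K = 1 and boost = 1 the
architecture reduces exactly to a single plain random forest — the
baseline the hybrid is compared against — and the test suite asserts
prediction-level identity with `sklearn`'s forest under the same seed.

Per-epoch label = the forest's majority class, confidence = the
averaged-probability vote fraction of that class (≥ 0.5 in the binary
case).

**Confidence-based correction**: scanning left to right until fixpoint,
a maximal run of identical labels shorter than `min_run` (default 3)
whose mean confidence is below `conf_thresh` (default 0.8) and whose
neighbours agree is flipped to the surrounding label.  Confident short
runs and runs ≥ `min_run` are never altered.  The exact rules of the
original formulation are not public; this rule implements the stated
intent (suppression state does not flicker epoch-to-epoch).

**End detection**: P_end = start of the first non-suppression epoch
following at least one suppression epoch.  No suppression epoch at all →
"no suppression detected"; suppression running to the window end →
P_end = window end, flagged as censored.  Leading non-suppression epochs
(the decaying seizure tail) are thereby ignored.

## Evaluation

TD_r = |P_end − T_end| per recording; TD_avg (and median) plus Acc_5s
and Acc_10s with inclusive thresholds.  Leave-one-out: per fold the
clustering model and forest are refit on the n−1 training recordings
(feature matrices and maps depend only on their own recording and are
computed once).  Only the fold's focal cluster's forest is trained — the
other K−1 specialists would never be consulted in that fold — which
changes nothing in the predictions and cuts training cost K-fold.
Conventions for degenerate folds: a recording annotated without PGES
takes T_end = 0 (suppression ends immediately); a prediction of "no
suppression" takes P_end = 0 and is flagged.  Both conventions are
reported in the `flagged` list of the report.

## Synthetic data

The generator emulates the structure the detector relies on, not
physiology:

* background EEG = 0.5–30 Hz band-limited Gaussian noise, σ = 1 μV
  during suppression (peak-to-peak comfortably below the 10 μV
  criterion per epoch) and σ = 15 μV outside it;
* a 2-s decaying broadband seizure tail (80 μV) at the window start;
* ISWs = raised-cosine-windowed 0.5–5 Hz sinusoid bursts (≈60 μV,
  0.8–1.6 s, jittered frequency/phase/gain across channels) arriving as
  a Poisson process (0.5 /s) after the suppression ends, with the first
  burst placed exactly at the true end time so ground truth is exact;
* artifacts by archetype, each with a channel mask and a per-second
  amplitude envelope: breathing = 0.2–0.5 Hz rhythm, muscle = 20–30 Hz
  noise bursts, movement = smooth 1–3 s transient offsets;
* dataset-level: archetypes assigned by deterministic stratified
  (largest-remainder) apportionment; PGES durations lognormal with
  median ≈ 40 s by default (configurable sampler); per-recording seeds
  spawned from one master seed, so everything is reproducible.

What passing the synthetic experiments shows: the pipeline's mechanics
are correct — features separate the two regimes, clustering recovers
planted artifact structure, the forests and the change-point read-out
recover the true transition, and the hybrid never loses to its own
baseline on clustered-artifact data.  What it does not show: performance
on real postictal EEG, where suppression is less stationary, artifacts
are mixed and idiosyncratic, annotations carry inter-rater noise, and
the suppressed/non-suppressed amplitude contrast is far weaker.  The
synthetic amplitude contrast (1 vs 15 μV) makes the classification far
easier than the clinical task; the experiments validate implementation,
not clinical accuracy.

## Reference experiment sizes

The frozen validation experiments (`pgesdetect.benchmarks`, reported by
`scripts/acceptance.py`) use: 200 three-second tone/noise mixtures for
the EMD audit; 10-s tones at 1/2/4/10 Hz for the Hilbert audit; 40
recordings × 90 s with two disjoint-channel 300 μV movement archetypes
for clustering recovery (movement artifacts of several hundred μV are
the regime where artifact pattern dominates the map; at mild amplitudes
the map legitimately reflects resumption timing as much as artifacts);
60 recordings × 150 s with suppression durations uniform on 20–120 s
for end-to-end leave-one-out recovery (K = 2, boost = 2, 50 trees); 36
recordings × 120 s with three archetypes for the hybrid-vs-baseline
comparison (K = 3 vs K = 1).  These sizes keep a complete run in the
tens of minutes on a single core while leaving each experiment's
conclusion stable across seeds.

## Known limitations

* The artifact feature map includes genuine post-resumption activity
  (ISWs are in-band by definition), so with mild artifacts K-means
  partly clusters by resumption timing — consistent with the method's
  design, but worth knowing when choosing K.
* The confidence-correction rule is an interpretation of an
  underspecified procedure; its two knobs are exposed in the config.
* EMD has no uniqueness theory; different envelope/stopping choices
  yield slightly different modes.  The per-epoch feature (a sum over all
  modes) is insensitive to mode splitting, which is why it, rather than
  individual modes, feeds the classifier.
* The EDF writer targets plain EDF (16-bit, 1-s records), sufficient for
  round-tripping synthetic data; EDF+ annotations are not produced.
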