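# Methods

This note documents the models, numerical choices and defaults behind
`msstm`, and what the synthetic benchmark does and does not demonstrate.

## Forward model and inverse solution

Scalp EEG is modelled as `A = Bθ + ω`, with `B` the (sensors × sources)
lead field, `θ` fixed-orientation source time courses, and `ω` sensor
noise. The package ships a *toy* spherical head: sensors on a unit sphere,
sources on a golden-angle spiral grid at radius 0.85, gain decaying with
squared distance, columns scaled to unit norm and full row rank verified.
This is deliberately not a BEM/MRI head model — it exists so the inverse
problem and its properties can be exercised end-to-end; a user-supplied
gain matrix and source coordinates drop into `LeadField` unchanged.

The inverse is a weighted minimum-norm estimate with weighting
`W = X·diag(‖B₁‖,…,‖B_d‖)` (`X` an optional discrete spatial operator,
identity by default), standardized sLORETA-style: each source estimate is
divided by the square root of its variance, the corresponding diagonal
entry of `W⁻¹Bᵀ(BW⁻¹Bᵀ + λI)⁺B`. Both data and gain are projected to the
common-average reference inside the solver (the gain itself is stored
unprojected, since average-referencing forces rank m−1 and would violate
the full-row-rank construction contract). Pseudo-inverses handle the
resulting rank deficiency. With `λ = 0` the standardized power argmax
reproduces a noiseless single dipole exactly (zero localization error);
the test suite checks this property over randomly chosen dipoles.
`λ = None` defaults to 0.05 × the mean eigenvalue of the sensor Gram
matrix, the usual minimum-norm heuristic for noisy data. Orientation is
fixed (radial), so the variance block per source is scalar.

Microstate analysis accepts sensor-space or source-space series through
the same `EEGRecording` interface (`source_localization.to_recording`);
the synthetic benchmark runs sensor-space by default because the toy
generator emits prototype maps directly in sensor space, and the
localization properties are validated separately.

## Microstate model

GFP is the spatial standard deviation across channels; its strict local
maxima (minimum spacing 10 ms, configurable) provide the high-SNR
topographies that are clustered. Clustering is a modified K-means: maps
are spatially centered and unit-normalized, assignment is nearest-template
in Euclidean distance (equivalently cosine, on unit vectors), centroids
are the renormalized mean of their members, empty clusters are re-seeded
from the worst-fitting maps, and the best of `n_init` (default 20) random
restarts by total GEV is kept. A polarity-invariant mode (absolute spatial
correlation, sign-aligned centroid updates) is available; the default
keeps plain Euclidean assignment for clustering and polarity-invariant
correlation for backfitting, since the squared-correlation fit measure is
sign-blind anyway. Spatial correlation is Pearson across channels after
removing the spatial mean.

Model selection computes, for each candidate K, total GEV and the CV
criterion `σ̂²·((C−1)/(C−K−1))²` with
`σ̂² = Σᵢ(xᵢᵀxᵢ − (a_{lᵢ}ᵀxᵢ)²)/(N(C−1))` — the standard residual-variance
form (the degrees-of-freedom factor requires C > K+1). The default rule
takes the smallest K whose GEV reaches 0.85 and sits at a local minimum of
CV, falling back to the smallest K over threshold, then to the maximal-GEV
K. A looser 0.70 threshold constant is exposed for per-subject
representative-map selection.

Backfitting assigns every sample to the prototype with the highest
absolute spatial correlation. Smoothing re-assigns segments shorter than a
minimum duration (default 30 ms) to the neighbouring label with the higher
mean fit value over the segment, iterating to a fixed point — so smoothing
is idempotent by construction.

Statistics per state: coverage (sample fraction), mean segment duration
(ms), occurrence (segments/s) and the segment-level transition matrix
(row-normalized counts; self-transitions are impossible at segment level,
and rows of states that never hand over stay zero). For any present state,
`occurrence × duration = 1000 × coverage` exactly; this identity is
property-tested on random label sequences.

## Features

Preprocessing filters are 4th-order zero-phase Butterworth second-order
sections (`sosfiltfilt`): band-stop 49–51 Hz for mains, band-pass
0.05–47 Hz. Band edges for the five-band split default to δ 1–4, θ 4–8,
α 8–13, β 13–30, γ 30–47 Hz (the γ ceiling matching the anti-alias
low-pass); all configurable. Note that repeated application of the *same*
narrow band-pass is not exactly idempotent — the soft Butterworth
shoulders re-attenuate band-edge content on every pass (≈4 % RMS change on
white noise) — whereas re-applying the wide preprocessing band to an
already narrow-band signal changes RMS by ≈0.1 %; the latter is the
invariant the filter bank actually relies on and the one under test.

Windows are non-overlapping 1 s by default (stride configurable via an
overlap fraction; trailing partial windows are dropped). Per-window
microstate features concatenate coverage, duration, occurrence and the
flattened transition rows — K(K+3) values, 40 for K = 5 — computed from
the window's slice of a *recording-level* segmentation whose prototypes
were clustered once on pooled source-domain data, so windows are
comparable across subjects. Segments clipped by window boundaries count at
their clipped length. Five-band fusion concatenates in δ→γ order
(200 values). Differential entropy is `½ln(2πeσ̂²)` nats per channel with
the sample variance (zero-variance guard at ε = 1e−12); band power is the
integrated one-sided periodogram over the band, per channel. DE/PSD are
per channel per band; how the original study aggregated them is not
specified, so the per-channel convention is documented here.

## Style transfer mapping

Given target windows `y` and per-class source K-means prototypes (default
3 per class), each target window is paired with its nearest prototype over
all classes (label-blind — target labels are unknown by assumption), with
constant confidence `f = 0.8`. The affine map minimizing
`Σfᵢ‖Ayᵢ + b − xᵢ‖² + β‖A−I‖²_F` is closed-form: with weighted means
removed, `A = (Σf x̃ỹᵀ + βI)(Σf ỹỹᵀ + βI)⁻¹` and `b = x̄_w − Aȳ_w`. `b`
is unregularized; the solve falls back to a pseudo-inverse on singular
systems. Two β policies exist: a fixed value (module default 0.2) and the
scale-aware heuristic `β = β̃·Tr(Σfᵢyᵢyᵢᵀ)/M` with `β̃ ∈ [1,3]`. The /M
normalization makes β commensurate with the per-dimension second moment.
The benchmark pipeline uses the heuristic with β̃ = 2 because its features
are z-scored, where a fixed 0.2 (calibrated on some original feature
scale) would be vanishingly small. The mapping direction is
target→source, so the source-trained classifier applies to adapted target
features; the opposite direction is a matter of swapping arguments.

With the true clean/distorted correspondence as pairs, `f = 1`, `β = 0`,
the solver inverts a planted affine distortion to machine precision
(tested at 1e−6/1e−8 against a stacked least-squares oracle). The
nearest-prototype path instead contracts the target cloud toward the
prototypes — it reduces mean target-to-prototype distance (tested ≥50 %)
rather than literally inverting the planted map.

## Synthetic data: what it emulates, what it does not

The generator mirrors a 28-channel, 250 Hz, three-class design with five
microstates. Ground-truth prototypes are random mutually-orthogonal
zero-mean unit-norm maps (orthogonality makes states identifiable, the
regime the microstate model posits). State sequences are semi-Markov:
truncated-normal dwell times (mean per class/state, sd = mean/4, minimum
2 samples; geometric optionally), segment labels chained by class-
conditional zero-diagonal transition matrices. Class identity is carried
*only* by dynamics — transitions (one favoured successor per state,
rotated per class, margin 0.1 above uniform) and dwell means (flat 100 ms
for class 0, ±40 % linear ramps across states for the others) — never by
map shape, mirroring the premise that prototypes are shared and statistics
discriminate. Within a segment the active map is scaled by a half-sine
envelope (so every segment contains an interior GFP peak, which the
GFP-peak pipeline requires); white channel noise is scaled to a target
signal-to-noise RMS ratio (default 10). Trial-level jitter (10 %)
perturbs dwell means multiplicatively.

Subject "styles" are affine maps applied to *z-scored* feature vectors
(reference statistics from the clean pool): raw microstate feature
dimensions span orders of magnitude (coverage ≈ 0.2 vs duration ≈ 100 ms),
so a random affine on raw features would mostly encode the scale
mismatch. Styles are diagonal-dominant — per-feature log-normal gains and
offsets with mild cross-feature mixing (`A = diag(e^{s·n/2})·(I +
s/3·G/√M)`, `b = s/2·g`) — the form inter-subject EEG feature variability
actually takes (amplitude and duration biases), rather than an arbitrary
rotation no pairing heuristic could survive. The default strength 2.0 was
chosen so the benchmark reproduces the qualitative cross-subject regime
reported for real data: the unadapted classifier degrades markedly
(~53 % vs 33 % chance here) and STM recovers a consistent share of the
loss. At strength 0 every subject is exactly identity.

Not emulated: eye/muscle/line artifacts (the preprocessing filters are
tested on tones instead), realistic cortical geometry and volume
conduction, non-stationarity within trials, and any link between class
and topography shape. Passing tests therefore demonstrate correctness of
the algorithms and the direction of the adaptation effect under the
stated model — not real-data effect sizes.

## Benchmark scale and determinism

The canonical benchmark (`evaluation.benchmark_config`) uses 6 subjects ×
3 classes × 4 trials of 8 s at 250 Hz, broadband (single-band) microstate
features, K-means with 5 restarts, and a 3-fold grid-searched linear SVM
(C pool {0.01k, 0.1k, k | k = 1..9}, 27 values) — sizes chosen so the
full LOSO loop completes in seconds while each fold still sees ~480
training windows. The five-band, 200-dimensional configuration is
exercised by the dimension-identity checks. Accuracies are window-level
percentages; source-side model selection is the grid search's internal
stratified cross-validation on pooled source windows. Everything is a
pure function of (dataset, config, seed): one global seed fans out to
per-trial streams by fixed offsets, K-means restarts and SVM folds are
seeded, and the test suite asserts bit-identical reruns.

## Known limitations

- The toy lead field has no realistic forward physics; localization
  claims transfer to real data only qualitatively.
- Nearest-prototype pairing degrades under distortions that scramble
  neighbourhood structure (e.g. strong dense rotations); iterative
  classifier-in-the-loop confidence re-estimation is out of scope.
- The CNN classifier stage is not included; the evaluation layer is
  classifier-agnostic and the linear SVM is the reference path.
- EDF export is not provided; datasets serialize as `.npy` arrays with
  JSON sidecars.
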