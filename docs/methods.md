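# Methods

## Problem and model

The package classifies 30-second single-lead ECG windows into normal sinus
rhythm (NSR), atrial fibrillation (AFIB) and atrial flutter (AFL). The
classifier is a single entropy-criterion decision tree over 17
interpretable features, chosen over higher-capacity models so that a
clinically trained reader can audit the decision path and the feature
importances β. A triple-nested optimization scheme — candidate feature
subsets × outer performance-estimation folds × inner hyperparameter-search
folds — selects the tree; a multinomial logistic regression trained on the
same features is kept as the comparison baseline throughout.

## Preprocessing

Windows are non-overlapping 30 s cuts per lead, resampled to 128 Hz
(polyphase, anti-aliased; sub-128-Hz sources are rejected rather than
upsampled). Trailing fragments of at least 10 s are kept and zero-padded
after normalization; shorter fragments carry too few beats for the HRV
statistics and are dropped. Normalization subtracts the window mean and
divides by the maximum absolute value, so the output is zero-mean in
[−1, 1]; the alternative min→−1/max→+1 mapping was rejected because it
destroys the zero-centering that the wave-amplitude features rely on.

Despiking replaces non-finite samples and points deviating from a centered
1-s rolling mean by more than 8 rolling standard deviations, by linear
interpolation. The gate sits at 8 SD (not the 4–5 SD habitual for smooth
signals) because ECG is intrinsically spiky: an R peak over a quiet
baseline reaches 5–6 rolling SDs, and a tighter gate clips genuine QRS
complexes — which also breaks the idempotence of the normalization step.
Rail/dropout artifacts an order of magnitude taller than the QRS are still
removed with a wide margin.

Label conflicts inside a window resolve conservatively: any tachycardia
label overrides NSR; two distinct tachycardias, any non-studied rhythm, or
missing annotation coverage discard the window.

## Denoising

A cheap FFT gate decides whether a window needs denoising: contamination
is *significant* when the peak magnitude below 4 Hz or at/above 60 Hz
exceeds the mean magnitude over the 4–60 Hz pass-band. Note that genuine
ECG has low-frequency content (the beat fundamental sits near 1 Hz), so
realistic windows usually gate positive; the gate's job is to let through
the unambiguously clean ones untouched.

Gated windows are upsampled to a 256 Hz analysis rate and decomposed by
variational mode decomposition with K = 32 modes — under the uniform
center-frequency initialization the modes tile the 0–128 Hz half-spectrum
in nominal 4 Hz sub-bands. The solver is the standard ADMM scheme on the
positive-frequency half-spectrum (Wiener-filter mode updates,
center-of-mass frequency updates), numba-compiled. Defaults: bandwidth
penalty α = 8000 (a mode's half-power width then roughly matches the 4-Hz
band spacing; smaller α lets kept modes leak stop-band energy through
their skirts), τ = 0 (no exact-reconstruction dual ascent, appropriate
with noise present), tolerance 1e−6, iteration cap 150. The cap, not the
tolerance, usually ends the run; mode partitions stabilize long before
full ADMM convergence, and reconstruction quality is insensitive to
further iterations. A divergence guard (relative increment above 1e−2, or
non-finite modes) falls back to a zero-phase 4–60 Hz Butterworth
band-pass, flagged in provenance.

Reconstruction sums the modes whose measured center frequency lies inside
4–60 Hz, with a 0.5 Hz edge guard: a strong mains tone pulls a mode's
center to essentially exactly 60 Hz, and floating-point comparison against
the open interval would keep it; modes centered within half a guard of a
band edge are edge-contamination by construction. Index-based selection
(sub-bands 2–15 after sorting by center frequency) is available as the
even-tiling special case. The result is downsampled to 128 Hz and
re-normalized.

One systematic effect worth knowing: removing sub-4-Hz mass band-passes
the T wave and can leave small pre-QRS ripples that the P detector reads
as a low-amplitude P on P-less rhythms. This is harmless as long as
training and inference use the same (gated) denoising path — the
classifier learns the denoised feature distributions — but a model trained
on raw features must not be fed denoised windows.

## Delineation

R peaks: the signal is convolved with a unit-area Gaussian (σ = 12 ms) and
squared (polarity-robust); candidate maxima must exceed 0.4 × the 99th
percentile of the squared smoothed signal, with 250 ms minimum separation;
candidates are refined to the raw-signal extremum within ±40 ms and a
200 ms refractory is re-enforced after refinement. The σ = 12 ms / 99th
percentile pair was measured on the synthetic templates: at σ = 20 ms the
smoothed-squared T wave comes within a factor ~3 of the R level and the
95th percentile sits near the T level, so T waves double-detect; at
σ = 12 ms and the 99th percentile the R level exceeds the threshold by
~3× while T stays a factor ~2 below it across 50–140 BPM.

P/Q/S/T: Q and S are raw-signal minima in [−80, 0] and [0, 80] ms around
R. P and T are maxima of a low-frequency reconstruction — approximation
plus the two coarsest details of a 4-level sym4 DWT, i.e. 0–16 Hz at
128 Hz — searched in [−240, −80] and [80, 400] ms. Two measures keep this
reconstruction usable: the QRS segments (R ± 60 ms) are first replaced by
linear interpolation, because the QRS's own low-frequency leakage
otherwise swamps both windows; and the 0–16 Hz band (rather than 0–8 Hz)
is needed because the P wave (σ ≈ 25 ms) loses most of its amplitude below
8 Hz. The P window is additionally clipped so the previous T wave and its
tail cannot masquerade as P: it starts no earlier than 150 ms after the
previous beat's measured T peak (420 ms after the previous R when no T
was found) — at short RR the window vanishes, as P does physiologically. A wave is *missing* when its prominence over the window
median is below 0.02 normalized units, or when its located extremum sits
on the search-window boundary (a boundary maximum is a neighboring wave's
flank, not a wave apex); missing waves contribute amplitude 0 and zero
adjacent delays. Wave amplitudes are always read off the raw signal at
the located index.

## Features

HRV features use per-interval HR = 60000/RR_i (ms), population standard
deviations for SDSD/SDRR, and strict inequalities with denominator n − 1
(n = number of RR intervals) for PRR50/PRR20. The median beat is the beat
whose R amplitude is the lower median of all R amplitudes (ties → earliest
beat). The four "delay" features are the literal
peak-difference-over-signal-frequency contrasts (amp_X − amp_Y)/fs × 1000
for the consecutive pairs P-Q, Q-R, R-S, S-T — scaled amplitude contrasts,
not independent timing measurements. The timing reading
((index_Y − index_X)/fs) was implemented first and rejected: the PQ
*timing* of a true P wave (≈140 ms before Q) versus denoise-ringing bumps
(≈100 ms) makes that variant a sharper P-wave marker than the P amplitude
itself, inverting the expected feature-importance structure in which the
P-wave amplitude dominates; the amplitude-contrast reading keeps the
P evidence where it belongs. Every formula is mirrored by an independent
loop-based oracle in the test suite and checked to 1e−9 relative tolerance
on 1,000 random beat-series fixtures.

## Synthetic data

Each beat is a five-Gaussian PQRST template (offsets −180/−30/0/+30/+250
ms from R; amplitudes P 0.15–0.25 (per patient)/−0.12/1.0/−0.25/0.3;
widths 25/10/12/10/60 ms). Rhythm laws: NSR draws RR from a truncated
normal with a patient-level mean HR in 55–95 BPM and RR coefficient of
variation 0.05–0.18; AFIB draws i.i.d. RR from a truncated lognormal on
[300, 1500] ms (CV 0.15–0.30, mean HR 70–150), removes the P wave and adds
a fine fibrillatory 6-Hz oscillation (amplitude 0.008–0.018 —
deliberately below the 0.02 prominence gate, as fine fibrillation is
barely visible on a single lead); AFL superimposes a sawtooth at 240–340
waves/min (amplitude ~0.15) with a ventricular response at an integer
conduction ratio drawn from {2, 3, 3, 4} and mild irregularity
(CV 0.02–0.06, variable AV block).

Two slow within-record modulations keep windows of one patient from being
carbon copies: the local mean RR wanders by 2–6 % over a 1–4-minute
period (autonomic drift; disabled when a strictly metronomic CV = 0
rhythm is requested), and the P/T amplitudes wax and wane by 5–20 % over
1.5–5 minutes (electrode-contact drift).

These ranges were calibrated so the fixture reproduces the structure of
the real classification problem rather than an easier surrogate: the NSR
CV range overlaps AFIB's (ambulatory NSR with sinus arrhythmia or ectopy
overlaps rate-controlled AFIB on RR statistics, so P-wave evidence must
carry that split), and AFL is neither perfectly regular nor confined to
one rate (2:1 vs 3:1/4:1 conduction makes it a union of fast-regular and
slow-with-flutter-waves presentations). A generator whose classes
separate on SDRR alone would validate a different, easier problem.

Noise (per record, amplitudes relative to R = 1): baseline wander
0.05–0.20 at 0.15–0.45 Hz, 60-Hz powerline 0–0.10, white noise σ
0.01–0.04, and Poisson-timed 0.5-s half-sine motion bursts (~1/min,
amplitude 0.1–0.3). What the generator does **not** emulate: morphology
change across beats (ectopy, aberrancy), variable flutter block, sensor
saturation, real electrode-motion spectra, multi-lead correlation. Passing
tests therefore demonstrate the pipeline's mechanics and its behavior
under the stated rhythm definitions — not clinical-grade performance on
hospital recordings.

## Training and evaluation

The grid (depth {3,5,7,9,11,13} × min-split {2,10,30,50} × min-leaf
{1,5,10,20}, entropy only) contains the reference operating point
(depth 9, split 30, leaf 5). The randomized search draws 25 points; the
follow-up grid search explores the immediate grid neighborhood of the
randomized optimum. Inner folds are grouped *and* stratified — plain
stratified inner folds would leak patients between inner train and
validation. Class proportions are never rebalanced and the tree gets no
class weights. The final refit uses the modal best hyperparameters across
outer folds.

Selection: candidates must reach CV-mean F1 ≥ 0.75 for every rhythm; the
survivor maximizing the blended macro-F1 (class-wise mean of the average
of CV-mean and holdout F1) wins; ties prefer fewer tree nodes, then the
earlier candidate. A CV-only selection mode is a one-line change in
`selection_macro_f1`.

Evaluation reports row-normalized ("weighted") confusion matrices,
one-vs-rest per-class accuracy/precision/recall/F1 with the 0/0 → 0
convention, macro-F1 as the unweighted class mean (reported at 3
decimals), and one-vs-rest ROC with a micro-average over all pooled
(indicator, score) pairs. Tree scores are the training-class fractions at
the predicted leaf. Degenerate ROC inputs (constant scores, absent
classes) report the chance value 0.5 with no error.

## Benchmark sizing and export

The reference benchmark uses 300 windows per class from 15 synthetic
patients each (one 600-s record per patient), γ = 3 candidates of η = 10
features, 5 outer × 3 inner folds — sizes chosen so a full run, including
~900 VMD decompositions, completes in a few minutes on one CPU while still
exercising grouping, stratification and selection. Fifteen patients per
class (rather than fewer, longer records) keeps the grouped outer folds
statistically stable: with very few patients per class, a single unusual
patient dominates a fold and the cross-validated per-class F1 swings by
±0.1. The larger reference configuration (outer 10-fold) is the library
default for real corpora.

Export serializes the tree to a dependency-free JSON graph (split arrays +
leaf class fractions) evaluated with numpy only; the exporter refuses to
hand back a file that does not reproduce the native model's labels on a
1,000-vector probe exactly and its probabilities within 1e−6. Inference
wall times are logged in provenance but never asserted — they are
hardware-bound.

## Known limitations

- WFDB support covers headers, format 16/212 single-file signals and
  MIT-format rhythm annotations — enough for the classic arrhythmia
  corpora, not the full format zoo.
- The VMD iteration cap trades a few dB of stop-band rejection for
  runtime; raise `VmdConfig.max_iter` for offline use.
- P-wave delineation assumes the template polarity (upright P); inverted
  P waves would be reported missing.
- The AFIB/AFL boundary relies on flutter-wave regularity and rate; mixed
  fibrillation-flutter ("coarse AFIB") has no synthetic counterpart.
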