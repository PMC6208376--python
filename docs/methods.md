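# Methods

`hdqeeg` implements a quantitative-EEG (qEEG) statistical-pattern-recognition
analysis for two-group resting-EEG cohorts — healthy controls versus
Huntington's-disease (HD) gene carriers — together with a synthetic cohort
generator that makes every stage testable against planted ground truth.

## Spectral estimation

The input is a 19-channel 10–20-montage resting recording (≈3 min, eyes
closed), re-referenced to the instantaneous channel mean (average montage).
The signal is cut into consecutive 2-s segments overlapping by 1 s
(`N = floor(T − 2) + 1` segments for a `T`-second recording; 179 for 180 s).
Each segment is tapered with a Bartlett (triangular) window
`w[k] = 1 − |2k/(n−1) − 1|` and Fourier-transformed. The 2-s window fixes the
frequency resolution at 0.5 Hz; with a 45 Hz analysis cutoff each spectrum
keeps 91 bins (0.0–45.0 Hz, DC included — the only grid consistent with
45/0.5 + 1 values).

Per segment we form:

* the **auto-spectrum** per channel, `P_k = 2|X_k|²/(fs·Σw²)` (one-sided
  density; DC not doubled). With this normalization `Σ P_k Δf` equals the mean
  power of the windowed segment (Parseval), verified to <1e−6 relative error.
  Any fixed convention would do — downstream features are scale-covariant —
  but one must be fixed; this one makes unit checks possible.
* the **cross-correlation spectrum** for all 171 = C(19,2) channel pairs: the
  magnitude of the cross-spectral density `|X_i X_j*|` on the same grid. By
  the Wiener–Khinchin theorem this is the power spectrum of the pair's
  cross-correlation function. Magnitude (rather than real part or normalized
  coherence) is used because the quantity is treated downstream as a
  nonnegative power spectrum; auto-spectra are computed as `Re(X X*)` so a
  self-pair is bit-identical to the auto-spectrum.

The per-segment ensemble (N × 91 values per spectrum) is reduced to one
spectrum by a **robust location fit per frequency bin**: a Tukey biweight
M-estimate (c = 4.685, ~95% Gaussian efficiency), initialized at the median
with a fixed normalized-MAD scale, iterated to relative tolerance 1e−6 or 50
iterations, falling back to the median when the MAD is zero. Under 10% gross
contamination the estimate stays ≥5× closer to the clean value than the
arithmetic mean; this is the pipeline's only artifact defense (no epoch
rejection is implemented), which mirrors practice where artifacts are
monitored rather than removed. The per-bin estimator is vectorized over all
190 × 91 = 17 290 bins in single precision with an active-set convergence
mask; float32's ~1e−7 relative precision is far below segment-to-segment
spectral variability.

## Feature reduction

Each 91-bin spectrum is reduced to 11 band features: overlapping 8-Hz bands
starting at 0, 4, …, 40 Hz (the last truncated at 45 Hz) — the only 8-Hz/4-Hz
tiling producing exactly 11 bands on 0–45 Hz. Within a band, bins are averaged
under a Bartlett taper centered on the band, with weights renormalized to unit
sum so a constant spectrum maps to itself. The 190 spectra × 11 bands give the
canonical 2090-feature vector, ordered spectra-major (19 channels in canonical
order, then 171 pairs lexicographically), bands minor. Features are log10
transformed by default (band power is analyzed on the log scale throughout);
nonpositive values are floored at 1e−30 with a warning.

Classical band powers (log10 mean density over delta 0.5–4, theta 4–8, alpha
8–13, beta 13–30 Hz; half-open intervals) are computed from the single-channel
spectra for the group statistics. Published contrast tables of this kind
rarely state their band edges, so these conventional ones are fixed here.

## Disease classifier

A genetic algorithm (GA) searches 20-feature subsets maximizing the repeated
stratified k-fold cross-validated ROC AUC of a linear SVM (C = 1, z-score
standardization fitted inside each training fold). Chromosomes are index sets;
selection is tournament-of-3, crossover samples a child from the parents'
union (duplicates repaired with unused indices), mutation replaces single
genes, and 2-elitism makes the best-fitness trace nondecreasing. Fitness
values are cached per chromosome. The linear kernel is the default because 51
subjects × 20 features favors the simplest margin model; an RBF kernel is
available by configuration.

The trained model maps decision values through a Platt-type sigmoid
(a 1-D logistic regression `σ(A·f + B)` fitted on training decision values,
essentially unregularized) to a disease index in [0, 1]: low ≈ control-like,
high ≈ carrier-like. Sensitivity/specificity/accuracy are read at index 0.5
(the Youden-optimal point is also reported, since no operating threshold is
canonical for this kind of index).

Two evaluation protocols are provided and deliberately contrasted:

* **honest** (default in the library API): the GA selection is repeated inside
  every training fold — unbiased, expensive;
* **paper** (used by the showcase): one subset selected on all data, then only
  the SVM is cross-validated. This single-selection protocol is optimistically
  biased; the test suite quantifies the gap — on label-shuffled data the GA's
  in-sample fitness exceeds 0.9 while the honest nested estimate stays at
  0.50 ± 0.07 (mean over 100 seeds).

## Clinical-correlation indices

For a clinical modality (SDMT, UHDRS-TMS, …) a GA searches feature subsets
whose **first principal component** score maximally Pearson-correlates with
the modality; the index is the subset, its per-feature standardization, and
the unit-norm PC1 loading, sign-oriented so the achieved correlation is
positive. Only PC1 is used (searching over the first m components is exposed
by configuration). Before the search, candidates are screened to the 30
features with the largest marginal |r| against the modality
(sure-independence screening). The screen matters: at pilot-study sample
sizes an unrestricted search over 2090 features maximizing in-sample
correlation is dominated by selection noise and its indices generalize poorly
(held-out r ≈ 0.6 in our recovery experiment, versus ≈ 0.8 with screening
against a planted 0.86); `screen_size=None` restores the unrestricted search.
In-sample optimized correlations are upward-biased, so the recommended
protocol — used by the acceptance experiment — applies a fitted index to
held-out subjects.

Per subject, an index can also be evaluated on 5 equal consecutive
sub-recordings (36 s each for a 180-s recording), rerunning the full
spectra→features pipeline per sub-recording, to expose intra-recording
variability of the index value.

## Group statistics

Per (channel, classical band): group means of log10 band power, the classical
pooled-variance two-sample t (df = n1 + n2 − 2 = 49 at the study's 25/26),
its two-tailed p (uncorrected across the 76 cells, mirrored from the table
machinery this reproduces), and Cohen's d with the pooled SD. Sign
convention, stated because contrast tables rarely state it: **d is positive
when carrier power is higher** (d = carrier − control), **t is oriented
control − carrier**, so t and d always have opposite signs. The printed
columns of such a table are linked by the identity |t| = |d|·√(n1·n2/(n1+n2)),
which the suite verifies on all 22 reference rows to the printed rounding.

The full-spectrum group comparison is a label-permutation test: the statistic
is the squared distance between group-mean log spectra summed over all 19
channels and 91 bins; p = (1 + #{permuted ≥ observed})/(1 + n_perm). The
method behind the original global-difference p-value is unspecified, so this
permutation test is an explicit stand-in with exact finite-sample validity.

The burden-of-pathology score is (CAG − 35.5) × age with the inclusion flag
at > 250.

## Synthetic cohort generator

Each subject's channel signal is a sum of four band-limited Gaussian-noise
carriers (4th-order Butterworth band-passes of white noise at the classical
band edges), each scaled by 10^L where the latent L (log10 amplitude) is
drawn from a group-specific normal. Group means and SDs are calibrated to a
reference table of significant log10-band-power contrasts from a 25-control /
26-carrier resting-EEG cohort (22 channel×band cells, |d| 0.51–0.88; delta
higher in carriers frontally/temporally, theta/alpha higher in controls);
cells outside the table get per-band baseline powers and SD 0.4 with zero
contrast. `effect_scale` multiplies all planted differences;
`effect_scale_for_bayes_auc` converts a target Bayes-optimal AUC
Φ(√(Σd²·scale²)/√2) of the latent contrast into the matching scale (the
showcase uses 0.95 → scale ≈ 0.72).

Amplitudes are calibrated analytically: the mean in-band PSD per unit carrier
variance is computed from the filter responses, so the planted log10 band
powers land on the scale the spectral pipeline measures. Residual biases —
cross-band filter leakage (a strong delta or alpha carrier leaks ~0.1 dex
into a weak neighboring band), the average reference (−0.02 dex), window
leakage, and the robust estimator itself (the biweight location of a skewed
per-bin periodogram ensemble sits ~0.1 dex below its mean, by design — it
estimates the typical level and downweights the exponential upper tail) —
affect both groups alike, so planted *contrasts* (Cohen's d on the latent
scale) are preserved and absolute levels are reproduced to ~0.1–0.2 dex; the
suite verifies the mean empirical d across 500 replicate cohorts to within
0.05 and the absolute level to within 0.25 dex.

On top of the carriers: a narrowband alpha peak (10 ± 1 Hz filtered noise,
posterior channels) mixed into the alpha carrier — the mixture is normalized
so band-power calibration is preserved — optionally split into two peaks
(center ± 1.5 Hz) in the carrier group; and an optional extra ~22 Hz
resonance in right-temporal carrier channels. Their amplitudes are free
parameters (no quantitative description exists to calibrate them against);
the showcase enables both for carriers.

Clinical scores are linear functions of standardized latent amplitudes plus
Gaussian noise, with closed-form planted correlations (`noise_sd_for_r`).
Defaults: SDMT ← T5 alpha at r = 0.86; UHDRS-TMS ← C4 alpha at r = −0.84;
SWR ← O2 alpha at r = 0.5; TFC ← C4 alpha at r = 0.4; BDI-II pure noise.
Scores with hard ranges (TFC 0–13, …) are clipped after noise addition.
Couplings target **alpha** latents as a design choice: with 8-Hz overlapping
bands a theta latent is not linearly identifiable from the features (the
flanking delta and alpha carriers dominate every band containing theta; best
single-feature correlation with a theta latent ≈ 0.64), so a theta-coupled
score could not be recovered at the planted strength by any linear index —
whereas alpha amplitudes are expressed nearly directly (0.92–0.99) and
lower alpha power accompanying worse cognitive/motor scores is the dominant
association in the resting-EEG literature this generator emulates. Carrier
CAG is drawn N(43.2, 2.3) clipped to ≥40 (controls: absent), ages ~N(49.7,
8.5) / N(52.7, 8.7).

Randomness: one seed per cohort, split into per-subject substreams keyed by
subject index, so growing a cohort never perturbs earlier subjects; identical
configuration and seed reproduce a cohort bit-for-bit.

What the generator does **not** emulate: volume conduction and realistic
inter-channel correlation structure (channels are independent, so pairwise
spectra carry only amplitude — not phase-coupling — information), ocular/ECG
artifacts, drowsiness nonstationarity, 1/f background, or biophysical
(dipole/forward-model) sources. Passing tests therefore demonstrate that the
machinery recovers planted spectral-amplitude structure, not that it would
perform identically on recorded EEG.

## Problem sizes and budgets

The end-to-end showcase uses the study conditions: 25 + 26 subjects, 180 s at
250 Hz. Its GA runs at population 30 × 15 generations with a 2-repeat 10-fold
CV fitness (the classifier fitness is the expensive part; the
clinical-correlation GA, whose PCA fitness is cheap, runs at the module
defaults of 100 × 50). Final classifier evaluation uses 10 repeats of
10-fold CV, with 3- and 5-fold comparisons. These sizes are the package's
showcase choices; all are configuration fields, and the module defaults keep
the larger GA (population 100, 50 generations).

The recovery experiments use: 200 held-out subjects for the clinical-index
check; 100 seeds for the label-shuffle null; 10 runs of the planted-feature
recovery (10 informative features of d = 1.0 among 500 noise features,
n = 100/group — the effect size keeps the subset fitness off its ceiling, so
selection pressure persists, while staying well above the spurious
differences chance hands the strongest noise features at that n).

## Numerical details and edge cases

* EDF I/O: 16-bit, 1-s records, fixed symmetric physical range (±8000 µV for
  generated cohorts); round-trips are exact to one quantization step
  (~0.24 µV). Recordings are truncated to the first 180 s; shorter ones are
  accepted down to 60 s. T7/T8/P7/P8 are aliased to T3/T4/T5/T6; non-EEG
  leads are dropped with a log line; a missing analysis channel is a named
  error.
* Zero-variance features are dropped (with a warning) before PCA;
  constant modalities and single-class training sets are errors.
* Degenerate biweight scale (MAD = 0) falls back to the median; an all-zero
  weight set keeps the current iterate.
* The permutation p-value can never fall below 1/(1 + n_perm); n_perm < 99 is
  rejected.
* All derived seeds stay below 2³¹; every stage of a pipeline run derives its
  seed from the single global seed by hashing the stage name.

## Known limitations

* The cross-spectrum choice (magnitude) and the robust-fit algorithm
  (biweight) are documented stand-ins where the emulated analysis is
  underspecified; alternatives (real part/coherence; Huber/median) are
  configuration options.
* The "paper-mode" protocol is provided because it mirrors the
  single-selection analysis typical of small pilot studies; its metrics are
  optimistic by construction, and the honest mode quantifies by how much.
* In-sample clinical-correlation indices are upward-biased even with
  screening; held-out evaluation is the supported estimate of index quality.
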