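# Methods

`glycopore` analyzes single-channel ionic-current recordings of an engineered
α-hemolysin nanopore sensing multisialylated ganglioside oligosaccharides
(GT1a, GT1b, GT1c, GT1aα, GQ1c, GP1c). The pipeline turns a raw current trace
into per-event descriptors, population-level kinetic parameters, and an
event-by-event identity call with an explicit "unknown" category. Because no
recordings are distributed with the package, a synthetic generator reproduces
the statistical structure of such recordings and serves as ground truth for
every test.

## Signal model and synthetic generator

A recording is modelled as an open-pore baseline of current I₀ (default
100 pA — all analyses use ratios, so the absolute level is immaterial)
carrying Gaussian noise (σ = 1 pA), a slow random-walk drift (0.3 pA·s^−1/2),
and Poisson-arriving blockade events. During an event the current drops to
I₀·(1 − d), where the normalized depth d ~ N(depth_mean, depth_sd) per class.
Intra-event fluctuation is a stationary AR(1) process (lag-1 correlation ρ,
marginal SD σ_intra) plus a Poisson process of rectangular "spikes" — brief
excursions toward the open-pore level with a class-specific rate (ms⁻¹),
amplitude (pA) and width (samples). Dwell times are single- or two-component
exponential. The finished trace is low-pass filtered with a zero-phase 4-pole
Butterworth at 5 kHz and sampled at 50 kHz, the recording bandwidth of the
emulated instrument. Events never overlap (single-pore occupancy); an arrival
during an ongoing event is dropped and counted.

Class presets fix the published kinetics: GT1c on the double-mutant pore is
biexponential with τ_slow = 3.19 ms and τ_fast = 0.08 ms (mixture weight
w_slow is unpublished; default 0.5), GT1b/GT1a/GT1aα are single-exponential
with τ = 0.23/0.19/0.50 ms, the depth means are 0.97/0.92/0.92/0.95, GT1c on
the single mutant has τ = 0.40 ms and arrival rate 45.04 s⁻¹. GQ1c and GP1c
kinetics are unpublished; their presets are distinct placeholders flagged
`non_paper`.

Two families of parameters are deliberately package choices:

- **Event-level depth SDs (0.004–0.008).** The published "±" on the fitted
  ΔI₁/I₀ values is the SD across three replicate experiments, not the width
  of the event-amplitude histogram, which is never printed. Values of a few
  tenths of a percent of I₀ are typical of near-complete blockades.
- **Fluctuation and spike parameters (ρ, σ_intra, spike rate/amp/width).**
  Only qualitative statements exist ("more frequent spikes and pronounced
  fluctuations" for GT1aα). The presets encode that ordering and are chosen
  so that every class pair is separated by at least one strong short-event
  statistic: GT1b is quiet (σ 0.4 pA), GT1a is noisy with occasional large
  spikes (σ 2 pA, 3 ms⁻¹), GT1aα combines slow correlated fluctuation
  (ρ 0.85) with dense large spikes (8 ms⁻¹, 30 pA), GT1c is intermediate.
  This realizes the benchmark's intended well-separated-by-construction
  geometry; it does not claim to reproduce the real pore's noise physics.

What the generator does **not** emulate: voltage- and concentration-dependent
kinetics, sub-state structure within events, capacitive transients, 1/f
baseline noise, gating artifacts, or correlations between depth and dwell.
Passing tests therefore demonstrate that the analysis code recovers the
parameters of this model class, not that it would reach the same accuracy on
laboratory recordings.

## Event detection and QC

The detector is a Schmitt trigger against a running baseline: an event opens
when the current falls below I₀·(1 − 0.3) and closes above I₀·(1 − 0.25)
(threshold 0.3, hysteresis 0.05). The running I₀ is the blockwise median of
open-pore samples over a trailing 10 ms window, which follows drift but
ignores the blockades. The 30% detection level is deliberate: the analytes
block ≥ 90% of the current, and after the 5 kHz filter a two-sample blockade
attains only ~40% of its nominal depth, so a 50% level silently discards a
double-digit fraction of brief events; 30% of I₀ is still ≥ 5 baseline σ.

Each event's I₀ is the mean of the preceding inter-event interval (from the
previous event's end). QC excludes events shorter than 0.05 ms and events
whose preceding baseline has fewer than 50 samples; both cutoffs exist in the
emulated workflow but are unpublished, so the values are package defaults.
Event frequency is the count of non-excluded events over the recording time.
Externally picked boundary tables (CSV with sample or millisecond columns)
bypass the detector and share the same segmentation/QC path.

The filter attenuates short events toward baseline, so trace-derived
amplitude populations are biased low unless restricted to longer dwells; the
identification workflow (below) uses a stricter duration cutoff of 0.16 ms —
one 8-sample Welch window — because shorter blockades carry no fluctuation
information at all. Frequency estimation keeps the permissive 0.05 ms cutoff;
a counting analysis should not discard short captures.

## Features

Nineteen descriptors per event, in a fixed canonical order: dwell time; mean,
median, SD, skewness, excess kurtosis of the segment; ΔI₁/I₀ with the segment
median as the blockade level (robust to spikes; the mean is available);
blockade charge ∫(I₀ − I)dt; 10–90% rise time, 90–10% fall time and FWHM of
the depth waveform; Welch-PSD spectral centroid, relative band powers in
(0, 500], (500, 2000], (2000, 5000] Hz and normalized spectral entropy
(−Σp·ln p / ln N over positive-frequency bins); approximate entropy
ApEn(m=2, r=0.2·SD) with the self-match-inclusive definition; and spike count
and rate from a MAD detector (samples beyond 5·(1.4826·MAD) of the median,
runs of ≥ 2 samples count once). Band edges are package choices anchored to
the 5 kHz hardware bandwidth; Welch uses a Hann taper, segment length
min(256, n), 50% overlap, mean detrend.

Missingness is first-class: skew/kurt need ≥ 4 samples and non-zero variance,
the spectral set needs ≥ 8 samples, ApEn needs ≥ 50. No zero-filling happens
at extraction; the per-feature missing rate is itself a reported statistic
(long-residence events drive the ApEn missing rate to ~0, which is the point
of dwell-prolonging pore engineering).

## Kinetic fits and ion selectivity

Dwell-time models are maximum likelihood on unbinned data (the alternative —
least squares on histograms — is bin-sensitive and was not specified):
single-exponential τ̂ = mean with SE τ/√n; the two-component mixture is
fitted by EM from five deterministic quantile-based starts, components
ordered τ_slow ≥ τ_fast, SEs from the finite-difference observed information,
and AIC against the nested single model reported. Amplitude populations get a
Gaussian MLE with a normality flag for dispersion inconsistent with one mode.

Ion selectivity uses the Goldman–Hodgkin–Katz zero-current relation for
K⁺/Cl⁻ with activities approximated by concentrations and T = 298.15 K. With
V the trans-side potential (cis grounded), exp(VF/RT) = (r[K]_cis +
[Cl]_trans)/(r[K]_trans + [Cl]_cis) for r = P_K⁺/P_Cl⁻; the forward and
inverse forms are algebraically exact inverses, and the tests verify the
forward form against a numeric root of the summed GHK flux equations.

## Identification workflow

Dataset assembly subsamples each class to the target size and splits
70/15/15, stratified exactly (±1 event per class); per-class sizes count
QC-retained events. Features are ranked by one-way ANOVA F on standardized
values with listwise deletion per feature (ranking before imputation, so
imputation artifacts cannot drive selection); the top 12 of 19 are kept.
Preprocessing is median imputation with a missingness-indicator column per
feature that had training missingness, then standardization — every statistic
from training rows only, enforced by a SHA-256 fingerprint of the training
matrix. HDBSCAN (min_cluster_size 50) drops noise-labelled points from
training only. Ten candidate classifiers — MLP (64, 32, early stopping),
random forest, XGBoost, RBF-SVC, LDA, kNN, logistic regression, Gaussian
naive Bayes, extra-trees, QDA — are compared by stratified 10-fold CV
(repeats configurable; 5 at full scale, 1 for desk-scale runs), with
accuracy, macro-F1 and balanced accuracy reported and the winner chosen by
macro-F1. The five models beyond the named ones are package choices. The
fitted bundle (preprocessor, selected features, label codec, model, CV
report, config hash) serializes to a directory and round-trips bit-exactly.

The out-of-distribution gate fits one Gaussian KDE per class in the
standardized selected-feature space (Scott bandwidth with a 10⁻² floor).
Initial thresholds sit at the 5th percentile of each class's training
log-likelihoods; calibration moves them to the (1 − coverage) quantile of the
class's validation log-likelihoods (target coverage 0.70). Quantiles use
numpy's median-unbiased estimator — log-likelihood samples are left-skewed
and the linear-interpolation quantile of a few hundred points is visibly
biased. At inference an event is scored only under its predicted class's
density; below threshold it becomes UNK. Calibration adjusts thresholds only,
never re-fits densities. Metrics are reported for all events and for the
accepted-only subset, plus per-class acceptance rates and mixture
compositions over {classes} ∪ {UNK}.

## Numerical choices and degenerate inputs

Readers reject invalid inputs rather than repairing them. Zero-variance
segments yield MISSING shape statistics and zero ApEn; zero MAD yields zero
spikes; zero total PSD power yields MISSING spectral features. Ties in the
voltage-series argmax resolve to the lower voltage. EM label switching is
resolved by the τ_slow ≥ τ_fast convention; the EM log-likelihood path is
recorded and must be non-decreasing. Coverage 1 (0) makes the gate accept
(reject) everything. All randomness flows through `numpy.random.default_rng`
with explicit seeds; identical seeds give bit-identical traces, splits and
predictions.

## Problem sizes

Default study sizes: gate calibration uses 2,000 retained events per class;
classifier evaluation 5,000 per class with 10-fold CV and one repeat; dwell
fits 10,000–20,000 draws; frequency recovery one 120-s trace at 50 kHz. These
sizes keep a full reproduction run in minutes on one CPU while leaving the
recovered parameters' standard errors far smaller than the tolerances they
are compared at.

## Known limitations

Detection resolves no sub-state structure and merges events separated by less
than the filter rise time. Amplitude fits on trace-derived populations are
attenuation-biased for dwells under ~0.3 ms (use the duration-QC'd table).
The GHK computation is two-ion and concentration-based. The 19-feature list
pins the two unnamed members of the published count to spike count and rate —
an interpretation, flagged as such. UMAP is treated as an opaque embedding
for plots; nothing downstream consumes its coordinates.
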