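# Methods

## Signal model and preprocessing

The analysis object is the overnight RR tachogram: the sequence of intervals
between consecutive ECG R peaks. Preprocessing follows standard pediatric
overnight-HRV practice:

* **Trimming.** The first and last 15 minutes are removed (lead placement and
  wake-up artifacts); at least 3 h of signal must remain, checked again after
  artifact rejection. When the input is an RR file rather than an ECG, the
  trim applies to the beat-time span.
* **R-peak detection.** Band-pass 8–20 Hz (3rd-order Butterworth, zero
  phase), first difference, Hilbert-transform envelope, adaptive threshold at
  1.2× a 2 s running RMS with a global floor at half the whole-signal
  envelope RMS, a 0.2 s refractory period, and a search-back pass that
  recovers beats in gaps longer than 1.66× the median RR. The envelope makes
  the detector invariant to polarity and amplitude scaling.
* **Artifact rejection.** An interval is retained iff its duration lies in
  [0.33, 1.5] s **and** it differs from the previously *retained* interval by
  at most 0.66 s (the first retained interval faces only the duration
  clause). The comparison to the previously retained rather than previous raw
  interval makes the rule idempotent and keeps a single ectopic beat from
  cascading rejections. Rejected intervals are counted, never bridged by
  fabricated beats.
* **Resampling.** The tachogram (beat time, NN value) is interpolated with a
  cubic spline — linear interpolation is available by option — and evaluated
  on a uniform grid at 3.41 Hz. The spline spans rejection gaps, avoiding the
  spectral artifacts of zero-filling. Each NN value is anchored at the beat
  closing its interval, so the resampled signal is the generating modulation
  waveform delayed by roughly one beat; this matters only when comparing
  against a known generator, not for any spectral feature.

## Bispectrum estimation

The direct (segment-averaging) estimator: 1024-sample segments, 50% overlap,
per-segment mean removal, Hamming window, 2048-point FFT, and the triple
product X(f1)X(f2)X*(f1+f2) averaged over segments on the first-quadrant
support f1 + f2 ≤ f_N (bin spacing Δf = 3.41/2048 ≈ 0.001665 Hz). A 3 h
recording yields ≥ 70 segments. Per-segment mean removal keeps the DC bin
from dominating the normalization. Scaling the input by c scales raw
magnitudes by |c|³; every downstream feature operates on the normalized
matrix and is therefore scale-free.

Normalization divides every element by the scalar BP = Σ|B| over the stored
support. The sum is taken over the full computable first quadrant rather than
the non-redundant triangle; since the divisor is one positive scalar, the
choice cannot alter any ratio, ranking or normalized feature, only the common
scale. No bicoherence-style per-bin normalization is applied.

Detecting quadratic phase coupling against a noise background is an
*ensemble* operation: the complex bispectra of independent realizations are
averaged (`average_bispectra`), so coherent triads (φ3 = φ1 + φ2) add
constructively while random-phase triple products cancel. For the bundled
demonstration the triad amplitude is placed near the per-bin noise floor
(noise SD 8 s against unit cosines in 512-sample segments, i.e. per-bin SNR
≈ 1.2, from the analytic Hamming-window bin-amplitude formula): coherent
averaging over ~120 realizations then lifts the coupled peak an order of
magnitude above the median ROI magnitude while the uncoupled peak stays at
background. With a strong triad the uncoupled peak would also dominate any
finite ensemble — phase cancellation shrinks it only as 1/√K — which is why
the fixture is designed at noise level.

## Regions

Regions are square band×band sets intersected with the non-redundant ROI
triangle 0 ≤ f1 ≤ f2, f1 + f2 ≤ f_N. Band edges are half-open [lo, hi) with
each family's topmost edge closed, so boundary bins are never double-counted
within a family (the classic and OSA-specific families may overlap each
other; BW2 straddles the VLF/LF boundary by construction). BWRes is located
per subject at the Welch-PSD maximum (Hamming, 1024-sample segments, 50%
overlap) inside 0.15–0.40 Hz, extended ±0.02 Hz and clipped to that
physiologic respiratory range; locating the peak on the power spectrum rather
than the bispectral diagonal is the default, with the diagonal available as a
config option. Because the adaptive band tracks respiration rather than the
matrix diagonal, its f1 = f2 bins lose their harmonic (f3 = 2f1)
interpretation; the four diagonal-dependent features are therefore excluded
for BWRes even when the band happens to contain diagonal bins.

## Features

Fourteen features per region (ten for BWRes): amplitudes (max, min, sum of
normalized magnitudes), Shannon entropies of the magnitude distribution
raised to powers 1–3, phase entropy over a 64-bin histogram of [−π, π),
log-magnitude sums/moments H_1..H_4, the magnitude-weighted bifrequency
centroid (f1m, f2m), and RP_Diag — the region's share of the unit-normalized
whole-diagonal magnitude profile, summed on a linear scale so that power
redistributed to diagonal bins *outside* the region is still felt.

Numerical conventions, chosen where the underlying definitions are silent:

* entropies use natural logarithms (a base change only rescales);
* 0·log 0 := 0 in all entropy sums;
* magnitudes are floored at 1e−15 before logs in H_1..H_4 so normalized
  values cannot underflow to −∞; the floor is far below any meaningful
  magnitude;
* the diagonal index k in H_3/H_4 is the 1-based position within the
  region's diagonal (region-local; a global-bin variant is configurable);
* WCOB weights are the magnitudes |B_N| — a centroid weighted by complex
  values is not a frequency;
* the phase histogram uses N = 64 bins by default (configurable).

Catalog widths follow from the schema: 3 classic regions × 14 = 42 columns;
BW1 and BW2 at 14 plus BWRes at 10 = 38 columns. Subjects whose extraction
fails are logged and dropped, never imputed.

## Selection and classification

FCBF ranks features by symmetrical uncertainty with the severity label,
SU = 2·I(x;y)/(H(x)+H(y)), and discards any candidate at least as associated
with an already-kept feature as with the label. Continuous features are
discretized by equal-frequency binning (10 bins) *inside each bootstrap
replicate*, making selection invariant to monotone transforms; supervised
discretization is a config hook. Voting runs over B = 1000 replicates with a
strict "> 500 votes" rule; the four-group severity label is used for
selection (the subset is then shared by all three binary cutoffs). Ties in
the SU ranking break by column order for reproducibility.

The classifier is a single-hidden-layer MLP with logistic activations and a
logistic output giving the posterior probability of the severe side of the
cutoff. The loss is mean cross-entropy plus (λ/n)·Σw² over connection weights
(biases unpenalized), minimized by L-BFGS (deterministic given the seed; the
backend is scikit-learn's MLPClassifier with alpha = 2λ, which implements
exactly this penalty). Features are standardized with training-set statistics
only; test data reuses the stored mean/SD. Hyperparameters (N_H ∈ {2..20} ∪
{22, 24, .., 50}, λ ∈ {0.5, 1.0, .., 10.0}; 680 combinations) maximize
Cohen's kappa averaged over bootstrap replicates, evaluated on each
replicate's out-of-bag subjects — out-of-bag evaluation avoids the optimism
of resubstitution kappa. Single-class replicates are redrawn. Ties break
toward the smaller network, then the smaller penalty. Decision threshold for
Se/Sp/Acc is 0.5; AUC uses the rank (Mann–Whitney) identity with midranks.

Kappa is defined as (p_o − p_e)/(1 − p_e), with the degenerate all-equal
constant case (p_e = 1) defined as perfect agreement, 1.

## Statistical evaluation

Group differences use tie-corrected Kruskal–Wallis; the all-identical input
(H undefined through 0/0) is reported as H = 0, p = 1. Bonferroni correction
spans the feature family of one report (all feature×index pairs for the
correlation report), and significance is declared at adjusted p < 0.01.
Partial Spearman correlations rank all three variables and apply the
first-order partial-correlation formula, with p from the t approximation on
n − 3 degrees of freedom. AHI and age are the labels the synthetic cohorts
emit; other polysomnographic indices (OAHI, ODI, WASO, stage percentages,
arousal indices) are accepted as optional columns.

## The synthetic cohort generator

The generator is a test fixture with controllable spectra, not a
physiological model. RR(t) = mean_rr + Σᵢ aᵢ(AHI)·cos(2πfᵢt + φᵢ) (+ optional
QPC triads) + white noise, realized at beat times by iterating
t_{k+1} = t_k + RR(t_k). Defaults: 3.6 h duration (≥ 3 h after trimming),
mean RR 0.70 s (a typical sleeping child), oscillations at 0.015 Hz (20 ms),
0.09 Hz (30 ms), a subject-specific respiratory frequency near 0.25 Hz
(30 ms, shrinking ~0.5 ms per AHI unit) and an apnea-cycle component at
0.055 Hz whose amplitude grows 2 ms per AHI unit from a 2 ms baseline —
about 30 ms of apnea-band modulation for a severe subject, within the range
of overnight pediatric RR modulation depths. Artifacts replace a configurable
fraction of beats with short (0.2 s) beats, long (2.0 s) beats and +0.8 s
jumps in equal proportion, exercising all rejection clauses. All randomness
derives from one generator per subject, with subject seeds derived from the
cohort seed by counter.

What the generator does *not* emulate: sleep staging and stage transitions,
respiratory sinus arrhythmia waveshape, 1/f background structure,
age-dependent heart-rate trends, ectopic-beat morphology, and any direct tie
between simulated AHI and true apneic event timing. Passing tests on this
cohort therefore demonstrate that the pipeline recovers planted spectral and
phase-coupling structure with the stated monotone AHI dependence — not
clinical diagnostic performance. Real-cohort accuracy depends on private
clinical recordings and is out of scope here.

## Problem sizes and degenerate inputs

The bundled analyses use a 60-subject cohort for direction-of-effect and
severity classification demonstrations, 120-realization QPC ensembles, a
300-subject planted-signal table for selection recovery, and scaled-down
bootstrap counts (B = 8–200) where the full B = 1000 would only tighten
already-clear averages; defaults in `PipelineConfig` keep the full-scale
values. Degenerate inputs fail loudly: all-zero signals flag BP = 0 and
refuse normalization, empty regions and zero-variance ranks raise, and
single-class training sets are rejected.

## Known limitations

* The R-peak detector is a clean-signal implementation; it is validated on
  synthetic ECGs and is not tuned for pathological morphologies or severe
  baseline wander.
* Phase-histogram features (PE) are discontinuous in the underlying phases;
  under floating-point rescaling of the input, phases of bins whose segment
  products nearly cancel can cross bin edges, so scale invariance of PE holds
  only to ~1e−2 in entropy rather than machine precision.
* BWRes is implemented as the band×band square intersected with the ROI; an
  off-diagonal rectangular construction (respiration × another band) would be
  a different region definition and is deliberately not assumed.
* FCBF's discretization (equal-frequency, 10 bins) and the four-group
  selection label are defaults chosen here; both are configurable.
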