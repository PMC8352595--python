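# Methods

This note documents the models behind each module, the parameters that
matter, the numerical conventions we fixed where several were defensible, and
what the synthetic data does and does not emulate.

## Polysome shift analysis

### Model

For gene *a* in sample *N* with read count n(a, N) and transcript length
length(a), the read density on the TPM scale is

    d(a, N) = 1e6 * (n(a, N) / length(a)) / sum_j (n(j, N) / length(j)).

Length division removes the read-sampling advantage of long transcripts; the
per-sample normalization makes densities comparable across libraries of
different depth, at the cost that each column is compositional (sums to 1e6).
The polysome index

    PI(a) = d(a, poly) / (d(a, poly) + d(a, sub))

is the proportion of the transcript's density found in the polysomal
fractions, and the polysome shift ratio

    PSR(a) = log2(PI_mut(a) / PI_wt(a))

measures the change in polysome occupancy between genotypes. PI and PSR are
computed from replicate-pooled counts (pooling stabilizes the density of
low-count genes); significance is a two-sided, equal-variance two-sample
t-test on the PIs of individual replicates, each replicate TPM-normalized on
its own. No multiple-testing correction is applied by default — the
classification rule is raw p < alpha (default 0.05) with the PSR sign; a
Benjamini–Hochberg option exists but is off.

Degenerate-input conventions: PI is undefined (NaN) when both densities are
0; PSR is undefined when either genotype PI is 0 (log of 0) and the gene is
labelled `undefined` rather than +-inf. In the t-test, genes with zero pooled
variance get p = 1 when the group means are equal and p = 0 otherwise; genes
with fewer than two defined replicate PIs in either group are untestable
(NaN), not an error.

Thresholds: the GO-input lists use PSR <= -0.23 (round(log2(0.85), 2)) and
PSR >= 0.20 (round(log2(1.15), 2)), both inclusive; the expression filter
keeps genes with mean TPM strictly greater than 0.5. The mean TPM is taken
over all sample columns present (poly, sub and cyto replicates alike); the
input table is treated as the gene universe — any biotype filtering is the
caller's job.

### Compositional geometry of PI

Because the poly and sub columns are *separately* normalized to 1e6, the
abundance-weighted mean of the TPM-scale PI is exactly 0.5 in every dataset:
sum over genes of (d_poly + d_sub) * PI = sum d_poly = 1e6, which is half of
sum (d_poly + d_sub). PI is therefore a relative quantity — it does not
estimate the physical fraction of transcript copies on polysomes unless the
two fractions happen to contain equal total length-normalized material. PSR,
as a ratio of PIs, inherits a milder version of this compositional coupling.
The synthetic generator is built around this fact (below).

## Synthetic polysome experiments

The generator interprets its PI parameters on the TPM scale (the estimand of
the pipeline). Per gene it draws a transcript length (uniform integer in
`length_range`, default 300–10,000 nt), a relative abundance (log-normal,
sigma = 1), and a wild-type PI from a normal clipped to (0, 1)
(`pi_baseline_mean` 0.5, `pi_baseline_sd` 0.12 by default — centred where the
compositional constraint puts the typical gene). A planted fraction of genes
(default 10%) has its mutant PI set to PI_wt * 2^true_delta_psr, so the true
PSR of a shifted gene equals the requested delta exactly; when direct scaling
would leave (0, 1) (possible for positive deltas) the shift falls back to the
log-odds scale, and the truth object always records the realized
log2(PI_mut/PI_wt).

To make the drawn PIs and the 1e6-per-column constraint simultaneously
satisfiable, gene masses are exponentially tilted (m_a = c_a *
exp(-s (PI_a - 0.5)), with s solved by 1-D root finding) so the
mass-weighted mean PI is exactly 0.5 per genotype. This is what makes the
downstream estimator unbiased for the stored truth; without it, per-column
renormalization would shift every estimated PSR by a composition-dependent
offset (about +0.1 at the default design). When the drawn PIs do not straddle
0.5 — degenerate configurations such as a single gene with PI = 1 — no
positive-mass tilt exists and masses are used as drawn.

Expected counts in a sample are proportional to density * length (inverting
the TPM transform); with `dispersion` = 0 each sample is a single multinomial
draw of `total_reads_per_sample` reads (so per-sample totals are conserved
exactly), otherwise counts are independent negative binomials with
variance mu + dispersion * mu^2 (default dispersion 0.05, a typical
biological-replicate overdispersion for bulk RNA-seq). Defaults — 2000 genes,
depth 1e6, 3 replicates per genotype x fraction — mirror a modest bulk
polysome-profiling design.

What the generator does not emulate: GC/positional biases, isoform
structure, correlated dispersion across fractions, or library-prep batch
effects. Passing recovery tests therefore show the estimator is correct for
its own sampling model, not that real libraries are free of those artifacts.

## Ciliary beat frequency

### Algorithm

Given a T x H x W stack at acquisition frequency f_s (default expectation
250 Hz), per pixel:

1. **Spectrum** — power = |rfft(series)|^2 on bins k f_s / T,
   k = 0..T//2. "Power" is fixed as the squared DFT magnitude; peak
   positions are invariant to any monotone alternative.
2. **Smoothing** — centred moving average whose width is the nearest odd
   number of bins spanning `smooth_window_hz` (default 5 Hz; 11 bins at
   512 frames / 250 Hz). Edge bins average over the bins actually available
   (shrinking window), which preserves total power for interior-supported
   spectra and never manufactures power at the edges.
3. **Primary peak** — argmax power within [f_min, f_max] (defaults 3 Hz and
   f_s/4, i.e. 62.5 Hz at 250 Hz); ties resolve to the lowest frequency.
   f_min = 3 Hz excludes the DC bin, making the pipeline invariant to
   constant intensity offsets.
4. **Signal/noise split** — sort pixels by primary-peak power (stable sort,
   ties by pixel index); the bottom ceil(0.2 P) pixels define threshold =
   mean + 1.5 * SD (population SD, so the all-equal case is exact); signal
   pixels are strictly above it. This threshold is deliberately permissive:
   at realistic noise levels many background pixels clear it, and recall of
   truly oscillating pixels (not precision) is the design goal.
5. **Noise reference** — per-bin mean + 1.5 * SD over noise-pixel spectra.
6. **CBF** — noise reference subtracted from each signal pixel's spectrum,
   negatives clamped to zero, spectra averaged into a cell spectrum whose
   in-band argmax is the CBF. With zero signal pixels, or when no in-band
   power survives the subtraction, the CBF is reported as undefined (a
   flagged state, not an exception).

`run_cbf` orchestrates the stages per ROI (default: the whole frame as one
ROI); a ROI whose pixels are all classified as signal falls back to a zero
noise spectrum.

### Which spectra feed the final stage

The 5 Hz smoothing exists to make single-pixel peak detection robust: one
pixel's raw periodogram is exponentially noisy per bin, and averaging ~11
bins tames it. The final cell spectrum, however, is already an average over
thousands of signal pixels, which suppresses noise by itself — and smoothing
it flattens the peak into an ~11-bin plateau whose argmax wanders by several
bins. We therefore smooth only for stages 3–4 and build the noise reference
and cell spectrum (stages 5–6) from the raw spectra. Empirically this reads
the peak to the nearest bin essentially always at SNR >= 2, whereas a
smoothed final spectrum misses the one-bin band in ~10% of runs at the same
conditions.

### Preprocessing and time projections

For swimming-cell rendering: invert over the bit range, rescale to full
range, Gaussian blur (sigma 0.5 px, per frame), subtract the per-pixel
temporal median (clamping negatives — this removes everything static),
rescale, then rolling-ball background subtraction (radius 5 px, per frame;
`skimage.restoration.rolling_ball`). A constant stack makes the rescale an
identity rather than an error. Colour-coded time projections tint each frame
with its position in a matplotlib colormap (default `jet`) and take the
per-channel maximum over time.

### Synthetic stacks

Pixels in configured regions oscillate sinusoidally at stated frequencies
(validated against Nyquist) on a constant baseline, plus Gaussian noise,
quantized to uint8 (typical high-speed camera output; 16-bit available via
`dtype`). Defaults — 128 x 128, 512 frames at 250 Hz, amplitude 30 on
baseline 100, noise SD 10 (SNR 3) — match a short high-speed recording of a
beating patch. Not emulated: waveform shape, metachronal phase gradients,
focus drift, photobleaching; recovery results speak to frequency read-out,
not to tracking real waveforms.

## Cohort statistics

Mendelian goodness of fit: Pearson chi-square of observed genotype counts
against a ratio-proportional expectation (default 1:2:1), df = classes - 1.
Fisher's exact test: two-sided by probability ordering (the standard exact
convention — sum the probabilities of all tables with the observed margins
that are no more likely than the observed one). 2x2 chi-square: Pearson
formula with optional Yates continuity correction, off by default; pooling
multi-category defect counts into defective/normal is the caller's choice
and both corrected and uncorrected variants are exposed. All three are thin,
validated wrappers over scipy.stats with explicit degenerate-input errors
(zero expected classes, empty margins).

## Proteome trajectory profiling

Missing LFQ values are treated as absent (NaN; a reader option maps
0-encoded missingness to NaN). Imputation draws, per column, from
Normal(mean - 1.8 SD, (0.3 SD)^2) of the column's observed log2 intensities
and exponentiates back — the widely used "left-shifted normal" convention
for intensities below the detection limit; width and downshift are exposed
because no single pair is canonical. Z-profiles use the sample SD (n - 1),
appropriate at small replicate counts; constant rows become all-zero
profiles and are flagged rather than dropped. GO subsetting is a
case-insensitive substring test on the concatenated annotation strings
('cilia' matches 'ciliary'). Trajectory scoring correlates each protein's
Z-profile with the per-stage mean of the group and labels r >= 0.8 as
`match`; the threshold is a parameter, and no claim is made that it
reproduces any particular published figure's colouring. Constant profiles
have undefined r and are labelled `deviate`, flagged.

The LFQ generator plants a two-genotype, five-stage design in which half the
proteins ramp up along differentiation (log2 amplitude ~2, attenuated by
`group_effect` log2 units in the mutant) and half are flat, with log-normal
replicate noise (SD 0.3 log2 units) and missing-at-random dropouts. Real
LFQ missingness is intensity-dependent (left-censored); the generator's MAR
dropouts are deliberately simpler, so imputation tests verify the sampling
contract, not censoring realism.

## Problem sizes

Simulation-backed checks run at 2000 genes x 3 replicates x depth 1e6 for
the polysome recovery and null type-I analyses, and 50 recordings of
128 x 128 x 512 frames for CBF recovery — sizes at which the recovery
targets are comfortably identified while a full test run stays in the tens
of seconds.

## Known limitations

- PI/PSR are compositional (see above); cross-study comparison of absolute
  PIs is not meaningful.
- The signal/noise threshold is permissive by construction; n_signal_pixels
  is not an estimate of the motile-pixel count and the reported fraction
  only loosely tracks visual motility scoring.
- The t-test treats per-replicate PIs as approximately normal; at very low
  counts a count-based test would be better calibrated.
- Fisher's two-sided p by probability ordering can differ from
  doubling-the-one-sided-p conventions used by some software.
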