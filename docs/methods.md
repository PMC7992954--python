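# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Synthetic data

Every generator is a pure function of its parameter object and a single
integer seed, and always emits ground truth beside the data, so each
downstream estimator has an exact recovery target.

**Cell fields.** Cells are textured ellipses — bright rim (default 200
intensity units) around a dimmer interior (120) on a noisy background
(30 ± 2) — because a rim/interior contrast is the minimal structure that
exercises a bandpass filter, a histogram threshold, and a watershed the
way phase-contrast cells do. Axis ratios are drawn in [1.0, 1.2], radii
from a clipped normal (default 8 ± 1 px). Placement is rejection
sampling with a 2-px clearance between cell boundaries; a configurable
fraction of cells is instead placed as *touching pairs* at centre
distance 0.85 × (r₁ + r₂), which merges their masks into one connected
component and forces the splitter to work. The red channel carries a
bright (180) disk over a dim background (20) for cells drawn as labeled.
Ground truth records centroid, radius, exact pixel area, label flag, and
pair membership. A density guard raises a placement error when the
exclusion discs exceed ~55% of the field.

**Confluency curves.** C(t) = clip(C₀ + r·t + ε, 0, 100) with ε ~
N(0, σ), sampled on a regular grid (default 2 h over 72 h, σ = 0.5%).
The mean path is linear because the downstream readout is a
linear-regression slope: the generator's null satisfies the analysis
model exactly. A logistic variant (capacity 100%, matched initial slope)
is available as a stress test. Note the hard clip at 100%: growth at
2 %/h crosses it within 72 h from any starting point, so slope recovery
experiments must either record less or regress on the pre-saturation
window (below).

**Competition series.** Two exponential populations, labeled fraction
f(t) = f₀e^{r₁t} / (f₀e^{r₁t} + (1−f₀)e^{r₂t}), total count n₀ times
the mixture growth factor. Rendered counts are deterministic roundings
of the expectations rather than binomial draws, so the rendered fraction
differs from the analytic one only by ≤ 0.5/total — at the default
n₀ = 20 that keeps the ground truth within 0.025 of the formula at the
first timepoint and far closer later, which is what makes image-level
fraction recovery attributable to the segmentation rather than to
sampling noise.

**Dose-response, isotopologue, and Ct tables.** Viability = 4PL + N(0, σ)
(default σ = 0.05 of the normalized signal, triplicate wells, 8 doses
spanning the transition). MS intensities = scale × fraction ×
lognormal(0, σ) — multiplicative noise, the standard behaviour of ion
counts — optionally convolved with natural ¹³C abundance first. Ct
tables put expression 1 in the reference group and the programmed fold
in the treated group via Ct_gene = Ct_control − log₂(expression) +
N(0, σ), so ΔΔCt inverts the programme exactly at zero noise.

What the generators do **not** emulate: uneven illumination, focus
drift, cell debris and apoptotic bodies, cell motility between frames,
plate-edge effects, amplification-efficiency differences between qPCR
primers, and chromatographic artefacts. Passing the recovery tests
therefore shows the algorithms are correct and well-calibrated under
clean assay statistics, not that they are robust to every failure mode
of real instruments.

## Imaging

The counting chain is bandpass → automatic threshold → watershed →
measurement.

- **Bandpass** is a difference of Gaussians with sigmas of half the two
  cutoff sizes (defaults 2 px and 64 px): a separable, fully
  reproducible realization of the classic FFT bandpass, specified by the
  same two structure sizes.
- **Threshold** is Otsu's between-class-variance criterion on a 256-bin
  histogram; IsoData is available as a config switch. Bright cells on a
  dark background are assumed; an inversion flag handles the opposite
  dialect. A constant image is a degenerate-histogram error.
- **Watershed** floods the negated Euclidean distance transform from
  markers at its h-maxima. Two numerical choices matter. First, the
  distance map is smoothed with a 0.5-px Gaussian before peak finding so
  the pixelated plateau of a single convex ellipse cannot seed twice.
  Second, the suppression depth defaults to h = 0.5 px: touching pairs
  of *unequal* radius have shallow saddle-to-peak depth on the smaller
  cell, and depths of 1–2 px silently merge an appreciable fraction of
  them, while 0.5 px splits >97% without fragmenting single cells
  (measured on 50 synthetic fields, max count error < 2%). Components
  too shallow to hold any marker keep their connected-component label,
  so watershed labels always refine connected components.
- **Measurement** discards objects outside [min_area, max_area]
  (defaults 30–5000 px; the lower gate should be reduced for cells
  smaller than ~6 px radius), computes centroid/area/mean intensities,
  and flags an object as labeled when its mean red intensity exceeds
  2.0 × the median red intensity over background pixels. Pixel
  coordinates are 0-based (row, col); areas are reported in pixels.

**Confluency** is 100 × foreground/total pixels. By default the
high-pass side of the bandpass is taken in its infinite-cutoff limit
(smooth lightly, subtract the global mean): a finite high-pass would
hollow out any confluent sheet larger than the cutoff and report a
nearly empty well. Because a histogram threshold always bisects
*something*, an explicit contrast gate declares a frame empty (0%, with
a warning) when the foreground/background mean separation is below 4 ×
the pooled within-class standard deviation — pure noise splits at about
1.6 σ, real cells at far more. Multiple frames per well/timepoint are
averaged.

## Growth and the fructolytic index

Growth rate is the OLS slope of % confluency on time (slope, intercept,
R², residual SE). An optional window [t₀, t₁] restricts the regression;
it exists to exclude lag phases and, equally important, saturation: once
a well approaches 100% confluency the linear model is wrong and the
slope biased low. Recovery experiments in this package record 72 h but
regress on 0–46 h from a 5% start, within which no arm at ≤ 2 %/h
reaches the clip.

The index (r_fru − r_ns)/(r_glc − r_ns) requires the glucose arm to
outgrow the no-sugar control by ε (default 0.05 %/h) — with a
non-growing positive control the index is meaningless and a dedicated
error is raised. Negative indices are reported as-is (a fructose arm
below the control is real die-off, not noise to clamp). Replicate
experiments (three by default) are summarized as mean ± SEM; ranking is
ascending by mean with alphabetical tie-break; the fructolytic/
non-fructolytic call uses a configurable cutoff (default 0.2, a free
parameter — no canonical value exists).

## Dose-response and qPCR

The 4PL is fit by least squares with the IC50 on the log scale
(stable across serial-dilution designs), initialized from the data
extremes and the dose nearest half-maximum. The curve is reported in the
canonical hill > 0 orientation. IC50 is the *relative* midpoint
parameter of the fitted curve (not the absolute 50%-of-control
crossing), the standard convention once viability is normalized to the
zero-drug wells of the same sugar condition. Flat data (range < 1% of
the signal) is a no-transition error; optimizer failure is reported via
`converged=False` and propagates NaN through the sensitivity ratio.

ΔΔCt assumes amplification efficiency 2 (perfect doubling, no
efficiency correction). Any set of flagged control genes is accepted and
averaged per sample. Fold SEM uses the delta method on the ΔΔCt scale
(fold × ln2 × combined SE). Ct > 30 is flagged low-confidence. The gDNA
copy-number ratio is the same arithmetic against a single-copy reference
gene and a calibrator sample.

The two-group test is Student's pooled-variance t by default (matching
the named method; Welch via flag), with explicit handling of
zero-variance degeneracies. The two-way ANOVA is a fixed-effects
cell-means implementation: the residual mean square pools within-cell
variance over all cells, and Fisher's-LSD comparisons are plain t tests
on that MS with the residual df and no multiplicity adjustment (that is
the definition of LSD).

## Tracer

Fractions are intensity(M+k)/Σ intensities per metabolite-replicate;
the vector always sums to 1 after both computation and correction.
Natural-abundance correction solves M_obs = A·x, with A the
lower-triangular binomial matrix A[i+j, i] = C(C−i, j)·p^j·(1−p)^(C−i−j),
by forward substitution; p defaults to 0.0107. Small negative solutions
(> −10⁻⁶) are numerical noise, clipped and renormalized; large ones
(< −0.01) trigger a data-inconsistency warning. Correction is OFF by
default (many published M+n panels are uncorrected) but recommended when
comparing metabolites of different carbon counts. Only ¹³C is corrected;
H/O/N isotope effects are ignored — adequate for carbon-skeleton tracing,
a documented limitation otherwise. Formulas for the named metabolites
(fructose, F1P, lactate) and common TCA intermediates are built in and
extensible; carbon counts are parsed from standard molecular formulas.

## Pipeline

A run is a pure function of (YAML config, master seed): per-stage seeds
are derived deterministically from the master seed, every output CSV
carries version/config-hash/seed header comments, unknown config keys
are rejected by name, and a failing stage aborts the run with its name
while renaming its partial outputs to `*.partial`. The bundled demo
config exercises every stage in about a second.

## Problem sizes

The recovery experiments use 200 replicate triplets for the index, 50
fields of 50–300 cells for counting, one five-timepoint series (up to
~1200 cells per 1024² frame) for the competition assay, 100 curve pairs
for the IC50 ratio, and 10,000 null simulations for t-test calibration —
sizes chosen so Monte-Carlo error is comfortably below each check's
tolerance while the whole suite runs in a few minutes on one CPU.

## Known limitations

- No tracking of individual cells across frames; competition fractions
  are per-timepoint population statistics.
- The segmentation defaults are tuned for bright, roughly convex cells
  of 4–12 px radius; strongly elongated or heavily overlapping (> ~30%)
  cells will merge or fragment.
- The linear growth model and OLS readout are only valid below
  confluency saturation; use the regression window for fast-growing
  wells.
- No mzML parsing, peak picking, or RNA-seq quantification — upstream
  vendor/aligner territory, out of scope.
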