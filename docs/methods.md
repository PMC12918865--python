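# Methods

## Scope and data model

The package analyzes two kinds of data: whole-cell voltage-clamp current
traces (delimited text, 20 kHz sampling, inward events negative at −70 mV,
outward positive at 0 mV) and four-channel single-z-plane fluorescence
images (multipage TIFF: homer, bassoon, VGLUT1, VGLUT2; 27 nm pixels).
Because no public recordings or images exist for this preparation, both are
produced by ground-truthed simulators that are first-class, tested parts of
the package; every downstream claim in the test suite is a recovery claim
against planted truth.

## Trace simulation

Events form two independent Poisson processes (Type 1 fast, Type 2 slow;
default 1.5 Hz each, 3 Hz total — the package's standing model of a healthy
relay-neuron recording). Each event contributes a peak-normalized
biexponential kernel A·(e^(−t/τ_d) − e^(−t/τ_r)) with τ_r = 0.5 ms and
τ_d ∈ {2, 8} ms by default; per-event τ_d can be jittered log-normally
(`tau_jitter`, an SD on the log scale, default 0.2 in the cohort pipeline)
with the multiplicative factor mean-corrected so component means stay at
2 and 8 ms. Amplitudes are normal (15 ± 4 pA) truncated below a 5 pA floor
so every planted event is detectable in principle; instrument noise is
i.i.d. Gaussian with RMS 1.4 pA, which puts the 7 pA automated detection
threshold at exactly 5 × RMS. Kernels are rendered until the tail falls
below 1e−12 of the amplitude so a noise-free trace equals the analytic sum
of kernels to numerical precision.

What the simulator does *not* model: series-resistance filtering, dendritic
cable attenuation, amplitude–kinetics correlations, bursting/non-Poisson
timing, baseline drift, and line noise. Detection and classification
figures measured here are therefore upper bounds on real-data performance;
the procedures themselves do not assume any of the omitted features.

## Filtering and event detection

Traces are low-pass filtered before detection with a zero-phase
forward–backward 4-pole Butterworth at 1 kHz. The family and order are a
package choice (only the cutoff is dictated by the acquisition convention);
zero-phase filtering was chosen so decay kinetics are not skewed by phase
lag, at the cost of a known symmetric broadening of the fastest decays.

Candidate events are local maxima of the oriented filtered trace with
absolute height ≥ 0.7 × threshold, prominence ≥ 0.2 × threshold and
separation ≥ 3 ms. The filtered noise floor (σ ≈ 0.44 pA after 1 kHz
filtering of 1.4 pA white noise) sits ~11σ below even the 5 pA threshold,
so these loose gates admit essentially no noise peaks while keeping events
riding on a predecessor's decay. Amplitude is measured baseline-to-peak:
the baseline is the median of a 5 ms window ending at the pre-peak local
minimum (searched ≤ 10 ms back, never across the previous peak), and the
peak value is read from the unfiltered trace averaged over ±0.25 ms to
avoid filter attenuation (amplitude recovery is unbiased to < 1%).

The second detection stage mimics the manual ≥ 5 pA pass: events measuring
between 5 and 7 pA must additionally show a 20–80% rise faster than 3 ms
and a half-decay no faster than their rise. This shape criterion is a
stand-in for human curation, whose actual criteria are unrecorded; both
thresholds and the shape gate are configurable.

Known limitation: events arriving 1–5 ms after a large fast-decaying
predecessor can lose several pA of measured amplitude to the ongoing decay
and fall below threshold. At 3 Hz this costs ~1–2% of events, so frequency
estimates carry a small negative bias that is visible only because the
simulation's between-cell variance is pure counting noise.

## Decay metric

The decay of each event is summarized over the 30–70% of-peak band. The
post-peak segment is smoothed with a short (0.35 ms) centered boxcar with
edge padding — a boxcar average of an exponential is the same exponential
up to a constant, so the smoothing stabilizes the threshold crossings
without touching the time constant. The 70% and 30% crossings are located
with linear interpolation (the event's measured amplitude is the peak
reference), and a monoexponential A·e^(−t/τ) is least-squares fitted to
the smoothed samples between them (log-linear initialization, then
nonlinear refinement). Noise-free monoexponentials are recovered exactly;
with 1.4 pA noise on 15 pA events the estimator's bias is ≤ ~7% at
τ = 2 ms and ~5% at 8 ms. An alternative metric — the 70→30% transit time,
equal to τ·ln(7/3) for an exponential — is available behind the same
interface. Events whose decay never reaches 30% of peak before the next
onset are flagged unmeasurable and excluded (logged).

## Multimodality test

The test behind "the per-cell decay distribution is multimodal" is a
likelihood-ratio comparison of two- versus one-component Gaussian mixtures
with a parametric-bootstrap null. The statistic is invariant to location
and scale, so its null distribution under a Gaussian depends only on the
sample size; the package caches one bootstrap table per n (199 draws,
fixed internal seeds), making the test exact-by-construction up to
bootstrap resolution and cheap across many cells. Design rationale: the
multimodality test used on the original recordings is unnamed; among
candidates, the mixture LRT is fully specified, calibrated by construction,
and fast. It is configurable (`n_boot`), requires ≥ 30 events, and at
n = 300 rejects a 2-vs-8 ms mixture essentially always while holding near
the nominal 5% size on unimodal data.

## Histogram, Akima spline and critical value

Per-cell decay histograms use Freedman–Diaconis binning widened to at least
10 bins: on a wide bimodal distribution the FD rule alone can be too coarse
to resolve the fast mode. Spline nodes are (bin center, count) pairs.
The interpolant is Akima's 1970 piecewise cubic (scipy's implementation);
an independent brute-force implementation of Akima's slope-weighting
formulas lives in the test suite and agrees with the package spline and its
derivative to < 1e−9, which is the dual-route guarantee that the critical
value is computed on the intended curve.

Modes are the two tallest local maxima of the spline (dense-grid scan,
minimum separation two bin widths, ties broken toward the wider pair). The
critical value is the zero of the spline's first derivative strictly
between the modes at which the spline is lowest: sign changes are bracketed
on a 10×-oversampled grid and refined by bisection to 1e−6 ms. A perfectly
symmetric two-mode histogram yields the exact midpoint. If the derivative
never changes sign between modes the cell is flagged non-separable rather
than forced. Events split at the critical value (decay < τ\* → Type 1);
per-type frequencies are computed over the same analyzed duration as the
parent summary, so the partition conserves total frequency.

## Image simulation and synapse counting

Puncta are rendered as 2-D Gaussians on a flat offset: bassoon/homer
σ = 3 px with amplitudes that give thresholded areas ≈ 0.05 µm² (inside the
0.02–5 µm² bounds), VGLUT1 terminals σ = 8 px, VGLUT2 sensory terminals
σ = 12 px and ~2.5× punctum brightness. Paired homer puncta are placed 3 px
from their bassoon partner (guaranteed ≥ 1 px mask overlap); every VGLUT
terminal carries one bassoon punctum; all other objects are placed by
rejection sampling with class-dependent exclusion radii so no accidental
colocalizations arise (exceeding the retry budget raises an error).
Somatic VGLUT2 background is smooth, dim (default 150 intensity against a
1000-unit positivity cutoff) and carries single-pixel hot speckles under
dedicated bassoon puncta — the feature the median blur exists to remove.
Per-pixel noise is Gaussian (default) or Poisson.

Counting follows the particle-analysis conventions: 4-connected components
above the channel's minimum intensity, area bounds applied in µm² via the
pixel size (uncalibrated images are rejected), bassoon∩homer counted per
bassoon punctum at most once, VGLUT positivity as ≥ 1 pixel at the upper
("maximum") intensity threshold, VGLUT2 median-blurred first (disk radius
2 px, a package default; the radius used originally is unrecorded). On
simulator defaults (200 planted colocalizations of each type) all three
counts are recovered exactly, and disabling the blur inflates the
VGLUT2+bassoon count by exactly the planted speckle contingent.

## Statistics layer

Normality is checked with the D'Agostino–Pearson omnibus K² (n ≥ 8) and
heteroscedasticity with a Spearman rank correlation between |residual| and
fitted value — the natural reading of the "Spearman test for equal
variances", which is named but not defined in common software manuals.
Frequency measures get the conditional transform: if any value in the full
dataset is ≤ 1.0 Hz, add 1.0 to every value, then log10 (the rule is
evaluated dataset-wide, not per group, to keep the transform uniform).
The factorial ANOVA uses Type III sums of squares with sum-to-zero
contrasts (Prism's behavior; Type II is available), requires every cell
n ≥ 2, and flags zero-residual-variance designs as degenerate. Pairwise
genotype contrasts at each age use t statistics on the pooled residual mean
square with its degrees of freedom, Sidak-adjusted with m = number of ages;
a one-way variant across the six groups is provided for the analyses that
were reported that way. Geometric means and their 95% t-intervals are
always computed on the raw (untransformed) values. Calibration measured by
the acceptance suite: genotype type-I error 5.5% over 1000 null
simulations, geometric-mean CI coverage 95.3% over 1000 draws.

## Pipeline and reproducibility

`ExperimentConfig` (YAML-serializable) fixes the cohort design, all
generator parameters, thresholds and a master seed. Per-cell and per-image
seeds are spawned as `SeedSequence([master, genotype_idx, age_idx,
mouse_idx])`, so adding a group never perturbs existing groups' data.
Every output table carries the config hash and master seed in header
comments; identical config + seed reproduces tables byte-for-byte. The
planted cohort effect (Type 1 rate halved in the second genotype at 4W and
8W, VGLUT2 terminal count reduced likewise in the imaging arm) mirrors the
input-specific deficit the analysis is designed to resolve.

Problem sizes in the test and acceptance suites (e.g. 120 s recordings,
100 replicate seeds for rate recovery, 100 simulated cells for the
bimodal-separation rates, 1000 null ANOVA replicates) are the package's
standing validation conditions; they were chosen to give Monte-Carlo errors
well below the tolerances being checked.

## Known limitations

* The manual-curation stand-in is a heuristic; real curation decisions are
  not recoverable from any record.
* The 1 kHz zero-phase filter broadens τ = 2 ms decays by ~8–10%; the
  bimodal separation is insensitive to this (both modes shift slightly),
  but absolute decay constants from the full pipeline inherit it.
* Frequency estimates under-count by ~1–2% at 3 Hz due to events riding on
  a fast predecessor's decay — visible only because simulated between-cell
  variance is pure counting noise.
* Mixture-model (EM) decomposition, > 2 decay modes, 3-D segmentation and
  intensity-based synapse strength are out of scope.
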