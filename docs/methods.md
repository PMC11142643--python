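# Methods

This note documents the quantification procedures larvaquant implements,
the assumptions behind them, the design of the synthetic-data generators
used to exercise them, and the numerical choices that make runs
reproducible.

## Calcium-trace quantification

**ΔF/F.** Each ROI's trace F_i (mean fluorescence over the ROI's pixels at
frame i) is normalized over the whole recording as

    ΔF/F = (F_i − F_min) / (F_max − F_min),

where F_min and F_max are the global extrema of the non-missing values.
The result is a dimensionless fraction in [0, 1] that attains both bounds;
percent ΔF/F is 100× that and is used only for display. This global
min–max normalization is deliberately simple: no running-percentile
baseline, no bleach correction, no smoothing. A constant trace has no
dynamic range and is rejected as degenerate rather than silently mapped.

**Evoked-response ratio.** For optogenetic sessions, F_post is the
trapezoid area under the curve over the first 15 non-missing frames at or
after stimulation onset and F_pre over the last 15 non-missing frames
before it (5.8 s windows at 2.6 Hz); the response measure is F_post/F_pre.
Because the ratio compares two identically shaped windows, it is computed
on whatever values the caller supplies; applying it after min–max
normalization compresses the baseline toward zero and inflates the ratio,
so raw traces are the intended input. Frames flagged missing — the
laser-switch latency gaps — are skipped before the windows are formed, and
the retained frames of each window are integrated on a unit-spaced
abscissa so both windows have identical support. F_pre = 0 raises an
undefined-ratio error.

**AUC.** Elsewhere the trapezoid abscissa is the frame index, with missing
frames bridged by joining their non-missing neighbours. Ratios of AUCs are
unit-free, so the abscissa choice cancels; it is fixed for
reproducibility.

**Peaks.** Calcium events are local maxima of the normalized trace with
topographic prominence ≥ 0.3 (i.e. 30 %ΔF/F, since peak finding operates
on the min–max-normalized trace) and width at half prominence ≥ 10 frames.
These mirror MATLAB `findpeaks` semantics (`MinPeakProminence`,
`MinPeakWidth` with the default half-prominence width reference);
internally scipy's `find_peaks` provides the machinery, and the test suite
checks it against an independent exhaustive local-maxima + textbook
prominence oracle. Plateau ties resolve to the leftmost sample of the
plateau, deterministically. Onset detection uses the same machinery with a
laxer prominence of 0.2 and reports the first qualifying peak; the two
thresholds are kept separate because event counting and onset detection
are calibrated differently.

**Response duration.** The baseline is the mean ΔF/F over the 100 frames
immediately before the shock (≈19.2 s at 5.2 Hz). The duration is the time
from the shock to the first frame whose value is ≤ that baseline, with no
smoothing. A trace that never returns is right-censored at the end of the
recording and flagged, not dropped. A tolerance of 1e−12 (relative to the
baseline magnitude) absorbs summation rounding in the mean so a trace
sitting exactly at baseline reads as returned. Note the comparison starts
at the shock frame itself: a response that has not yet risen at that frame
can terminate the duration immediately, which compresses durations for
noisy traces; this is the literal reading of the definition and is kept.

**Amplitude histograms.** Pooled per-frame ΔF/F values within an epoch are
binned over [0, 1] (final bin right-inclusive). An alternative mode bins
the ΔF/F values at detected peak frames instead; the per-frame mode is the
default.

## Locomotor quantification

**Distance.** Per-frame displacement is the Euclidean step
D_i = √((x_{i+1}−x_i)² + (y_{i+1}−y_i)²); epoch distances sum the steps
between consecutive frames inside the half-open epoch. Standard epochs:
baseline = first 115 s, pre-shock = 5 s before the shock frame, post-shock
= 5 s after.

**Movement phases.** Displacements are binned into whole seconds (integer
fps required; the trailing partial second is dropped) and a second counts
as movement when its summed displacement exceeds ε (default 0 cm — any
positive displacement; configurable to absorb centroid jitter). Phases are
maximal runs of movement seconds, so sub-second pauses never break a phase
and phases are separated by at least one immobile second. Reported
statistics are the phase count and mean integer duration.

**Turning.** At each trajectory vertex (consecutive frame triple, starting
with the second frame), the law-of-cosines angle
C = arccos((a² + b² − c²) / 2ab) is computed with the cosine argument
clamped to [−1, 1]; a and b are the flanking displacements, c the chord. A
vertex contributes when the larva is active there, i.e. both flanking
displacements exceed ε. Total turning over an epoch is divided by the
total distance of the whole epoch. Two modes exist because the literal
angle is 180° for straight swimming: `interior_angle` (default, the
literal formula, where more turning means smaller summed angle per
distance) and `heading_change` (180° − C, zero for straight swimming).
The literal formula is the default; the complement is provided because
either could be the intended report.

## Group statistics

Shapiro–Wilk on every group (n ≥ 3, nonzero variance) gates the family: if
any group rejects normality at α = 0.05 the comparison is nonparametric.
Two groups: two-sided Student's t (pooled variance; Welch by flag) or
Wilcoxon rank-sum (exact for small tie-free samples, continuity-corrected
normal approximation otherwise). Three or more groups: tie-corrected
Kruskal–Wallis, with the all-values-tied degenerate case reported as H = 0,
p = 1 by convention, followed by Dunn's z-based all-pairs post-hoc computed
directly from rank arithmetic with the pooled tie correction. The
multiplicity adjustment defaults to Holm (conservative, standard in
rank-based post-hoc packages) and can be set to Bonferroni or
Benjamini–Hochberg. Summaries are mean ± SEM (sample SD, n−1 denominator,
over √n; SEM absent for n = 1). Pre/post epochs are treated as separate
groups in the omnibus rather than as paired contrasts.

## Synthetic-data generators

The generators define the study conditions the tests run under; all take
explicit seeds and emit ground-truth logs consistent with their output by
construction.

**Calcium sessions** (5.2 Hz, 2000 frames ≈ 385 s, shock at frame 600).
Each neuron's trace is a baseline level plus spontaneous transients,
an evoked transient at the shock, an optional slow sinusoid, and white
Gaussian noise. The transient kernel is the standard GCaMP-like
difference of exponentials (1 − e^(−t/τ_rise)) e^(−t/τ_decay), scaled to
unit peak. Defaults: τ_rise = 1 s, τ_decay = 5 s — deliberately slow,
nuclear-indicator-like kinetics chosen so a transient's half-prominence
width (~25 frames clean) clears the 10-frame width criterion with margin
even at 20% noise; with a 3-s decay the measured width of a noisy
transient hovers at the criterion and detection becomes threshold-limited
rather than event-limited. Spontaneous events are Poisson in number
(rate in events/min) and placed uniformly subject to a 12-s refractory
separation (about four decay constants), implemented as an exact
constrained-uniform draw with an end margin so every programmed transient
has room to rise to a measurable peak. The refractory spacing makes
"programmed suprathreshold events" a meaningful ground truth: without it,
transients stacked within a couple of decay constants merge under the
prominence criterion and no detector could count them.

Two archetypes: `quiet_sustained` (0.5 events/min, evoked decay 20 s, no
oscillation) and `oscillatory_brief` (1.5 events/min, evoked decay 4 s,
plus a 30-s-period sinusoid of amplitude 20 a.u. with random phase, whose
crests are recurring suprathreshold fluctuations). Amplitudes default to
30 a.u. for spontaneous events and 50 a.u. for the evoked response on a
100 a.u. baseline with 2 a.u. noise. These values are calibrated only to
reproduce the qualitative contrast between the two populations — the
oscillatory archetype shows roughly 3× more detected peaks and a several-
fold shorter shock response — not any particular published mean.

**Optogenetic sessions** (2.6 Hz): 200 baseline frames, 20 stimulation
frames at gain × baseline mean, 150 recovery frames (370 frames = 142.3 s);
the two switch-boundary frames are marked missing by default.

**Trajectories** (60 fps, 6-cm arena with reflecting walls). Movement is
laid out per second by an alternating-renewal process: phase lengths are
Poisson around the profile mean (≥1 s), gaps are the 1-s minimum plus a
Poisson remainder whose mean makes the expected phase count per 115 s
match the profile. Within a movement second the larva advances at the
profile speed with per-frame Gaussian heading jitter; immobile seconds
hold the position exactly, so ε = 0 segmentation recovers programmed
layouts exactly. Wall handling folds the unbounded path into the arena
(mirror reflection); steps that cross a wall shorten slightly at the fold,
which is immaterial at the default speeds. Profiles: `control`
(7.74 phases/115 s of mean 7.35 s at 0.35 cm/s, 20°/frame jitter),
`ablated_rln3a_NI` (same phase count, 10.38-s phases, 0.53 cm/s,
35°/frame — longer phases and more distance without more phases), and
`post_shock` (control plus a forced 5-s hyperactive epoch at 1.2 cm/s
after the stimulus). Speeds were chosen so baseline distances land near
20 cm (control) and 43 cm (ablated) per 115 s.

**Image stacks.** Each neuron is a unit-peak Gaussian blob scaled by its
trace value on a constant background with white noise, clipped at zero;
ground-truth ROIs are discs of radius 2σ. This is plumbing for testing ROI
extraction, not an optics model.

**What the generators do not emulate:** motion artifacts, bleaching,
neuropil contamination, indicator saturation, correlated (pink) noise,
body shape or tail kinematics, wall thigmotaxis, and inter-individual
variability beyond the sampling noise of the renewal/Poisson processes.
Passing tests therefore demonstrate that the quantification recovers known
structure under the stated noise model, not that it is robust to every
artifact of real recordings.

## ROI extraction

The reference image is the per-pixel maximum-intensity projection of the
series. Polygon ROIs (0-based row/col vertices) rasterize by an even-odd
pixel-center test with boundary pixels included — a deterministic stand-in
for interactive tools whose inclusion rule is unspecified. Traces are the
arithmetic mean of stack intensities over the mask per frame. No
registration, background subtraction, or neuropil correction is applied.

## Numerical and design choices

- Frame indexing is 0-based everywhere; epochs are half-open
  [start, end).
- Framewise SD bands across ROIs use the population convention (ddof 0)
  so a single trace yields a zero-width band; group SEMs use sample SD
  (ddof 1).
- The cosine argument in the turning angle is clamped to [−1, 1] before
  arccos; collinear and backtracking triples are exact.
- Reported session durations round frame/rate quotients to one decimal;
  the library functions return unrounded values.
- Seeds are mandatory in generator specs and pipeline configs; per-larva
  seeds derive from the run seed via `numpy.random.SeedSequence.spawn`,
  reduced mod 2³¹.
- CSV floats serialize with 12 significant digits; trace and trajectory
  files carry their acquisition rate in `#`-prefixed header comments.
- Problem sizes in the test and acceptance runs — cohorts of ~10 larvae ×
  6 neurons, 2000-frame sessions, 120-s trajectories at 60 fps, 15–20
  seeds for stochastic checks — were chosen as the smallest sizes at which
  the cohort contrasts are stable across seeds.

## Known limitations

- The evoked-response duration starts its search at the shock frame, so
  pre-rise noise can truncate it (see above); a variant that searches from
  the response peak would be less literal but more robust.
- The `interior_angle` turning default means larger values indicate
  *less* turning; users comparing across studies should check which
  convention a given report uses (both are provided).
- The Wilcoxon rank-sum implementation follows scipy's exact/asymptotic
  switching; exact p-values for large tied samples are not attempted.
- The generators' archetype and profile calibrations target direction and
  rough magnitude of group contrasts, not distributional realism of any
  particular dataset.
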