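# larvaquant

Quantification of larval-zebrafish neural-activity recordings and swim
behaviour: calcium-imaging trace metrics (ΔF/F, evoked-response AUC
ratios, peak counts, response durations), locomotor trajectory metrics
(epoch distances, movement-phase segmentation, turning-per-distance), and
the normality-gated group statistics used to compare experimental cohorts
— together with seeded synthetic-data generators that emulate the
recordings with known ground truth.

It is written for systems-neuroscience labs analysing confocal calcium
imaging of small neuronal populations (e.g. hindbrain nucleus-incertus
neurons) and high-frame-rate tracking of freely swimming larvae, and for
anyone who wants those quantifications as a tested, reproducible library
rather than a pile of one-off scripts.

## The quantities it computes

**ΔF/F** for a ROI trace F_i is the global min–max normalization
`(F_i − F_min)/(F_max − F_min)`, a fraction in [0, 1]. Calcium events are
local maxima with topographic prominence ≥ 0.3 and half-prominence width
≥ 10 frames (MATLAB `findpeaks` semantics). The evoked response to an
optogenetic stimulus is quantified as **F_post/F_pre**, the ratio of
trapezoid AUCs over 15-frame windows after vs before stimulation onset
(5.8 s at 2.6 Hz). The **response duration** after a shock is the time for
ΔF/F to return to or below the mean of the 100 pre-shock frames.

For 60-fps trajectories, distance is the summed Euclidean step
`D_i = √((x_{i+1}−x_i)² + (y_{i+1}−y_i)²)`; **movement phases** are
maximal runs of whole seconds containing movement (so phases are separated
by ≥ 1 s of immobility); **turning per distance** sums the law-of-cosines
angle `C = arccos((a²+b²−c²)/2ab)` at each active trajectory vertex and
divides by path length.

Group comparisons are gated by Shapiro–Wilk normality: two-sample
t / Wilcoxon rank-sum for two groups, tie-corrected Kruskal–Wallis with
Dunn's all-pairs post-hoc (Holm-adjusted) for three or more; all summaries
are mean ± SEM.

See `docs/methods.md` for assumptions, parameter defaults, and the design
of the synthetic generators.

## Worked example

Simulate optogenetically stimulated (gain 3) and unstimulated cohorts of
ten sessions each, quantify F_post/F_pre per larva, and compare the
groups:

```sh
$ larvaquant pipeline --paradigm reachr --seed 5 --out runs/reachr
[post_pre_ratio]
Two-sample t-test: statistic=-320, p=3e-35
data structure: normal
  reachr_neg: 1.003 +/- 0.001733 (n=10)
  reachr_pos: 3.001 +/- 0.005997 (n=10)
```

The unstimulated cohort's AUC ratio is 1 (no evoked change), the
stimulated cohort recovers the programmed 3× activation, and the
Shapiro–Wilk gate selects the parametric test, which reports the group
difference. The output directory contains `metrics.csv` (one row per
larva and metric), `stats.csv` and `posthoc.csv` (the comparison tables),
and `provenance.json` (resolved config, seed, config hash) sufficient to
regenerate the run.

The same pattern works from Python:

```python
from larvaquant import (SyntheticCalciumSpec, generate_calcium_traces,
                        normalize_dff, detect_peaks)

spec = SyntheticCalciumSpec(archetype="oscillatory_brief", seed=1)
traces, truth = generate_calcium_traces(spec)
peaks = detect_peaks(normalize_dff(traces[0]))
print(peaks.count)          # 11 suprathreshold events in this session
```

Other subcommands: `simulate` (emit synthetic CSV/TIFF inputs with ground
truth), `extract` (TIFF stack + polygon-ROI JSON → trace CSV), `calcium`
and `locomotion` (metric tables from trace/trajectory CSVs), `stats`
(group comparison on a metric table). Every threshold (`--prominence`,
`--min-width`, `--window`, `--baseline-frames`, `--epsilon`) is a flag.

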