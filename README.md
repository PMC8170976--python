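# gutmotion

Analysis toolkit for **gut-first Parkinson phenotyping**: quantifying
gastrointestinal motility from ex vivo video recordings of intact gut
segments, together with the molecular readouts (miRNA counts, proteomics,
immunofluorescence) used to characterise the enteric nervous system of
pre-symptomatic α-synuclein-overexpressing mice against wild-type controls.
It is written for physiologists and molecular biologists who have diameter
traces or organ-bath videos, hybridisation count matrices, protein intensity
tables, or stained sections — and who want the whole chain from raw signal to
starred group comparison to be scripted, seeded and testable.

## What it computes

**Spatiotemporal motility mapping.** A recording of a ~2 cm segment is
reduced to a diameter matrix *D(x, t)* (30 loci along the segment, 25
frames/s) either from a trace file or by tracking the tube's upper and lower
edge in the video (`track_edges`). A per-locus moving median *B(x, t)*
absorbs slow whole-organ movement, leaving the signed amplitude

    A(x, t) = D(x, t) − B(x, t)        (dilatation > 0, contraction < 0)

optionally normalised to each locus' initial diameter, and rendered as the
familiar diverging-colour heatmap.

**Contraction cycles.** Contraction onsets are leading-edge zero crossings
of *A*, gated by a Schmitt trigger with hysteresis band *h* (default
0.075 mm, inside the 0.05–0.1 mm range used on real recordings): an onset is
registered only when the signal, having been above *+h/2*, falls below
*−h/2*; the onset time is the interpolated zero crossing in between. From the
cycles come the three endpoints:

* contraction rate — median onset count over loci, per min or per 10 min;
* mean interval — mean full-cycle duration per locus, then averaged over loci;
* wave velocity — onsets chained across adjacent loci, onset time regressed
  on position, velocity = 1/slope (mm/s, aboral positive; synchronous
  contractions are flagged, not given a number).

**Omics.** miRNA counts are normalised so the geometric mean of the
housekeeping genes (Actb, B2m, Gapdh, Rpl19) is equal across samples,
filtered at a mean of ≥ 100 counts, and tested per feature with a two-sided
Student's t on log2(count + 1); protein intensity tables go through the same
two-group machinery. Volcano tables/plots, set-overlap (Venn) counts,
integer-rounded significant proportions, and counter-regulation pairing
(significantly **up** miRNA × significantly **down** target protein, against
a user-supplied target map) are built on top.

**Image quantification.** Otsu (or fixed-threshold) binarisation with
percent-positive area per section or within a mask (e.g. marker area per
Tuj1-positive ganglionic area), connected-component cell counts, live/dead
tallies (double-positive pixels count as dead), marker/PGP9.5 ratios and
percent reductions.

**Group statistics.** Shapiro–Wilk normality screen (recorded, never
silently switching the test), two-sided equal-variance Student's t with
Cohen's d

    d = (m₁ − m₂) / s_pooled,   s_pooled² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2)

two-way ANOVA, and cohort endpoint tables with the p ≤ 0.05 (*), ≤ 0.01 (**),
≤ 0.001 (***) star convention.

**Synthetic data.** Every stage has a seeded generator with known ground
truth: propagating biphasic contraction waves with drift and noise, rendered
video stacks, spiked count matrices with stable housekeeping features, and
fluorescence images with exact positive area and countable objects. These
drive the test suite end to end; no study data are required.

## Worked example

```python
import gutmotion as gm

params = gm.WaveParams(frequency=40, amplitude=0.4, velocity=15,
                       drift_amplitude=0.5, noise_sd=0.02, duration=60, seed=1)
trace  = gm.simulate_trace(params)                      # 30 loci x 1500 frames
stmap  = gm.normalize(gm.baseline_correct(trace, window_s=20))
print(gm.summarize(stmap, hysteresis_mm=0.075, window="per_min").to_dict())
```

```
{'contraction_rate': 40.0,
 'mean_interval_s': 1.5011421776476714,
 'velocity_mm_s': 15.01518649011545,
 'n_waves_used': 40,
 'reporting_window': 'per_min',
 'hysteresis_mm': 0.075}
```

The generator ran at 40 contractions/min, 0.4 mm deep, travelling aborally at
15 mm/s under 0.5 mm slow drift and 0.02 mm frame noise; the pipeline
recovers the rate exactly and the interval (1.5 s) and velocity within a
fraction of a percent. A two-group cohort comparison:

```python
import pandas as pd

wt   = gm.WaveParams(frequency=40, velocity=15, noise_sd=0.02)
case = gm.WaveParams(frequency=34, velocity=9,  noise_sd=0.02)
rows = []
for m in gm.simulate_cohort(wt, case, n_wt=6, n_case=7, seed=2):
    s = gm.summarize(gm.baseline_correct(m.trace, window_s=20))
    rows.append({"group": m.group, "rate": s.contraction_rate,
                 "velocity": s.velocity_mm_s})
print(gm.compare_cohorts(pd.DataFrame(rows)).round(3))
```

```
          n_WT  n_case  mean_WT  mean_case  sd_WT  sd_case  t_statistic  p_value  cohens_d stars
endpoint
rate         6       7   38.583     34.286  2.333    1.113        4.353    0.001     2.422    **
velocity     6       7   14.910      8.784  1.019    0.697       12.827    0.000     7.136   ***
```

The case group was simulated 15% slower and with 40% lower wave velocity;
both endpoints come out significantly reduced, with the velocity deficit the
stronger effect — the same direction of change the motility assay shows in
the pre-symptomatic mice.

The same flows are scriptable from a shell:

```bash
gutmotion simulate trace --seed 1 --out trace.tsv
gutmotion map --input trace.tsv --out-prefix run1
gutmotion metrics --map run1 --hysteresis-mm 0.075 --window per_min --out summary.json
gutmotion simulate counts --seed 3 --out counts.tsv
gutmotion omics de --counts counts.tsv --groups counts.groups.tsv --out de.tsv
```

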