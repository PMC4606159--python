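# neuroaging

Quantification pipeline for mouse normal-aging phenotyping studies.

Aging studies in mice combine three very different kinds of raw data: DAB
immunostained brain sections (GFAP for astrocytes, CD68 for microglia, c-Fos
for recent neuronal activity), behavioral session logs (shuttle-box active
avoidance, fear-conditioning motion traces, acoustic startle, Barnes maze,
open-field locomotion), and hippocampal slice field recordings (fEPSPs).
`neuroaging` implements the quantification layer that turns each of these into
the scalar endpoints reported in such studies, together with a synthetic-data
module that generates ground-truthed stand-ins for every input family, so the
whole pipeline is testable without any raw images, videos, or sweeps.

## What it computes

**IHC morphometry** (`neuroaging.ihc`) — inside a manually drawn ROI (DG,
HPF, isocortex), a fixed intensity threshold selects dark stained pixels;
8-connected components above a marker-specific cutoff (135 µm² for clustered
GFAP, 13 µm² for enlarged CD68, 7 µm² for c-Fos nuclei) become stained
objects. Per ROI: percent positive area, density (objects/mm²), mean object
size (mm²) and the shape factor

&nbsp;&nbsp;&nbsp;&nbsp;*SF* = 4π·*A* / *P*²,

which is 1 for a perfect circle and approaches 0 for a thin line. Touching
c-Fos nuclei are split by marker-controlled watershed on the distance
transform before counting. Section values are averaged over the 3–4 sections
per animal.

**Behavior** (`neuroaging.behavior`) — avoidance/escape/failure percentages
in blocks of 20 trials (their sum is exactly 100 per block); the learning
slope as the OLS fit of % avoidance per block of 5 trials on block index;
freezing as the percentage of 0.5 s observation intervals whose motion index
stays below 20 (artificial units) throughout; shock reactivity from 2 s
motion bins around the shock; startle amplitude as the mean of 65 per-ms
accelerometer readings and its regression slope on stimulus intensity (dB
above background, no-stimulus trials excluded); Barnes probe target-hole
preference (target bouts minus mean of the 19 nontarget holes); percent
center beam breaks in the open field.

**Electrophysiology** (`neuroaging.ephys`) — fEPSP initial slope as a linear
fit over the 20–80% span of the negative-going rise after artifact blanking;
input–output curves over logarithmically increasing stimulation intensity;
paired-pulse ratios (p2/p1 of slopes) over the doubling ISI ladder
25→1600 ms; baseline-normalized LTP time courses around theta-burst
stimulation (5 pulses at 100 Hz × 10 bursts at 200 ms intervals per bout).

**Statistics** (`neuroaging.stats`) — mixed-design/between-subjects ANOVA
with Tukey HSD, Pearson r/r²/p, Kaplan–Meier morbidity curves with the
generalized Wilcoxon (Gehan–Breslow) χ², and the box-plot convention
(quartile box, whiskers at the outermost points within 1.5 IQR).

## Worked example

```python
import numpy as np
from neuroaging import synthetic as syn, ihc, behavior as bhv

# a ground-truthed stained-section phantom: 12 dark ellipses, 0.5 um/px
rng = np.random.default_rng(7)
objs = syn.nonoverlapping_objects(12, (512, 512), (14, 20), rng)
spec = syn.SectionPhantomSpec(image_shape=(512, 512), pixel_size=0.5,
                              objects=objs, noise_sd=3.0, seed=7)
img, truth = syn.generate_section(spec)

roi = ihc.ROIMask(np.ones((512, 512), bool), "HPF")
mask = ihc.threshold_dark(img, roi, threshold=140)
table = ihc.label_and_filter(mask, 0.5, min_area=ihc.MIN_AREA_UM2["GFAP"])
res = ihc.quantify_region(table, roi, 0.5, stain="GFAP")
print(res.n_objects, res.percent_positive_area)
```

prints `n_objects=12` and `percent_positive_area=4.043%` against a
ground-truth analytic coverage of 4.037% — all 12 objects recovered and the
stained-area percentage within 0.2% relative of the constructed truth
(`density=183.1/mm^2`, `mean_shape_factor=0.982`).

```python
trials = syn.generate_aa_session(
    syn.AASessionSpec(p_avoid_start=0.05, p_avoid_end=0.75, seed=7))
for b in bhv.block_percentages(trials):
    print(b.block, b.pct_avoid, b.pct_escape, b.pct_failure)
print(bhv.avoidance_slope(trials))
```

prints five blocks of 20 trials rising from `avoid 5%` to `avoid 80%`
(each block summing to 100%) and a learning slope of
`3.85 % avoidance per block of 5 (r^2 = 0.52)` — the rate at which this
simulated animal acquires the avoidance response.

A thin CLI mirrors the library: `neuroaging simulate section|aa|startle|
motion|sweep`, `neuroaging quantify ihc`, `neuroaging analyze
aa|fc|startle|barnes|openfield|ephys`, and `neuroaging stats
anova|tukey|pearson|km|boxplot`. Run any subcommand with `--help`.

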