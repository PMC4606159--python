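# Methods

This note documents the models, estimators, defaults, and design choices in
`neuroaging`, in the order the pipeline runs them.

## Stained-section phantoms and morphometry

The synthetic section model is a light, noisy background (default intensity
200 on the 8-bit scale, Gaussian noise SD 3) with dark elliptical objects
(default stain intensity 80), emulating DAB chromogen on unstained tissue.
Stain polarity is therefore dark-on-light, and all threshold operators select
*low* intensities. Ellipses are rasterized with sub-pixel area coverage
(4×4 sub-samples per pixel, sequential alpha compositing), so measured pixel
areas converge to the analytic ellipse area πab as object size grows; the
ground-truth table carries the analytic area, the Ramanujan perimeter
approximation (exact for circles), the centroid, and the class label. This
anti-aliased construction is what makes convergence and recovery tests
meaningful: a thresholded disc's pixel count approaches πr² because the edge
is cut near the 50%-coverage contour.

The intensity threshold is a fixed configuration value applied consistently
across all images of a study. Its default (140) was calibrated on phantoms:
with background ≈ 200 and stain 60–100, 140 cuts the one-pixel anti-aliased
edge near 50% coverage, making thresholded areas track analytic areas. Real
studies must calibrate this value once on their own material and then freeze
it.

Size cutoffs are marker-specific and applied to final labeled objects:
135 µm² (clustered GFAP), 13 µm² (enlarged CD68), 7 µm² (c-Fos nuclei,
removing noncellular speckles). Components are 8-connected. Whether such
cutoffs precede or follow morphological clean-up is a genuine dialect
question; here they are applied last, to the objects that are counted.

**Perimeter estimator.** Object perimeters use the Crofton (4-direction)
estimator rather than pixel-edge counting. Pixel-edge perimeters of a
digitized disc overestimate by ~11%, biasing the circle's shape factor
4πA/P² to ≈ 0.9; the Crofton estimator keeps rasterized discs of radius
≥ 10 px within ~1% of the ideal value 1, preserving the defining property
that a perfect circle scores 1 and a thin line scores ≈ 0. Shape factors of
small rasterized convex objects can exceed 1 by a discretization epsilon
that shrinks with resolution.

**c-Fos counting.** The nucleus counter thresholds, fills holes, opens with
a 1-pixel-radius disk (the exact post-watershed morphological clean-up is a
free choice; the radius is exposed as config), computes the Euclidean
distance transform, places watershed markers at distance-transform maxima
separated by at least one expected nucleus radius (default 3 µm, config;
markers closer than the floor are merged), and splits touching nuclei by
marker-controlled watershed before the 7 µm² exclusion. Objects clipped by
the ROI boundary are retained as clipped; no border exclusion is applied.
RGB input images are collapsed to a single luminance channel before
thresholding (DAB is dark in all channels); grayscale passes through.

Per-animal aggregation is the unweighted mean over the 3–4 sections.
Sections with no surviving object contribute their zero percentage and zero
density but are skipped in the size and shape-factor means — mirroring the
convention of keeping an animal without detectable clusters in the density
analysis while excluding it from size/shape averages.

## Behavioral generators and endpoints

**Active avoidance.** A session is 100 trials. The generative learning curve
interpolates the per-trial avoidance probability from `p_avoid_start`
(default 0.05) to `p_avoid_end` (default 0.75), linearly or along a logistic
ramp; non-avoided trials become escape failures with probability `p_failure`
(default 0.05) and escapes otherwise. ITIs are uniform on [25, 55] s (mean
40 s, the protocol's range). Latency distributions are a synthetic-only
modeling choice — uniform U(0, 5) s for avoidances (the cue window) and
cue + 5 s + U(0, 2) s for escapes (the shock window) — since only outcome
classes and their windows are defined by the task; ties at exactly the 2 s
escape/failure boundary are resolved as escapes.

Analysis reports outcome percentages in blocks of 20 consecutive trials and
the learning slope as ordinary least squares of % avoidance per block of 5
on block index 1..k. Block indexing from 1 only shifts the intercept, never
the slope. Partial final blocks (N not divisible by the block size) are
reported with a flag but excluded from slope fits (unequal variance). The
failure percentage is computed as `100 − (pct_avoid + pct_escape)`, which
makes the per-block closure identity hold *exactly* in floating point for
any block size, including partial blocks.

**Fear conditioning.** The motion index lives on the tracker's 0.5 s
observation-interval grid; an interval registers freezing iff its index
stays below the motion threshold (default 20, artificial units) throughout
the interval, and the freezing percentage is frozen intervals over total
intervals within a phase. The tracker's 0.1 s observation duration is
treated as the sensor's integration window — a property of the input, not
an analysis step — so the whole-interval rule is the implemented dialect;
whether the original evaluation slid within the interval is not recoverable
and is flagged as such. The generator emits one index per interval:
intervals wholly inside a freeze bout read `frozen_level` (default 5),
everything else `moving_level` (default 120), plus truncated Gaussian noise
(SD 1); overlapping bouts are rejected. Shock reactivity collapses the
trace to 2 s bins aligned to each shock onset: baseline is the mean of the
five preceding bins, the response is the shock bin, both averaged over the
(two) trials.

**Acoustic startle.** A session is 8 trials at each of 12
dB-above-background levels {0, 4, 8, 12, 16, 20, 24, 28, 35, 42, 49, 55}
(96 active trials) with 8 interspersed no-stimulus trials; ITIs are uniform
on [8, 22] s (mean 15 s) and are not defined for NOSTIM trials. Trial
amplitude is *defined* as the mean of the 65 one-ms accelerometer readings;
the generator shapes the readings as a half-sine envelope normalized to unit
mean so this identity is exact. The per-animal endpoint is the OLS slope of
amplitude on dB; NOSTIM trials never enter the fit. Generator amplitudes
follow max(0, intercept + slope·dB + noise) with defaults intercept 5,
slope 2, noise SD 4 (in the accelerometer's arbitrary units).

**Barnes maze and open field.** The probe endpoint is bouts at the target
hole (position 0 of 20) minus the mean over the 19 nontarget holes; the
open-field endpoint is 100·center/total beam breaks, undefined (NaN,
flagged) when no beam was broken.

## Field-potential analysis

The synthetic fEPSP is a difference of exponentials (rise τ 1 ms, decay τ
8 ms) — the exact waveform is a free choice since only the initial slope is
analyzed — preceded by a 0.4 ms biphasic stimulus artifact and a 2 ms
synaptic delay. The generator defines "slope" as the least-squares
20–80% rise slope of its kernel evaluated on a 1 MHz grid, and scales the
waveform so each pulse's slope equals `true_initial_slope × ppr_profile[k]`.
That calibration is self-contained in the generator; the analyzer recovers
the slope from the 20 kHz sampled trace by an independent route.

The slope estimator: baseline is a line fitted to the 2 ms before the
stimulus (detrending, on by default — it removes the decaying tail of a
preceding response, which otherwise biases the second pulse of a 25 ms pair
by ~2%); the response window runs from 1.5 ms after the stimulus (blanking
the artifact and keeping any fiber volley out of the fit) to the next
stimulus or 30 ms. The most negative deflection defines the amplitude;
deflections under 0.02 mV are flagged null. The 20% and 80% crossing times
are located on a lightly smoothed copy (5-sample boxcar, used only for
localization) with sub-sample interpolation, and the line is fitted to the
raw deflection interpolated onto a dense grid between the crossings —
removing the sample-discretization of the window endpoints. Whether the
original "slope" is a window fit or peak dV/dt is not recoverable; the
window fit is the implemented choice. At zero noise the estimator recovers
constructed slopes to ≲ 0.4%; single-sweep slopes at realistic noise
(0.005 mV RMS against a ~0.4 mV fEPSP) scatter by a few percent, which is
why `ppr` accepts replicate sweeps and averages the waveforms point-wise
before measuring — the standard practice.

I–O curves are (intensity, mean slope) sorted ascending, with null-measure
counts flagged. The PPR ladder is fixed at {25, 50, 100, 200, 400, 800,
1600} ms. TBS bookkeeping: 5 pulses at 100 Hz per burst, 10 bursts at 200 ms
onset intervals (50 pulses/bout), bout onsets 20 s apart. LTP time courses
divide every sweep slope by the baseline-window mean (×100, so the baseline
epoch is 100% by construction and normalization is idempotent); each
induction opens a 20 min epoch summarized by the mean over its final 5 min
(a choice — the convention reports curves, not epoch scalars); baseline
drift is flagged when the two baseline half-means differ by more than 20%.

## Statistics layer

Mixed-design ANOVA (one between-, one within-subjects factor) is the
uncorrected univariate F by default, with Greenhouse–Geisser available by
flag (no sphericity correction is the study convention). Subjects missing
any within level are dropped listwise and the count reported; denominator
degrees of freedom are reported as computed after deletion. Tukey HSD uses
the studentized-range distribution with the pooled error term. "Generalized
Wilcoxon" is implemented as Gehan–Breslow: the weighted log-rank with
weights equal to the number at risk, emphasizing early events; end-of-study
tissue collection censors. With zero events the χ² is 0 and p = 1 by
convention. Quartiles use linear interpolation (the numpy default); the
box-plot convention places whiskers at the outermost observations within
1.5 IQR beyond the quartiles and classifies everything beyond as outliers.

Implementation stands on pingouin (ANOVA), scipy (Tukey, Pearson, OLS) and
lifelines (Kaplan–Meier, weighted log-rank); the test suite checks these
routes against independent oracles — a hand-rolled risk-table Gehan χ²
accumulated event time by event time, the q = √2·|t| two-group Tukey
relation, and a 1000-simulation null calibration of the between-effect
type-I error at n = 17/group.

## Problem sizes and determinism

All generators draw from one `numpy` PCG64 generator per session/spec, so
identical spec + seed reproduces outputs bit-for-bit. The test suite uses
phantoms of 256²–512² pixels with 6–12 objects, 100-trial behavioral
sessions (100–300 replicates where a Monte-Carlo mean is compared to its
expectation oracle), 20 kHz sweeps of ≤ 0.2 s, and 1000 simulations for the
ANOVA calibration — sizes at which every distributional check sits several
Monte-Carlo standard errors inside its tolerance while the whole suite runs
in well under a minute of compute for everything but the calibration.

## Limitations

The phantoms are geometric: no staining texture, vessels, section tears,
uneven illumination, or out-of-focus blur, so passing recovery tests
demonstrates correctness of the measurement chain, not robustness to
histological artifacts — the intensity threshold in particular must be
recalibrated on real material. Behavioral generators model outcome
probabilities and window-uniform latencies, not videos or trajectories;
tracking internals (TopScan/Video-Freeze equivalents) are upstream of this
package and their outputs are its inputs. The ephys module analyzes single
extracellular sweeps with annotated stimuli; population-spike metrics,
whole-cell recordings, and slice-health QC beyond the baseline-drift flag
are out of scope. Group-level F and p values from the original animal
cohorts are not reproducible desk-side because the raw data are not
deposited; the statistics layer therefore reproduces conventions and
calibrations, not specific published values.
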