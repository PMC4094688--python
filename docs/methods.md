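# Methods

This note documents the models, numerical choices and limitations of
`lvecho`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Phantom model

The generator emulates end-systolic apical two-chamber contrast frames as a
fixed 2-D geometry (no cardiac motion — the acquisition it emulates is
ECG-triggered at one cardiac phase, so the truth mask is constant across a
sequence):

* **Cavity** — a truncated ellipse, apex at the top (transducer side). The
  generating ellipse has vertical semi-axis 0.62 of the long axis; the
  atrioventricular (AV) plane truncates it below the equator, giving a
  rounded apex and wide base. Defaults: apex at 0.06 H, long axis 0.68 H,
  basal width 0.47 W (chosen so the default phantom also fits a 128-px
  raster).
* **Atrium** — an ellipse beyond the AV plane rendered at the same
  contrast intensity as the cavity, so that intensity alone cannot separate
  the chambers and the AV constraint in the segmentation is genuinely
  load-bearing.
* **Myocardial wall** — a band of thickness 0.05 H around the blood pool at
  fixed level 0.15; background 0.05.
* **Time course** — cavity/atrium contrast follows
  f(t) = 0 → linear ramp over `washin_time` → 1 during `plateau_duration` →
  exp(−Δt/`washout_tau`). Defaults: arrival 5 s, wash-in 2 s, wash-out
  τ = 4 s, 1 frame/s.
* **Inhomogeneity** (dimensionless ≥ 0) — a linear axial gain ramp
  (gain 1 → 1 − 0.25·inhom down the long axis, floored at 0.2) times up to
  three elliptical dropouts centred on the cavity border with depth
  0.8·inhom and radius ≈ 0.12 H. Dropout count is
  min(3, ⌊2.5·inhom + 0.5⌋); three candidates are always drawn from the
  generator so random-state consumption does not depend on the level.
  Border placement mimics attenuation/swirling artifacts, which is what
  actually degrades border delineation at low dose.
* **Speckle** — i.i.d. multiplicative gamma noise with shape
  `speckle_looks` (mean 1, CV = 1/√looks); default 36 looks (CV ≈ 0.17).
  `speckle_looks=None` is the noiseless limit. This single-parameter
  surrogate reproduces the first two moments of smoothed speckle; it has no
  spatial correlation and no log-compression.

### Dose presets

| dose label  | peak intensity | inhomogeneity | plateau (s) |
|-------------|----------------|---------------|-------------|
| 1.5         | 0.45           | 0.60          | 15          |
| 3           | 0.60           | 0.45          | 16          |
| 5           | 0.75           | 0.20          | 30          |
| sonovue-1.5 | 0.80           | 0.15          | 30          |

The presets encode the qualitative in-vivo findings: the 5 ml dose behaves
like the SonoVue reference; lower doses are dimmer, less homogeneous and
fade within the first 20-s interval. The intermediate-dose plateau is 16 s
rather than a value nearer 20 s because the enhancement of that dose must
end clearly before the second 20-s interval opens: with wash-in and a
~1-frame arrival-detection lag, an 18-s plateau reaches the interval-1
boundary at full intensity and would mislabel the intermediate dose's
useful period. All preset values are configuration, not constants.

The score-table simulator draws 0/1/2 visibility scores i.i.d. from
per-(dose, region) categorical distributions; its defaults are the observed
per-region score fractions of the in-vivo study (n = 48 per region). The
physiology simulator uses porcine anesthesia baselines SaO2 98 ± 1.5 %,
HR 93 ± 14 bpm, MAP 78 ± 13 mmHg (between-animal sd) with minute-to-minute
noise 0.3 / 2.0 / 2.5 and optional relative post-injection shifts.

## Frame selection

"Highest and most homogeneous enhancement" is operationalized as
`score = mean(ROI) − λ·CV(ROI)` with λ = 0.5 — monotone in both desiderata
with one trade-off parameter. Contrast arrival is the first frame whose ROI
mean exceeds baseline + 0.2·(max − baseline), where baseline is the mean
over pre-rise frames; the definition is offset-invariant. Intervals are
contiguous 20-s windows anchored at arrival; ties in the per-window argmax
break to the earliest frame. The useful-duration label is the last
contiguous interval whose selected frame scores ≥ 0.25 (default); with the
dose presets above this threshold separates the plateau scores (≈ 0.3–0.7)
from post-washout scores (< 0.2) for all four presets.

## Segmentation

Classical geodesic active contour with interior {φ < 0}:

    φ_t = w·g·κ·|∇φ| − g·c·|∇φ| + ∇g·∇φ
    g   = 1 / (1 + (|∇(G_σ∗I)|/g₀)²),  I min-max normalized

* σ = 2 px; g₀ = 0.02 intensity-units/px (the gradient magnitude at which
  g = ½). Without the g₀ scale, realistic smoothed edges (|∇I| ≈ 0.1/px)
  leave g ≈ 0.99 and cannot oppose a balloon force.
* Balloon c = +0.4 (outward; the seed covers only ≈¼ of the cavity).
  Values ≥ 0.5 were observed to creep through speckle-weakened edge points
  over thousands of iterations; 0.4 holds the equilibrium without stalling
  growth. Curvature weight w = 1 (exposed as `curvature_weight`).
* Explicit scheme: Osher–Sethian upwind gradient for the balloon term,
  velocity-signed one-sided differences for ∇g·∇φ, central differences for
  curvature; dt = 0.25 — at the parabolic stability limit dt·w ≤ 0.25 of
  the explicit curvature term. dt = 0.45 is provably unstable here (the
  front jumps the edge capture band).
* Reinitialization every 50 iterations by Sussman relaxation
  φ_t = S(φ₀)(1 − |∇φ|), 10 sweeps. A distance-transform reinit of the
  binarized interior was rejected: it quantizes the interface to whole
  pixels, freezing any sub-pixel approach slower than 1 px per reinit
  period.
* Seed: axis-aligned ellipse (circle by default) of area
  `seed_area_fraction` (0.25) × caller-supplied expected LV area, signed
  distance via the Euclidean distance transform; seeds crossing the AV
  plane are rejected.
* AV constraint: the closed half-plane beyond the AV line not containing
  the seed centre is clamped to φ = +5 after every update (`av_mode="clamp"`,
  default). The alternative `av_mode="edge"` instead sets g ≈ 0 on a 3-px
  band along the line — it constrains but does not guarantee zero atrial
  pixels, which is why the hard clamp is the default.
* 2500 iterations by default (fixed-iteration protocol); an optional
  early-stop (area change < 0.01 % over 100 iterations) is off by default.
  Output is the largest connected component of {φ < 0}; ties φ = 0 count
  as exterior. Collapse of the interior raises an error carrying the
  iteration number.

## Reference delineation

Periodic cubic interpolating spline (`scipy.interpolate.splprep`, s = 0,
chord-length parameterization) through 20 ordered border landmarks;
orientation is normalized internally so clockwise and counter-clockwise
observer conventions are equivalent. Rasterization takes pixel centres
(0-based, row-major) strictly inside the curve (even-odd rule via point-in-
polygon tests); it is invariant to the curve's start point and orientation.
Self-intersecting landmark polygons or splines are rejected. A headless
observer surrogate samples n arc-length-equispaced boundary points from a
truth mask with optional Gaussian jitter (pipeline default 1.5 px),
standing in for interactive point-picking.

## Evaluation and statistics

Dice D = 2|A∩B|/(|A|+|B|); both-empty input is defined as 0 with a warning.
Bins `<0.8`, `0.8–0.9`, `>0.9`; both boundary values 0.8 and 0.9 belong to
the middle bin. The Wilcoxon signed-rank discards zero differences by
default (Pratt handling available), mid-ranks ties, and is exact by full
2^n sign enumeration for n_effective ≤ 12, otherwise a tie- and
continuity-corrected normal approximation (verified to match scipy's). The
McNemar test on one-vs-rest Dice-bin indicators is exact-binomial for
b + c ≤ 25 discordant pairs, else χ² with 1 df; no multiple-testing
correction is applied across the three bins (a Bonferroni option would be
a one-line wrapper; the three tests are reported jointly). The paired t
test reports the 95% CI and flags zero-variance input. Summaries carry the
significance bands NS / P<0.05 / P<0.001 alongside raw p-values.

## Pipeline seeding

One global seed fans out as
`SeedSequence(entropy=seed, spawn_key=(stage, dose_index, animal, observer))`
with stage 0 = phantom, 1 = landmarks, 2 = scores, 3 = physiology, so any
subset of a run reproduces bit-for-bit regardless of execution order.

## Problem sizes

Full-scale analyses use 256×256 rasters and 2500 iterations (≈ 6 s per
segmentation on one CPU). The package also defines a reduced preset
(`RunConfig.reduced()`: 128 px, 800 iterations, ≈ 1 s per segmentation)
used for the multi-seed dose-ordering sweeps and the end-to-end example
runs; the reduced scale preserves the dose ordering but compresses its
dynamic range (border dropouts are relatively smaller at 128 px, so
low-dose Dice values are higher than at full scale).

## What the phantom does and does not show

The phantom reproduces the *statistical structure* the analysis depends on:
dose-ordered opacification, homogeneity and enhancement duration; an
atrium that defeats intensity-based chamber separation; speckle-limited
edges. It does **not** simulate acoustic wave propagation, nonlinear
microbubble dynamics, contrast pulse sequences, mechanical-index effects,
3-D geometry, cardiac or respiratory motion, or real observer behaviour
(scores are drawn from fixed categorical distributions; references are
jittered truth boundaries). Passing tests therefore demonstrate that the
analysis chain is correct and well-calibrated under these controlled
conditions, not that the segmentation would achieve the same Dice values
on in-vivo images. Statistical outputs are validated against enumeration
oracles and simulated error rates rather than against published p-values,
which are reported in the source study only as significance bands.
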