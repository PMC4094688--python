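# lvecho

Tools for studying **semiautomatic endocardial border delineation in
contrast-enhanced echocardiography** — aimed at researchers comparing
ultrasound contrast-agent doses by how well the left-ventricular (LV) blood
pool can be segmented after opacification.

After a microbubble contrast bolus, the LV blood pool brightens
("opacification") and the endocardial border — the boundary between blood
pool and myocardium — becomes delineable. How reliably it can be delineated
depends on the dose: low doses opacify weakly and inhomogeneously
(attenuation gradients, swirling dropouts) and fade quickly. Because real
porcine/clinical contrast images of such studies are not publicly deposited,
this package provides the full analysis chain *plus* a synthetic phantom
generator that emulates the statistical structure the analysis depends on,
so every step is testable against known ground truth.

The pipeline mirrors a dose-comparison study design
(8 animals × 4 injections × 3 observers):

1. **phantom** — apical two-chamber contrast frames: a truncated-ellipse
   cavity inside a darker myocardial wall, an equally bright atrium beyond
   the atrioventricular (AV) plane, multiplicative gamma speckle
   (variance 1/looks), dose-dependent peak intensity, inhomogeneity
   (axial gain ramp + border dropouts), and a wash-in → plateau → wash-out
   time course. Also simulates observer segment-score tables and per-minute
   physiological logs (SaO2, heart rate, mean arterial pressure).
2. **frame_selection** — splits a sequence into 20-s intervals from contrast
   arrival and picks the best-enhanced frame per interval by the score
   `mean(ROI) − λ·CV(ROI)`; reports the duration of clinically useful
   enhancement ("0–20 s", "20–40 s", …).
3. **segmentation** — geodesic active contour (Caselles) level set:

       φ_t = g·κ·|∇φ| − g·c·|∇φ| + ∇g·∇φ,   g = 1 / (1 + (|∇(G_σ∗I)|/g₀)²)

   with an elliptical seed of ≈¼ of the expected LV area, a constant balloon
   force `c`, 2500 iterations by default, and a hard AV-plane constraint
   (contrast cannot separate ventricle from atrium by intensity, so the
   atrial half-plane is clamped to exterior after every update).
4. **reference** — the expert reference border: 20 landmark points joined by
   a periodic cubic spline and rasterized (even-odd pixel-center rule).
5. **evaluation** — Dice value `D(A,B) = 2|A∩B| / (|A|+|B|)` between the
   semiautomatic mask A and the reference B, binned into the clinical
   quality intervals `<0.8`, `0.8–0.9`, `>0.9`.
6. **scoring / stats** — 6-segment visibility scores (0/1/2) per region
   (apical/mid/base) and the statistical battery: Wilcoxon signed-rank on
   paired scores (exact by sign enumeration for small n), McNemar on paired
   Dice-bin indicators (exact binomial for few discordant pairs), paired
   two-sided t with 95% CI on relative physiological differences.
7. **pipeline / cli** — one seeded, fully reproducible end-to-end run.

## Worked example

```python
import numpy as np
from scipy import ndimage
from lvecho import PhantomConfig, generate_sequence, SegmentationSpec, segment, dice, bin_dice
from lvecho import frame_selection as fs
from lvecho.reference import sample_landmarks, landmarks_to_mask

cfg = PhantomConfig.for_dose("5", rng_seed=1)       # high-dose injection phantom
seq = generate_sequence(cfg)
truth = seq.truth_mask

selections = fs.select_frames(seq, truth)
for s in selections:
    print(f"interval {s.interval_index} [{s.interval_bounds[0]:.0f}, "
          f"{s.interval_bounds[1]:.0f}) s  frame {s.selected_frame}  "
          f"score {s.enhancement_score:.3f}")
print("useful duration:", fs.useful_duration(selections))

best = max(selections, key=lambda s: s.enhancement_score)
spec = SegmentationSpec(
    seed_center=tuple(ndimage.center_of_mass(truth)),
    expected_area=float(truth.sum()),
    av_plane=seq.av_plane,
)
mask = segment(seq.frames[best.selected_frame], spec)

reference = landmarks_to_mask(sample_landmarks(truth, jitter_sd=1.5, rng=0), truth.shape)
d = dice(mask, reference)
print(f"Dice vs reference: {d:.3f}  bin: {bin_dice(d)}")
```

prints

```
interval 0 [6, 26) s  frame 11  score 0.640
interval 1 [26, 46) s  frame 26  score 0.639
interval 2 [46, 66) s  frame 46  score -0.009
useful duration: 20–40 s
Dice vs reference: 0.986  bin: >0.9
```

The enhancement score stays high through the first two 20-s intervals (the
high dose plateaus for ~30 s), so the clinically useful period is
"20–40 s"; the active contour recovers the cavity almost perfectly against
a jittered 20-landmark observer reference (Dice 0.986, top quality bin).
Low-dose phantoms (`PhantomConfig.for_dose("1.5")`) instead fade within the
first interval and segment poorly (Dice typically below 0.8), reproducing
the qualitative dose ordering such studies report.

The same analysis is available from the shell:

```bash
lvecho generate --dose 5 --seed 1 --out run/seq
lvecho select run/seq/sequence.json
lvecho segment run/seq/sequence.json --frame 11 --out run/seg
lvecho run-all --reduced --seed 0 --out run/full
```

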