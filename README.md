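# tailquant

Quantitative image analysis for zebrafish larval tail-regeneration
experiments.

After the tip of a larval zebrafish tail is excised, a stereotyped
sequence unfolds within hours: reactive oxygen species (ROS, chiefly
H₂O₂) flare along the wound edge, the trunk contracts along the
anterior–posterior axis, notochord cells are squeezed out of the cut
sheath into a "bead" on the stump, and a proliferative blastema forms
under a wound epithelium. Scoring these events from micrographs requires
a set of small, carefully specified measurements — and doing them
blinded, with fixed thresholds, so treatment groups can be compared.
`tailquant` packages that measurement pipeline as an open, tested
library and CLI for researchers quantifying regeneration phenotypes:

- **Blinded analysis** — duplicate a folder of images under random
  6-digit codes, save a key, and re-attach original names to result
  tables after measurement.
- **In situ staining area** — select pixels of the blue oxidised-BCIP
  precipitate with per-channel RGB windows (inclusive `[min, max]` on
  each of R, G, B; a pixel is counted iff it falls inside all three),
  optionally within an ROI and minus an artefact-exclusion mask.
- **Wound-ROS score** — detect the embryo outline on brightfield,
  then compute
  `score = mean(F | within 50 μm of the wound edge) − median(F | trunk, 1 mm distal)`,
  the background-corrected wound fluorescence. Distances are geodesic
  within the embryo silhouette.
- **Signed Menger curvature** of notochord cell membranes: for the
  circle through two sheath-contact points and the membrane apex,
  `|κ| = 4A/(abc)` with `A` the triangle area and `a, b, c` its side
  lengths; `κ > 0` for a posterior bow, `κ < 0` anterior, `κ = 0` for a
  straight membrane perpendicular to the sheath.
- **Morphometry** — trunk contraction `100·(L_pre − L_post)/L_pre`
  between named landmarks measured parallel to the notochord; tail
  length / regrowth as axial distances; notochord-bead area from a
  polygon ROI (shoelace formula).
- **Mitotic-figure counting** — maximum-intensity projection,
  thresholding, 8-connected components, and the filter
  `area > 50 μm² AND distance-to-caudal-end ≤ 500 μm`.
- **Synthetic fixtures** — a ground-truthed generator for every image
  class above, so each stage is validated against known truth without
  any raw micrographs.

## Worked example

```python
from tailquant import (PixelCalibration, Point2D, MembraneTriple,
                       menger_curvature, quantify_wound_ros, measure_contraction)
from tailquant.synth import (WoundSceneParams, gen_wound_embryo,
                             ContractionParams, gen_contraction_pair)

cal = PixelCalibration(1.0)  # 1 μm per pixel

# A membrane bowed toward the posterior (apex at larger x than its chord)
t = MembraneTriple(Point2D(210, 120), Point2D(214, 160), Point2D(222, 141), cal)
r = menger_curvature(t)
print(f"kappa = {r.kappa:+.5f} um^-1   (R = {r.radius_um:.1f} um, sign {r.sign:+d})")

# Wound-ROS score on a noisy synthetic larva (truth: 200 − 50 = 150)
bright, fluor, truth = gen_wound_embryo(WoundSceneParams(noise_sigma=5.0), seed=1)
res = quantify_wound_ros(fluor, bright)
print(f"wound mean = {res.wound_mean:.2f}, trunk median = {res.trunk_median:.2f}, "
      f"score = {res.score:.2f}")

# Trunk contraction from a jittered landmark pair (truth: 4.4 %)
pre, post, _ = gen_contraction_pair(ContractionParams(jitter_sigma_um=2.0), seed=1)
c = measure_contraction(pre, post, (1, 0), cal)
print(f"L_pre = {c.L_pre_um:.1f} um, L_post = {c.L_post_um:.1f} um, "
      f"contraction = {c.contraction_percent:.2f}%")
```

prints

```
kappa = +0.03951 um^-1   (R = 25.3 um, sign +1)
wound mean = 199.92, trunk median = 50.00, score = 149.92
L_pre = 800.0 um, L_post = 763.1 um, contraction = 4.61%
```

The curvature line says the membrane arc is approximated by a 25.3 μm
circle bowing posteriorly. The ROS score recovers the constructed
150-unit wound elevation to within a tenth of an intensity unit despite
σ = 5 pixel noise. The single jittered contraction pair reads 4.61%
against a 4.4% truth; averaging over pairs (as in a real experiment)
converges to the group mean.

## Command line

One executable with a subcommand per measurement:

```sh
tailquant synth --scene wound --seed 0 --out-dir fix/
tailquant ros-quant --fluor fix/fluor.tif --bright fix/bright.tif --out results.csv
tailquant blind --in raw/ --out coded/ --seed 42 --key key.csv
tailquant stain-quant --image coded/000123.tif --threshold 0,100,0,100,120,255 --out results.csv
tailquant unblind --results results.csv --key key.csv
tailquant curvature --triples triples.csv --pixel-size-um 0.65 --out results.csv
tailquant contraction --pre pre.csv --post post.csv --axis 1,0 --out results.csv
tailquant spots --image proj.tif --caudal 700,400 --out results.csv
```

All quantification commands append tidy rows
(`image_id,measurement,value,units`) to a shared CSV for downstream
statistics, which this package deliberately leaves to external tools.

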