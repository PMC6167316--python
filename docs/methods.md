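# Methods

This note documents the measurement definitions, parameter choices and
numerical conventions implemented in `tailquant`, and what the synthetic
fixtures do and do not establish about real data.

## Coordinate and unit conventions

Images are assumed oriented anterior-left, dorsal-up, so "posterior"
means larger `x` (column index) and "ventral" larger `y` (row index).
Pixel `(i, j)` covers `[i, i+1) × [j, j+1)` with its centre at
`(i+0.5, j+0.5)`; rasterisation (polygon masks, synthetic disks) is by
pixel-centre inclusion. All physical quantities use a single isotropic
pixel size in μm/pixel, taken from TIFF resolution metadata (stored as
pixels per μm with a unit-less resolution tag) or a user override;
anisotropic pixels are rejected rather than silently averaged because
every distance, area and curvature formula below assumes isotropy.

## Blinding

Each image is duplicated under a random zero-padded 6-digit code with
its extension preserved; the original→code table is the key. Codes are
drawn from a seeded RNG when reproducibility is wanted and from system
entropy otherwise. Unblinding remaps only identifiers in the tidy
result table, never values, so a blinded measurement run is verifiably
identical to an unblinded one.

## RGB-threshold staining area

A threshold is six integers `(r_min, r_max, g_min, g_max, b_min, b_max)`;
a pixel is selected iff each channel lies inside its window, **bounds
inclusive at both ends** (the window semantics of intensity thresholds;
the convention is fixed and documented so areas are bit-stable).
Stained area = selected pixels × px², intersected with an optional
polygon ROI and minus an optional exclusion mask supplied as a polygon
file — artefact exclusion is file-based rather than interactive so runs
are reproducible. One threshold must serve a whole comparative batch;
the CLI takes it once per invocation and applies it to every image.

## Wound-ROS score

`score = mean(F over wound band) − median(F over trunk reference)`.

- *Outline*: Otsu's threshold on the brightfield histogram, embryo taken
  as the darker class, largest 8-connected component, holes filled.
  Detection fails loudly if the component covers <1% of the image. A
  pre-computed mask may be supplied instead.
- *Wound edge*: the boundary arc within `edge_window_um` (default 25 μm)
  of the mask's maximal-x extent — the posterior stump. A two-point
  wound line can override this for oblique amputation planes.
- *Wound band*: embryo pixels whose **geodesic** distance within the
  mask to the edge arc is ≤ 50 μm. Geodesic (minimum-cost-path with
  unit cost inside the mask) rather than Euclidean distance is used so
  that a curved fin fold cannot put non-adjacent tissue "near" the
  wound through background.
- *Trunk reference*: embryo pixels at geodesic distance 1000–1100 μm
  from the edge arc. The 100 μm band depth is a package default (the
  reference area's size is otherwise unconstrained); the median is
  insensitive to it.

The median/mean asymmetry is deliberate: the trunk median is robust to
stray bright pixels (pigment, autofluorescence), while the band mean
integrates the graded wound signal. The score is invariant under
adding a constant to all intensities and scales linearly with gain.

## Signed Menger curvature

For sheath contacts `P_a`, `P_b` and apex `P_c` (all converted to μm),
`|κ| = 4A/(abc)` — the inverse circumcircle radius — with `A` the
triangle area and `a, b, c` the side lengths. The sign is the apex's
laterality: positive when the apex lies posterior (larger x) to its
perpendicular foot on the chord `P_aP_b`, negative when anterior. For
points on a circle this is equivalent to the circumcentre-side
convention (centre and apex always fall on opposite sides of the
chord), but apex laterality remains numerically stable as the membrane
straightens and the circumcentre recedes to infinity. Collinearity is
declared when the normalised sine `2A/(|P_a−P_c||P_b−P_c|) < 1e−9`,
mapping straight membranes to exactly `κ = 0`, sign 0 — the tolerance
makes the zero case reachable in floating point. A chord exactly
parallel to the body axis has no anterior/posterior laterality; the
degenerate zero x-offset resolves as positive (documented tie-break).

*Cell selection*: among annotated membrane traces that span the
notochord width and are not bent by contact with neighbouring cells
(bent membranes are excluded from analysis), the trace nearest the
reference line 600 μm anterior of the stump is chosen. Its triple is
the two chain endpoints plus the chain point furthest from their chord;
exact distance ties break to the smallest y (most dorsal point).

## Contraction, lengths, bead area

Axial lengths are the absolute projection of the endpoint displacement
onto a unit axis direction (the notochord direction), × pixel size —
the rectangle-parallel-to-the-body measurement. Contraction is
`100·(L_pre − L_post)/L_pre` between two named landmarks present in
both the pre-excision and 2 h post-excision sets; the package measures
one span across ~eight somites rather than per-somite distances, and by
default picks the axis-extreme pair of the common landmark names.
Bead area is the shoelace area of a polygon ROI × px², orientation
independent; degenerate polygons return 0 with a warning.

## Spot counting

Maximum-intensity projection (per-pixel max across slices of identical
geometry), then Otsu or absolute thresholding, 8-connected labelling,
and the filter `area > 50 μm²` (**strict**, a literal reading of
"greater than") and centroid distance to the caudal landmark
`≤ 500 μm` (inclusive). Distance is measured from the component
centroid, the standard object location. Both cut-offs and the
threshold are parameters so the filter is auditable; a blank image
yields count 0, not an error.

## Synthetic fixtures

The generator produces, deterministically per seed:

- *Wound scenes*: a dark silhouette (ellipse body + tapering tail,
  truncated at the stump) on bright background, and a fluorescence
  channel with basal level `I_b` inside the embryo and `I_w` near the
  wound. The elevated region extends `band_width + edge_window` from
  the cut plane; since geodesic distance bounds horizontal distance,
  the measured 50 μm band is always a subset of it, making the
  noiseless score exactly `I_w − I_b`.
- *Stain/spot disks* rasterised to an **exact** pixel count (the n
  nearest pixel centres, with a sub-pixel irrational centre offset to
  exclude distance ties), so area assertions are exact rather than
  within rounding, including the boundary case of a spot of exactly
  50 μm² = 50 pixels.
- *Membrane triples* placed exactly on circles of known radius with a
  near-vertical chord, apex on the bowed side: truth `κ = ±1/R` or 0.
- *Contraction pairs*: landmarks named `s0..s7` spaced over 800 μm
  (~eight somites, a realistic larval somite spacing of ~115 μm); the
  post set is the pre set scaled by `1 − c/100` along the axis plus
  Gaussian placement jitter (default tests use σ = 2 μm, the scale of
  manual landmark placement error). Presets carry the measured group
  means: untreated 4.4%, DPI 1.7%, PP2 1.2%.

Noise is additive Gaussian, clipped to the intensity range and rounded
to integer pixels; σ defaults to 0 so unit tests are exact. The
fixtures emulate the *geometry and statistics* each measurement relies
on — not optics. There is no point-spread function, no graded stain
boundary, no pigment or autofluorescence clutter, no oblique
amputation planes by default. Passing tests therefore establish that
the measurement definitions are implemented correctly and recover
known truth under idealised contrast; they do not establish robustness
of Otsu outline detection or spot segmentation on low-contrast real
micrographs, where the provided-mask and absolute-threshold code paths
exist as fallbacks.

## Problem sizes and numerical choices

Default scenes are sized so physical constraints hold at 1 μm/px
(wound scenes 256×1400 px, giving an embryo >1.2 mm so the 1 mm trunk
reference exists; spot scenes 800×1400 px). Recovery checks use 20
seeds (ROS, σ = 5) and 30 pairs (contraction, σ = 2 μm), sizes at which
the standard error of the mean is comfortably below the asserted
recovery bands (±2 intensity units; ±0.3 percentage points). Geodesic
distances use an 8-connected minimum-cost-path transform, which
overestimates Euclidean length by at most ~8% off-axis; tests that
compare against a Euclidean oracle do so on convex rectangles where the
two coincide along the relevant directions and assert subset/≥95%
coverage rather than pixel identity.

## Known limitations

- No automatic membrane segmentation: traces, sheath contacts and
  landmarks are supplied as annotations, mirroring the manual workflow.
- Single 2-D projections only; z-stacks must be pre-projected or passed
  as slice folders to `max_project`.
- ImageJ binary `.roi`/`.zip` formats are not read; ROIs are CSV point
  lists.
- Distance to the caudal end is measured to a point landmark; a
  plane-distance variant is not implemented.
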