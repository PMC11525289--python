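# Methods

This note documents the models, parameter choices and known limits of
`twpscope`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scene model (synthetic ground truth)

The generator emulates reflected-light microscopy of particles on a
membrane filter at 1.5 µm px⁻¹ (the default acquisition scale):

- **Background**: pale blue, RGB (186, 202, 222), with Gaussian noise
  (σ = 4 digital numbers). The blue cast is what the contrast enhancement
  later removes.
- **TWP**: ellipses, superellipses (exponent 2.5–5) and harmonic blobs
  (radial perturbation ≤ 8 % per harmonic, orders 2–5), aspect ratio
  1–2.2. Each shape is built as a continuous boundary polygon, rescaled so
  its exact minimal caliper width equals the requested mFD, rotated, then
  rasterised. True FD/mFD are computed from the polygon *before*
  rasterisation, so ground truth is independent of pixel-level
  measurement.
- **Chromatic diffraction rim**: the particle's outer band of width *h*
  (per-particle, default sampled uniformly from 3–5 µm) is replaced by
  saturated blue/yellow/red pixels; the remaining core is painted black.
  "Black" is an artifact convention: all channels ≤ 40 of 255, leaving a
  wide margin below the background. The rim is a purely annular
  replacement — no light-scattering physics — chosen because it
  reproduces the one consequence that matters for calibration: a
  colour-based detector measures the core, so measured ≈ true − 2h, and a
  particle with 2h ≥ its width has no black pixels and is undetectable.
- **Distractors**: charcoal as black angular polygons with sparse internal
  grey (48–95) texture — colourimetrically identical to TWP, separable
  only by texture, hence a *designed* false-positive source; organic
  matter as brown/green blobs with no black pixels.
- **Placement**: rejection sampling on bounding circles (no overlap unless
  requested), largest first, 1000 attempts before an explicit
  `PlacementError`.
- **Determinism**: one `numpy` Generator seeded from the spec; identical
  spec + seed is bit-identical.

What the generator does **not** emulate: uneven illumination, focus
gradients, mosaic seams, camera noise statistics, partially transparent
organic films, and — most importantly — the physical losses of an
extraction protocol (density separation, transfers). Passing tests
therefore validate the *image-analysis* chain, not wet-lab recovery.

## Pipeline choices

- **Enhancement** `v → clip(g(v − b), 0, 255)` with defaults g = 1.5,
  b = 30: the background (≥ ~180) maps toward white while black cores
  (≤ 40) map to ≈ 0. The published workflow states the goal, not the
  numbers; these are config values.
- **Features** for the pixel classifier: raw R,G,B; per-channel Gaussians
  at σ ∈ {1, 2, 4} px; gradient magnitude of luminance (σ = 1); grey
  local min/max in a 3×3 window; channel minimum (darkness). A random
  forest (100 trees, fixed seed, out-of-bag accuracy reported) is the
  closest well-defined analogue of an interactive trainable-segmentation
  default. A rule classifier (all channels ≤ 40) is provided for
  deterministic headless runs; both feed the same downstream code.
- **Binarization**: IsoData on the 8-bit probability raster — one named,
  reproducible automatic threshold. A constant raster yields an empty
  mask plus a warning rather than an arbitrary cut.
- **Watershed tolerance**: markers are *extended maxima* of the Euclidean
  distance transform — regional maxima of its morphological
  reconstruction from `EDT − tolerance`. A basin whose depth relative to
  its connecting saddle is below the tolerance (in pixels of distance)
  collapses into its neighbour. Extended maxima, rather than h-maxima,
  are required so that two *equal-height* fused discs merge at high
  tolerance. Cut lines are one pixel wide and removed from the
  foreground; the watershed flood fill runs 4-connected (the 8-connected
  fill with line extraction is pathologically slow in current
  scikit-image), while component labelling is 8-connected throughout.
- **Feret diameters**: particles are represented by the corners of their
  boundary pixels (each pixel a closed unit square), so a w×h rectangle
  measures FD = √(w²+h²), mFD = min(w, h) exactly. FD comes from rotating
  calipers over antipodal hull vertex pairs; mFD is the exact minimal
  width (minimum over hull edges of the farthest-vertex distance). A
  single-pixel particle reports FD = mFD = one pixel by convention.
- **Perimeter / circularity**: the default estimator traces the
  marching-squares boundary and smooths it with a 7-point circular moving
  average before measuring length; this removes the staircase bias that
  makes chain-length estimators overestimate curved outlines by ~5 %, so
  digital discs have circularity ≈ 1 (clipped at 1). The coarser weighted
  boundary-step estimator is available as `perimeter_mode="weighted"`;
  it depresses circularity by a few percent and is the main source of
  disagreement between platforms.
- **Size window**: retained particles satisfy 35 ≤ mFD < 2000 µm (lower
  bound inclusive); the pre-filter count always travels in the table
  metadata.

## Calibration

- Accuracy pairs use greedy one-to-one nearest-centroid matching within
  20 µm — far below inter-particle spacing in the synthetic scenes, so
  greedy equals optimal in practice (asserted against exhaustive
  assignment on small cases).
- The accuracy–size relation is summarised two ways: a LOESS smooth
  (span 0.75, visualisation only) and a continuous two-segment linear
  model `y = c + s₁(x − bp)` below the breakpoint, `c + s₂(x − bp)`
  above, fit by least squares from a 10-point multi-start grid over the
  breakpoint. Convergence and degeneracy (breakpoint at the data edge, or
  s₁ ≈ s₂) are flagged, never silently patched. A variant with s₂ fixed
  at 0 is available. On hinge-generated data (plateau 90 %, break 25 µm,
  noise σ = 2, 101 points) the median breakpoint error over 100 seeded
  simulations is well under 3 µm. Note the pipeline's *real*
  accuracy–size curve is concave (accuracy ≈ 100·(1 − 2h/d)), so the
  fitted breakpoint of real pairs sits above the visual plateau onset —
  the hinge is a summary device, which is also why the operational size
  limit is driven by the recovery rule instead.
- Recovery per threshold t is `100 · #detected(mFD ≥ t) / #true(mFD ≥ t)`
  per replicate (counts, not masses), averaged with sample SD/SE; the
  operational limit is the smallest t with mean recovery ≥ 80 %. On
  purely optical synthetic scenes recovery stays near 100 % at every
  threshold — extraction losses are out of scope — so the rule is
  exercised on constructed curves in the tests.

## Quantification

- LOD = mean + 3·SD and LOQ = mean + 10·SD of blank counts (sample SD,
  n−1), both floored at the operational resolution (1 particle per
  subsample): a counting method cannot report fractional particles, so
  with clean blanks both limits are 1.
- Concentration = mean replicate count × 1000 / subsample dry mass (g),
  in particles kg⁻¹ dry soil; SE scales the replicate SD identically
  (NaN for a single replicate). Note ~40 particles in 5 g → 8000 kg⁻¹.
- Group comparison: Kruskal–Wallis (tie-corrected, via scipy) with Dunn's
  pairwise z tests on pooled ranks, tie term Σ(t³−t)/(12(N−1)), Holm
  adjustment by default. Dunn is implemented in-package (no installed
  Python library provides it) and is cross-checked against an
  independent R implementation to 1e-8 in the acceptance suite. An
  all-identical degenerate input returns H = 0, p = 1.
- Mass: per-particle ellipsoid volume (π/6)·FD·mFD·(k·mFD) with thickness
  ratio k = 0.4 and density 1.8 g cm⁻³ (mineral-encrusted rubber) by
  default; every output carries the model tag and parameters because this
  is an order-of-magnitude device, not a measurement.

## Problem sizes

Default experiment scales, chosen as the package's standard desk-scale
study: size-accuracy runs use 120 particles across 620 px tiles
(12 per tile, round-robin by size so each tile carries its share of large
particles); detection runs use 3 scenes of 10 particles at 880 px;
breakpoint recovery uses 100 simulations of 101 pairs. All are seeded and
reproducible.

## Known limitations

- Charcoal is colourimetrically indistinguishable from TWP by design; the
  pipeline reports it as false positives rather than attempting
  texture-based discrimination.
- The recovery rule cannot be stressed end-to-end without an extraction
  loss model; only its selection logic is validated.
- The greedy matcher can mis-pair in pathologically dense scenes
  (spacing below the 20 µm radius); the generator's non-overlap placement
  avoids this regime.
- Perimeter (hence circularity) remains estimator-dependent at small
  sizes; both estimators are exposed, and circularity is clipped at 1.
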