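# Methods

## Model and scope

`veinseg` targets 8-bit grayscale near-infrared (NIR) images of forearm
vasculature, nominally 548×335 region-of-interest crops. The image is
treated as an additive superposition `I = R + G` of vessel signal `R` on a
smooth background `G`; vessels are darker than their surround because blood
absorbs NIR more strongly than the surrounding tissue. The method is
training-free and fully deterministic: every stage is a fixed image
operator, and all randomness in this repository lives in the synthetic
phantom generator.

Coordinate convention throughout: row-major arrays, origin top-left,
0-based `(row, col)` indexing. All spatial filters replicate edge pixels at
the border.

## Pipeline stages and parameters

### CLAHE (`enhancement.clahe`)

The frame is divided into `tiles_n × tiles_m` non-overlapping tiles
(default 8×8, the conventional grid for frames of this size). Each tile's
256-bin histogram is clipped at `L_C = clip_factor · Av`, where `Av` is the
tile's pixel count divided by its number of *occupied* gray levels
(`N_XY`). Clipped mass `S` is redistributed: a uniform share `S / N_XY` to
each occupied level, and the integer remainder dealt one count at a time at
gray-level step `L = 256 / S` starting from level 0. The per-tile mapping
is the rounded, rescaled histogram CDF; per-pixel outputs are bilinearly
interpolated between the four nearest tile centers (clamped at borders) to
avoid block artifacts. `clip_factor` defaults to 2.0 — enough to lift the
compressed NIR histogram without the noise explosion of unlimited
equalization; with one tile and an unbounded clip factor the operator
reduces exactly to plain histogram equalization, which is pinned by a test.

### Gaussian denoising (`enhancement.gaussian_filter`)

NIR sensor noise is well modelled as additive zero-mean Gaussian noise, so
the denoiser is a normalized Gaussian convolution, default 3×3 with
σ = 1.5 px. The kernel is the 2-D Gaussian sampled on the integer grid and
normalized to unit sum; an unrounded variant (`gaussian_filter_float`) is
exposed because linearity holds exactly only before quantization.

### Background estimation and subtraction (`background`)

`G` is estimated as `median(min(I, 3×3), 51×51)`. The minimum filter
deepens and slightly widens the dark vessels (by ~1 px per side), which
sharpens the vessel/background distinction in the residual; the median
filter then restores the vessel-free luminance because, over a window that
straddles a vessel, background pixels are in the majority. That majority
requirement sets the window size: with vessel calibres up to ~12 px, the
minimum filter and the optical edge blur stretch the dark band to ~20 px,
and two vessels crossing can double the dark fraction locally, so the
51 px default keeps the dark fraction safely below the median's 50%
breakdown point. Windows of 21–31 px (closer to the vessel scale)
measurably swallow the vessel interior: the background estimate follows
the vessel and the residual loses its core.

The residual `R = I − G` is kept in signed arithmetic (no clipping), so
`G + R` reconstructs `I` exactly; vessel evidence is its negative side
(`polarity="dark"`, configurable).

### Binarization (`background.binarize_difference`)

The residual histogram has a dominant background mode — centred slightly
below zero on the vessel-signal scale, because taking the windowed minimum
of noisy data biases the background estimate downward — and a vessel tail.
The `auto` threshold is a robust z-score cut relative to that mode:

    tau = median(s) + 1.5 · 1.4826 · MAD(s),   mask = s > tau

(`s` the residual on the vessel-signal scale, clamped at tau ≥ 0; a
constant residual gives an empty mask). The median/MAD locate the noise
floor robustly because the background dominates by area. The 1.5-sigma
multiplier is the standard inner-fence cut and is deliberately permissive:
the method favours recall, accepting extra foreground that the later
screening and smoothing stages are designed to absorb. An Otsu variant
restricted to the vessel-sign half of the histogram is kept as
`threshold="otsu"` for comparison; because that restriction excludes the
background mode, Otsu tends to split the vessel class itself and recovers
about half the vessel pixels, so it is not the default.

### Connected-domain screening (`components`)

Noise that survives binarization forms small isolated blobs, while vessels
are long connected structures. Components are labelled (8-connectivity by
default — vessels run diagonally, and 4-connectivity would fragment them)
and those with pixel area below `T` are removed; area exactly `T` is kept.
`T = 1500` for the 548×335 frame, the low end of the useful 1500–1800
range, favouring recall of small vessels. The threshold is an area at a
specific scale: for other frame sizes it should be scaled proportionally.

### T-element morphology (`morphology`)

The screened mask still has ragged edges and protrusions. The refinement
erodes with the four 90°-rotations of a directional T-shaped 6×6 element
(a 2×6 bar plus a 2×2 stem) in the fixed order t1→t2→t3→t4, each erosion
followed by a dilation with a disk `b`:

    f_n = (f_{n−1} ⊖ t_n) ⊕ b,   n = 1..4

Erosion/dilation are flat binary operators with an explicit anchor; the
6×6 elements have no central cell, so the anchor is fixed at (2,2), the
upper-left cell of the central 2×2 (this keeps the stem symmetric about
the anchor's column pair). Dilation reflects the element through its
anchor; erosion does not — with asymmetric elements this matters, and both
conventions are pinned against brute-force oracles. Element cells falling
outside the image are ignored by erosion and count as background for
dilation, so a mask touching the frame edge is not eaten from outside.

The disk radius defaults to 3: the T bar reaches 3 cells from the anchor,
so a radius-3 disk is the smallest that structurally restores what one
erosion can remove at an ideal straight edge. A radius-2 disk
under-compensates every round; measured on phantom masks, the four-round
schedule then progressively destroys vessels of binary width below ~8 px
(sensitivity fell from 0.87 to 0.61 across the schedule). With radius 3
the schedule smooths protrusions, closes pinholes, and leaves masks
slightly wider than the true vessel — the recall-favouring behaviour the
method is built around.

### Metrics (`metrics`)

Dice, accuracy and sensitivity are computed from pixel confusion counts
against a reference mask. Degenerate conventions: Dice of two empty masks
is 1; sensitivity with an empty reference is 1. Energy (squared forward
differences, both axes) and Brenner (squared lag-2 differences along rows)
are computed by default on intensities rescaled to [0,1] and divided by the
number of summed terms, making scores comparable across image sizes; raw
8-bit sums are available with `normalized=False`. The exact normalization
behind published absolute values of these scores varies between authors,
so only relative comparisons (e.g. sharp vs. blurred) are meaningful
across implementations.

## The phantom generator (`phantom`)

The generator emulates the statistical structure of NIR forearm crops:

- **background**: base intensity 180 with a linear illumination tilt of
  ±30 across the frame in a random direction (NIR illumination is bright
  and uneven, but smooth);
- **vessels**: by default 3 smooth curves — cubic splines through 4–8
  random control points ordered along a random principal direction, so
  curves are elongated rather than self-crossing — rasterized as tubes
  with calibre drawn uniformly from 6–12 px and intensity lowered by 40;
- **optics**: Gaussian blur of the vessel layer with σ = 1.5 px (vessel
  edges in real frames are fuzzy); the illumination field is already
  smooth and is not blurred, so a vessel-free phantom is exactly the field;
- **sensor**: additive zero-mean Gaussian noise, σ = 8, clipped to [0,255].

The ground-truth mask is the *pre-blur* tube footprint: blur models the
optics, truth is the anatomy. Identical spec + seed gives bit-identical
output. Defaults were chosen once for plausibility at the 548×335 scale —
vein calibres of a few px to ~1 mm-equivalent, noise visible but not
dominant (contrast/noise = 5), tilt strong enough to defeat any global
threshold. Real data differ in ways the phantom does not model: depth-
dependent contrast along a single vessel, branching trees rather than
independent curves, texture from hair and skin pigmentation, and specular
artifacts. Passing the phantom suite therefore demonstrates the pipeline's
mechanics — background removal, screening, smoothing — under controlled
conditions, not clinical-grade performance.

## Numerical choices and degenerate inputs

- All intermediate images are uint8; the residual is int16; no stage
  consumes randomness, so segmentation is bit-reproducible.
- CLAHE tile mappings use `round(255 · cdf / n)`; remainder redistribution
  cycles from gray level 0 (the start level is otherwise arbitrary and is
  fixed for reproducibility).
- An all-empty mask at any stage is a valid result (logged as a warning),
  not an error; empty masks are fixed points of screening and morphology.
- Erosion with an element whose anchor cell is false is allowed but warns,
  since anti-extensivity is then not guaranteed.
- Pipeline stage failures are re-raised with the stage name attached.

## Evaluation protocol and problem sizes

The acceptance script and the end-to-end test use 20 phantoms at the
default study conditions (548×335, 3 vessels, contrast 40, noise σ = 8) —
enough frames for stable means at roughly a minute of single-core compute.
Operator-level tests check exact equality against brute-force oracles
(literal double-loop transcriptions of the definitions) on random 16×16
masks, where exhaustive comparison is cheap. On the 20-phantom suite the
default pipeline reaches mean Dice ≈ 0.71, sensitivity ≈ 0.92, accuracy
≈ 0.93 (see `scripts/acceptance.py`).

## Known limitations

- The area threshold `T` and the median window are scale-specific; neither
  adapts to image size or vessel calibre automatically.
- Vessels of binary width below ~6 px cannot survive the 6×6 T-element
  erosions regardless of the disk radius; the method is blind to the
  finest vasculature by construction.
- The recall-favouring threshold and radius-3 dilation deliberately
  over-segment by 1–3 px of halo; applications needing exact calibre
  should re-estimate width from the residual map, not the binary mask.
- CLAHE amplifies noise together with contrast; on phantoms whose contrast
  is already adequate it slightly degrades the residual's signal-to-noise
  ratio, and it earns its place only on genuinely low-contrast inputs. It
  can be disabled per config (`clahe.enabled: false`).
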