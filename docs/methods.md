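# Methods

This note records the model implemented by `retinotilt`, its assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Receptive-field model

Each retinal ganglion cell is modelled as a linear, isotropic classical
receptive field: an excitatory centre Gaussian of scale `σc` px minus an
inhibitory surround Gaussian of scale `σs = s·σc`, both sampled at integer
pixel offsets on a square window and each renormalized to unit sum before
subtraction. Consequences of this construction:

* the kernel sums *exactly* to zero, so uniform luminance evokes no
  response (lateral inhibition as contrast estimation);
* the kernel has exact 4-fold rotational and mirror symmetry, so
  convolution and correlation coincide and filtering commutes with image
  mirroring;
* filtering is linear, so inverting stimulus contrast exactly negates the
  response.

**Window rule.** The support side is `h·σc + 1` px. When `h·σc` is not an
even integer it is rounded to the nearest even integer so the side stays
odd and the kernel has a unique centre pixel. With the defaults `s = 2`,
`h = 8` the half-width equals `2σs`, which keeps 95.4 % of the surround's
1-D marginal mass inside the window. (Over the 2-D square window the
enclosed surround volume is ≈ 91 %; the 95 % figure refers to the marginal,
and the bound asserted in tests is the marginal one.)

**Parameters.** `σc` (px) sets the scale; the analysis uses ladders of
`σc` rather than octave pyramids because gradual scale steps are what
expose the grouping transitions. `s` (dimensionless, > 1) defaults to 2;
1.6 is used for the dotted-checkerboard experiments and any value > 1 is
accepted. `h ≥ 2` defaults to 8. Boundary handling defaults to replicate
padding; `reflect` and `zero` are available. Replicate padding avoids the
spurious frame contrast that zero padding would inject into the Hough
stage.

**Convolution.** Implemented with `scipy.signal.convolve` (auto
direct/FFT). FFT round-off leaves ±1e−13-scale dust where the exact
response is zero (e.g. inside uniform tiles). Binarization therefore uses
`response > rtol · max|response|` with `rtol = 1e−8`: far below any
physical response, far above round-off. Without this guard the sign dust
binarizes into salt-and-pepper texture inside uniform regions and feeds
spurious line votes to the Hough stage.

**Scale selection.** `suggest_scales(min_feature, max_feature, h, step)`
starts the ladder at the finest integer scale whose window fits within the
smallest feature (`window ≤ min_feature`; for 10 px dots and `h = 8` this
is `σc = 1`, window 9) and extends while the window stays within twice the
largest feature (for 36 px tiles: `σc = 8`, window 65). The comparison at
the lower bound is non-strict so that a window exactly equal to the
feature size is still admitted; the canonical dot case is strict anyway
(9 < 10).

## Stimulus generators

The generators are first-class model inputs, pixel-defined with 0-based
row-major coordinates and luminances in [0, 1]:

* **Café Wall** — `rows × cols` tiles of `tile_px`, alternating
  `lum_dark`/`lum_light` (defaults 0/1), row `r` rolled right by
  `round(r · shift_frac · tile_px)` px with wraparound (default
  `shift_frac = 0.5`, the canonical half-tile displacement; rounding is
  half-up so the half-tile case is parity-independent). Mortar strips of
  `lum_mortar` (default 0.5 — the intermediate brightness the illusion
  requires, enforced as `lum_dark < lum_mortar < lum_light`) lie only
  *between* tile rows; with interior-only mortar the canvas is exactly
  `rows·tile + (rows−1)·mortar` px tall.
* **Munsterberg** — the same generator with mortar forced to 0; the
  model's negative control.
* **Bulge** — a checkerboard with square or disc dots of `dot_px <
  tile_px`, each taking the luminance opposite to the tile under its
  centre. Dot placement is parametric: a corner-offset rule (dots inset
  from each tile corner by a configurable offset) and an explicit
  coordinate list. The published Complex Bulge figure's exact dot
  coordinates are not reproducible from its description (and its printed
  574 × 572 px size is not an integer multiple of the 36 px tile,
  indicating cropping/rescaling), so the generator makes the layout fully
  parametric instead of hard-coding one figure.

What the generators deliberately idealize: stimuli are noise-free,
perfectly periodic, and quantized only on output (8-bit PNG). Passing
tests on these stimuli shows the model's behaviour on the idealized
patterns psychophysics uses, not robustness to photographic noise,
luminance calibration error, or geometric jitter.

## Tilt metrology

Tilt is measured per scale on the binarized response with a straight-line
(ρ, θ) Hough transform restricted to ±`angular_window` (default 10°,
bins of `angle_resolution` = 0.5°) around the four reference orientations
0°/45°/90°/135°. Up to `num_peaks` (100) accumulator peaks per window are
taken with non-maximum suppression; the vote threshold equals
`min_line_len`, since a line with fewer votes cannot yield a qualifying
segment. Along each peak line the binary map is sampled at unit steps
(probing the nearest pixel and its two perpendicular neighbours), runs
separated by more than `fill_gap` empty samples are split, and runs
shorter than `min_line_len` are dropped.

Two design choices matter and were made deliberately:

* **Segment orientation comes from the traced endpoints, not the
  accumulator bin.** A tilted accumulator line that merely grazes an
  exactly-horizontal edge reconstructs a run whose endpoints lie on that
  edge and therefore reports ≈ 0°; only runs that genuinely follow a
  tilted structure report a tilted orientation. This is what lets the
  Munsterberg control come out clean instead of inheriting the tilt of
  whatever accumulator bin grazed its straight edges. Segments whose
  endpoint orientation falls outside the window are discarded, keeping
  |deviation| ≤ `angular_window` invariant.
* **Stimulus-scaled defaults:** `min_line_len = 1.5·tile_px` and
  `fill_gap = tile_px/10`. A segment only evidences grouping *across*
  pattern elements — a mortar cue joining tiles of adjacent rows — if it
  is longer than a single tile; gaps are bridged only when much smaller
  than a tile, which closes blur-scale breaks inside one twisted-cord
  element without chaining distinct elements. Generic defaults
  (`min_line_len = 50`, `fill_gap = 10`) apply when no stimulus spec is
  available. All values are exposed in `HoughConfig`.

Ties in peak extraction are resolved by scikit-image's deterministic
ordering; the whole pipeline is deterministic, and the residual
asymmetry between a pattern and its mirror (tie-breaking plus
rasterization) is at the few-percent level of the measured tilt.

Orientation convention: degrees in [0, 180), 0 along the horizontal axis,
increasing counter-clockwise with the y-axis pointing up (so a positive
near-horizontal deviation raises the right-hand end on screen).

## Grouping analysis

The "twisted cord" of the Café Wall — the grouping of a mortar-line
segment with tiles of the rows above and below — is detected by connected
components (8-connectivity) of the binary map: a cord is present when a
component contains the centre pixel of a dark–dark mortar junction (the
mortar point farthest from any light tile, where only the mortar's own
intermediate luminance can drive a positive response) together with
pixels in both adjacent tile rows. The centre-pixel condition is what
separates a genuine mortar-line response from the blur of an adjacent
light tile leaking into the mortar band: on the 200 px-tile/8 px-mortar
wall the cord is present for σc = 4–16 and gone from σc = 20 on, matching
the scale at which the percept hands over from mortar cues to the
vertical zigzag grouping of same-coloured tiles.

## Rendering

Signed responses are displayed with a declared "jet-white" table: a
symmetric diverging map, zero → white, positive → warm up to dark red,
negative → cool down to dark blue, normalized by max |response|. The
anchor positions are mirror-symmetric and the colour rows reverse into
their own R↔B swap, so negating a response exactly swaps warm and cool
channels. The table is presentation-only; no analysis depends on it
beyond the declared endpoints.

## Problem sizes and numerical tolerances

The test suite exercises the full published geometries: Café Wall and
Munsterberg at 3 × 8 tiles of 200 px (616 × 1600 px canvas, six scales
σc = 4–24) and a 15 × 15-tile, 36 px-tile, 10 px-dot dotted checkerboard
(540 × 540 px, eight scales σc = 1–8, s = 1.6). Exact-arithmetic claims
(kernel zero-sum, symmetry) are asserted at 1e−12 of the weight scale;
convolution equivalences at 1e−9; zero-DC responses at 1e−10. The direct
quadruple-loop convolution oracle runs on 64 × 64 random images at
σc ≤ 4.

## Known limitations

* Classical receptive fields only: no extended/disinhibitory surround
  (three-Gaussian nCRF), no orientation-selective or colour-opponent
  channels, and no second-stage integration of local tilt cues into a
  global percept — the Hough statistics quantify the cues the retinal
  stage makes available, not the perceived magnitude.
* Hough deviations are quantized by endpoint rasterization
  (≈ atan(1/length); ~0.2° for tile-spanning segments).
* The mirror-symmetry of detection holds at distribution level, not
  segment-for-segment, because of accumulator tie-breaking.
* Predicted tilt angles are not calibrated against psychophysical tilt
  magnitudes; comparisons across patterns and scales are the intended
  use.
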