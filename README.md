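# retinotilt

Multiscale centre–surround (Difference-of-Gaussians) retinal filtering and
Hough-space tilt metrology for tile-illusion patterns.

## The scientific problem

In the **Café Wall illusion**, physically parallel "mortar" lines between
phase-shifted rows of dark and light tiles appear to converge and diverge.
Removing the mortar (the **Munsterberg pattern**) removes the illusion;
stamping small contrast-opposite dots onto a plain checkerboard (**Bulge
patterns**) makes straight checkerboard edges appear to bow. A long line of
work attributes the *origin* of these tilt percepts to the earliest stage of
vision: retinal ganglion cells with classical centre–surround receptive
fields, acting at many spatial scales at once.

`retinotilt` is a tool for researchers in computational visual neuroscience
who want to generate these stimuli parametrically, simulate the retinal
encoding, and *measure* the tilt that emerges — rather than just look at it.

## The model

A ganglion cell's receptive field is the classical Difference of Gaussians

```
DoG_{σc, sσc}(x, y) = G(x, y; σc) − G(x, y; s·σc),
G(x, y; σ) = 1/(2πσ²) · exp(−(x² + y²) / 2σ²)
```

with **surround ratio** `s = σ_surround/σ_centre` (default 2, with 1.6 used
for Bulge patterns) and a square support of side `h·σc + 1` px (**window
ratio** `h = 8`, which keeps ≥ 95 % of the surround Gaussian's marginal mass
inside the filter). Each truncated Gaussian is renormalized to unit sum, so
the kernel has exactly zero DC response: filtering implements lateral
inhibition, responding only to contrast.

Convolving a stimulus with this kernel over a ladder of centre scales
`σc` — tuned to the pattern's feature sizes, from below the smallest feature
(mortar height, dot size) to beyond the tile size — yields the model's
retinal encoding: an **edge map stack** of signed responses and their
binarized (response > 0, ON-centre) forms. Tilt is then quantified per scale
by a straight-line Hough analysis restricted to narrow angular windows
around the four reference orientations (0°, 45°, 90°, 135°): accumulator
peaks are extracted per window, line segments are reconstructed along each
peak with gap filling and a minimum-length filter, and each group reports
its segment count and mean absolute deviation in degrees.

## Worked example

```python
import retinotilt as rt
from retinotilt.retina import has_twisted_cord
from retinotilt.tiltmetry import HoughConfig, tilt_report

spec = rt.StimulusSpec(kind="cafe_wall", rows=3, cols=8,
                       tile_px=200, mortar_px=8, shift_frac=0.5)
image = rt.generate_cafe_wall(spec)          # 616 x 1600 px
stack = rt.edge_map(image, [4, 8, 12, 16, 20, 24], s=2, h=8)
report = tilt_report(stack, HoughConfig.for_spec(spec))
for sigma in stack.scales:
    print(sigma, has_twisted_cord(stack.level(sigma)[1], spec),
          report.count(sigma, 0.0), report.mean_abs_deviation(sigma, 0.0))
```

prints

```
stimulus: 616 x 1600 px
sigma    4: twisted cord True   near-horizontal segments 18  mean |tilt|  3.98 deg
sigma    8: twisted cord True   near-horizontal segments 20  mean |tilt|  5.50 deg
sigma   12: twisted cord True   near-horizontal segments 14  mean |tilt|  4.42 deg
sigma   16: twisted cord True   near-horizontal group empty
sigma   20: twisted cord False  near-horizontal segments 13  mean |tilt|  9.13 deg
sigma   24: twisted cord False  near-horizontal segments 14  mean |tilt|  8.64 deg
```

Read this as the illusion's life cycle across scales. At fine scales
(σc ≤ 12, comparable to the 8 px mortar) the binarized response groups each
mortar line with the tiles of the rows above and below — the "twisted cord"
elements — and the near-horizontal Hough group measures their tilt at
roughly 4–5.5° from horizontal. By σc = 20 the mortar cue has dissolved
(`twisted cord False`); the segments appearing at coarse scales belong to
the large-scale zigzag regrouping of same-coloured tiles, not to mortar
lines. Running the identical analysis on the Munsterberg control
(`mortar_px=0`) yields an *empty* near-horizontal group at σc = 8: no
mortar, no tilt cue — and mirroring the Café Wall flips the sign of every
deviation.

The same pipeline is scriptable from a shell via a YAML config:

```sh
retinotilt run config.yaml     # stimulus, edge maps, tilt report, renders
retinotilt generate config.yaml
retinotilt edgemap config.yaml
retinotilt tilt config.yaml
retinotilt render out/
```

`run` writes per-scale response/binary PNGs, jet-white renderings (zero
response shown white, ON warm, OFF cool), Hough-line overlays, a CSV of all
segments, a JSON tilt summary, and a manifest; re-running a config is
byte-identical.

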