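"""Parametric generators for tile-illusion stimuli.

The patterns studied here are "tile illusions": regular black/white tilings
whose apparent geometry differs from their physical geometry.  Three
families are generated, each as a grayscale luminance grid in [0, 1]:

* **Café Wall** — rows of alternating dark/light tiles, each row phase
  shifted horizontally, with thin "mortar" strips of intermediate luminance
  between rows.  The mortar lines are physically parallel but appear to
  converge/diverge.
* **Munsterberg** — the same tiling with the mortar removed (mortar height
  0).  No tilt is perceived; it serves as the negative control.
* **Bulge** — a plain checkerboard with small contrast-opposite dots
  stamped near tile corners (or at explicit coordinates), inducing an
  apparent bulge of the physically straight checkerboard edges.

Coordinates are 0-based, row-major, origin at the top-left; all lengths are
in pixels.  Images are written as 8-bit grayscale PNG.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "StimulusSpec",
    "LuminanceImage",
    "generate",
    "generate_cafe_wall",
    "generate_munsterberg",
    "generate_checkerboard",
    "generate_bulge",
    "load_spec",
    "spec_from_mapping",
]

KINDS = ("cafe_wall", "munsterberg", "checkerboard", "bulge")
DOT_RULES = ("corner_offset", "explicit")


@dataclass(frozen=True)
class LuminanceImage:
    """A 2-D grid of luminance values in [0, 1].

    Row-major, origin top-left, 0-based indexing; ``values[r, c]`` is the
    luminance of the pixel in row ``r``, column ``c``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("luminance grid must be 2-D with height, width >= 1")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("luminance values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_png(self, path: str | Path) -> Path:
        """Write as 8-bit grayscale PNG (luminance * 255, rounded)."""
        path = Path(path)
        arr = np.rint(self.values * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path, format="PNG")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "LuminanceImage":
        """Load a grayscale image (PNG/TIFF/...); colour inputs are converted."""
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float64)
        return cls(arr / 255.0)


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of a tile-illusion pattern.

    Parameters
    ----------
    kind
        One of ``cafe_wall``, ``munsterberg``, ``checkerboard``, ``bulge``.
    rows, cols
        Tile-row and tile-column counts.
    tile_px
        Tile side length in px.
    mortar_px
        Mortar strip height in px (0 allowed; forced to 0 for Munsterberg).
    shift_frac
        Per-row horizontal phase shift as a fraction of the tile width,
        in [0, 1).  Row ``r`` is shifted right by ``round(r * shift_frac *
        tile_px)`` px with horizontal wraparound.
    lum_dark, lum_light, lum_mortar
        Luminances in [0, 1].  When mortar is present the mortar luminance
        must lie strictly between the tile luminances (the illusion requires
        mortar of intermediate brightness).
    dot_px
        Dot side/diameter in px (bulge only; must be smaller than the tile).
    dot_layout
        Dot placement rule (bulge only): a mapping with ``rule`` equal to
        ``"corner_offset"`` (keys ``offset`` px and optionally ``corners``,
        a subset of ``("tl", "tr", "bl", "br")``) or ``"explicit"`` (key
        ``positions``: list of (row, col) top-left corners of dot bounding
        boxes).  Optional key ``shape``: ``"square"`` (default) or ``"disc"``.
    start_dark
        Parity of the first tile of each row (checkerboard alternates this
        per row by construction).
    """

    kind: str
    rows: int
    cols: int
    tile_px: int
    mortar_px: int = 0
    shift_frac: float = 0.5
    lum_dark: float = 0.0
    lum_light: float = 1.0
    lum_mortar: float = 0.5
    dot_px: int = 0
    dot_layout: Mapping[str, Any] | None = None
    start_dark: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; expected one of {KINDS}")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.tile_px < 1:
            raise ValueError("tile_px must be >= 1")
        if self.mortar_px < 0:
            raise ValueError("mortar_px must be >= 0")
        if not 0.0 <= self.shift_frac < 1.0:
            raise ValueError("shift_frac must lie in [0, 1)")
        for name in ("lum_dark", "lum_light", "lum_mortar"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lum_dark >= self.lum_light:
            raise ValueError("lum_dark must be < lum_light")
        if self.mortar_px > 0 and not (self.lum_dark < self.lum_mortar < self.lum_light):
            raise ValueError(
                "mortar luminance must lie strictly between the tile luminances "
                "(lum_dark < lum_mortar < lum_light) when mortar_px > 0"
            )
        if self.kind == "bulge":
            if self.dot_px >= 1 and self.dot_px >= self.tile_px:
                raise ValueError("bulge dots must be smaller than the tiles (dot_px < tile_px)")
            if self.dot_layout is not None:
                rule = dict(self.dot_layout).get("rule")
                if rule not in DOT_RULES:
                    raise ValueError(f"dot_layout rule must be one of {DOT_RULES}, got {rule!r}")

    def to_mapping(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["dot_layout"] is not None:
            d["dot_layout"] = dict(d["dot_layout"])
        return d


def spec_from_mapping(mapping: Mapping[str, Any]) -> StimulusSpec:
    """Build a :class:`StimulusSpec` from a plain mapping (YAML/JSON dict)."""
    known = {f.name for f in dataclasses.fields(StimulusSpec)}
    extra = set(mapping) - known
    if extra:
        raise ValueError(f"unknown StimulusSpec fields: {sorted(extra)}")
    return StimulusSpec(**dict(mapping))


def load_spec(path: str | Path) -> StimulusSpec:
    """Read a StimulusSpec from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping of StimulusSpec fields")
    return spec_from_mapping(data)


def _row_shift(spec: StimulusSpec, row: int) -> int:
    # round-half-up so the shift is deterministic at .5 (Python's round
    # rounds half to even, which would make the canonical half-tile shift
    # depend on tile parity)
    return int(np.floor(row * spec.shift_frac * spec.tile_px + 0.5))


def _tile_row(spec: StimulusSpec, width: int, parity: int) -> np.ndarray:
    tile_index = np.arange(width) // spec.tile_px
    dark = (tile_index + parity) % 2 == 0
    return np.where(dark, spec.lum_dark, spec.lum_light)


def generate_cafe_wall(spec: StimulusSpec) -> LuminanceImage:
    """Generate a Café Wall pattern.

    The image is ``rows * tile_px + (rows - 1) * mortar_px`` pixels tall and
    ``cols * tile_px`` wide: mortar strips sit only *between* consecutive
    tile rows (no outer mortar border).  Tiles alternate dark/light along
    each row and row ``r`` is rolled right by ``round(r * shift_frac *
    tile_px)`` px with wraparound.
    """
    if spec.kind not in ("cafe_wall", "munsterberg"):
        raise ValueError(f"expected a cafe_wall spec, got kind={spec.kind!r}")
    height = spec.rows * spec.tile_px + (spec.rows - 1) * spec.mortar_px
    width = spec.cols * spec.tile_px
    img = np.empty((height, width), dtype=np.float64)
    parity = 0 if spec.start_dark else 1
    y = 0
    for r in range(spec.rows):
        row = np.roll(_tile_row(spec, width, parity), _row_shift(spec, r))
        img[y : y + spec.tile_px] = row
        y += spec.tile_px
        if r < spec.rows - 1 and spec.mortar_px > 0:
            img[y : y + spec.mortar_px] = spec.lum_mortar
            y += spec.mortar_px
    return LuminanceImage(img)


def generate_munsterberg(spec: StimulusSpec) -> LuminanceImage:
    """Generate a Munsterberg pattern: a Café Wall without mortar lines."""
    if spec.kind not in ("munsterberg", "cafe_wall"):
        raise ValueError(f"expected a munsterberg spec, got kind={spec.kind!r}")
    return generate_cafe_wall(dataclasses.replace(spec, kind="cafe_wall", mortar_px=0))


def generate_checkerboard(spec: StimulusSpec) -> LuminanceImage:
    """Generate a plain checkerboard (row parity alternates, no mortar)."""
    width = spec.cols * spec.tile_px
    base = 0 if spec.start_dark else 1
    rows = [
        np.broadcast_to(_tile_row(spec, width, (base + r) % 2), (spec.tile_px, width))
        for r in range(spec.rows)
    ]
    return LuminanceImage(np.vstack(rows))


def mortar_bands(spec: StimulusSpec) -> list[tuple[int, int]]:
    """Half-open row ranges ``(top, bottom)`` of the mortar strips."""
    if spec.mortar_px <= 0:
        return []
    bands = []
    for r in range(spec.rows - 1):
        top = (r + 1) * spec.tile_px + r * spec.mortar_px
        bands.append((top, top + spec.mortar_px))
    return bands


def _dot_positions(spec: StimulusSpec) -> list[tuple[int, int]]:
    if spec.dot_layout is None or spec.dot_px < 1:
        return []
    layout = dict(spec.dot_layout)
    rule = layout["rule"]
    d, t = spec.dot_px, spec.tile_px
    if rule == "explicit":
        return [(int(r), int(c)) for r, c in layout.get("positions", [])]
    if rule == "corner_offset":
        offset = int(layout.get("offset", 2))
        corners = tuple(layout.get("corners", ("tl", "tr", "bl", "br")))
        positions = []
        for i in range(spec.rows):
            for j in range(spec.cols):
                top, left = i * t, j * t
                for corner in corners:
                    r = top + offset if corner[0] == "t" else top + t - offset - d
                    c = left + offset if corner[1] == "l" else left + t - offset - d
                    positions.append((r, c))
        return positions
    raise ValueError(f"unknown dot_layout rule {rule!r}")


def generate_bulge(spec: StimulusSpec) -> LuminanceImage:
    """Generate a checkerboard with superimposed contrast-opposite dots.

    Each dot (square or disc of side/diameter ``dot_px``) takes the
    luminance opposite to the tile under its centre.  Dots falling outside
    the image are rejected.
    """
    if spec.kind != "bulge":
        raise ValueError(f"expected a bulge spec, got kind={spec.kind!r}")
    img = generate_checkerboard(spec).values.copy()
    height, width = img.shape
    d = spec.dot_px
    shape = dict(spec.dot_layout or {}).get("shape", "square")
    if shape not in ("square", "disc"):
        raise ValueError(f"dot shape must be 'square' or 'disc', got {shape!r}")
    base = 0 if spec.start_dark else 1
    for r, c in _dot_positions(spec):
        if r < 0 or c < 0 or r + d > height or c + d > width:
            raise ValueError(f"dot at (row={r}, col={c}) with dot_px={d} falls outside the image")
        centre_r, centre_c = r + d // 2, c + d // 2
        tile_dark = (base + centre_r // spec.tile_px + centre_c // spec.tile_px) % 2 == 0
        lum = spec.lum_light if tile_dark else spec.lum_dark
        if shape == "square":
            img[r : r + d, c : c + d] = lum
        else:
            from skimage.draw import disk

            rr, cc = disk((r + (d - 1) / 2.0, c + (d - 1) / 2.0), d / 2.0, shape=img.shape)
            img[rr, cc] = lum
    return LuminanceImage(img)


_GENERATORS = {
    "cafe_wall": generate_cafe_wall,
    "munsterberg": generate_munsterberg,
    "checkerboard": generate_checkerboard,
    "bulge": generate_bulge,
}


def generate(spec: StimulusSpec) -> LuminanceImage:
    """Dispatch to the generator for ``spec.kind``."""
    return _GENERATORS[spec.kind](spec)
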