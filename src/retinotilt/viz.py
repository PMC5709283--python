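"""Figure-style rendering: jet-white colormap, montages and line overlays.

The signed DoG responses are displayed with a symmetric diverging map
("jet white"): zero response renders white, increasingly positive
responses run through warm colours to dark red, increasingly negative
ones through cool colours to dark blue, with the range set by the maximum
absolute response.  Binary maps with detected Hough segments are overlaid
in the convention of the tilt figures: segments in green, the longest
segment per scale in blue, segment endpoints marked with red/yellow
crosses.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import line as draw_line

from .tiltmetry import LineSegment

__all__ = ["JETWHITE_POSITIONS", "JETWHITE_COLORS", "render_jetwhite", "montage", "overlay_segments"]

# Declared jet-white colour table: standard jet endpoints with the central
# band replaced by white.  Positions are mirror-symmetric about 0.5 and the
# colour rows reverse into their own R<->B swap, so negating a response
# swaps the warm and cool channels exactly.
JETWHITE_POSITIONS = np.array([0.0, 0.125, 0.35, 0.5, 0.65, 0.875, 1.0])
JETWHITE_COLORS = np.array(
    [
        [0.0, 0.0, 0.5],  # darkest blue: strongest negative (OFF) response
        [0.0, 0.375, 1.0],
        [0.375, 0.875, 1.0],
        [1.0, 1.0, 1.0],  # zero response
        [1.0, 0.875, 0.375],
        [1.0, 0.375, 0.0],
        [0.5, 0.0, 0.0],  # darkest red: strongest positive (ON) response
    ]
)


def render_jetwhite(response: np.ndarray) -> np.ndarray:
    """Map a signed response to RGB floats in [0, 1] (zero -> white).

    The response is normalized symmetrically by its maximum absolute
    value; an all-zero response renders all-white.
    """
    resp = np.asarray(response, dtype=np.float64)
    peak = np.max(np.abs(resp)) if resp.size else 0.0
    u = np.full(resp.shape, 0.5) if peak == 0 else 0.5 * (1.0 + resp / peak)
    rgb = np.stack(
        [np.interp(u, JETWHITE_POSITIONS, JETWHITE_COLORS[:, k]) for k in range(3)],
        axis=-1,
    )
    return rgb


def _to_uint8(rgb: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)


def save_rgb(rgb: np.ndarray, path: str | Path) -> Path:
    """Write an RGB float image in [0, 1] as PNG."""
    path = Path(path)
    Image.fromarray(_to_uint8(rgb), mode="RGB").save(path, format="PNG")
    return path


def montage(panels: Sequence[np.ndarray], ncols: int = 3, pad: int = 4) -> np.ndarray:
    """Tile equally shaped RGB panels row-major with white gutters.

    Scales increase first left-to-right within a row, then row to row —
    the layout used for multiscale edge-map figures.
    """
    if not panels:
        raise ValueError("montage requires at least one panel")
    panels = [p if p.ndim == 3 else np.repeat(p[..., None].astype(np.float64), 3, axis=-1) for p in panels]
    h, w = panels[0].shape[:2]
    if any(p.shape[:2] != (h, w) for p in panels):
        raise ValueError("all montage panels must share one shape")
    ncols = min(ncols, len(panels))
    nrows = -(-len(panels) // ncols)
    out = np.ones((nrows * h + (nrows + 1) * pad, ncols * w + (ncols + 1) * pad, 3))
    for i, panel in enumerate(panels):
        r, c = divmod(i, ncols)
        top = pad + r * (h + pad)
        left = pad + c * (w + pad)
        out[top : top + h, left : left + w] = panel
    return out


def _cross(rgb: np.ndarray, row: int, col: int, color: tuple[float, float, float], arm: int = 3) -> None:
    h, w = rgb.shape[:2]
    for d in range(-arm, arm + 1):
        if 0 <= row + d < h:
            rgb[row + d, col] = color
        if 0 <= col + d < w:
            rgb[row, col + d] = color


def overlay_segments(
    binary: np.ndarray,
    segments: Sequence[LineSegment],
    longest_index: int | None = None,
) -> np.ndarray:
    """Draw detected segments on a binary map (green; longest blue).

    Endpoints are marked with red (start) and yellow (end) crosses.
    Returns an RGB float image.
    """
    base = (np.asarray(binary) > 0).astype(np.float64)
    rgb = np.repeat(base[..., None], 3, axis=-1)
    for i, seg in enumerate(segments):
        (r0, c0), (r1, c1) = seg.endpoints
        rr, cc = draw_line(r0, c0, r1, c1)
        rgb[rr, cc] = (0.0, 0.0, 1.0) if i == longest_index else (0.0, 0.8, 0.0)
    for seg in segments:
        (r0, c0), (r1, c1) = seg.endpoints
        _cross(rgb, r0, c0, (1.0, 0.0, 0.0))
        _cross(rgb, r1, c1, (1.0, 1.0, 0.0))
    return rgb
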