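"""Tilt quantification of binary edge maps via the Hough transform.

The apparent tilt predicted by the retinal model lives in the binarized
DoG edge maps: near-horizontal mortar cues in the Café Wall pattern come
out as line segments deviating slightly from 0 degrees.  To measure this,
a straight-line (rho, theta) Hough accumulation is restricted to narrow
angular windows around four reference orientations — horizontal (0°),
the two diagonals (45°, 135°) and vertical (90°) — peaks are extracted
per window, and line segments are reconstructed along each peak line with
gap filling and a minimum-length filter.  Per scale and per reference
orientation the report carries the detected segments, their count, the
mean absolute deviation from the reference in degrees, and the longest
segment.

Orientation convention: degrees in [0, 180), 0 along the horizontal image
axis, increasing counter-clockwise (with the origin at the top-left this
means a positive deviation from horizontal tilts the right end of the
line upwards on screen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from skimage.transform import hough_line, hough_line_peaks

from .retina import EdgeMapStack
from .stimuli import StimulusSpec

__all__ = [
    "HoughConfig",
    "LineSegment",
    "TiltReport",
    "detect_lines",
    "tilt_report",
]

REF_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


def _wrap_deviation(delta: float) -> float:
    """Wrap an orientation difference to (-90, 90]."""
    return -((90.0 - delta) % 180.0 - 90.0)


@dataclass(frozen=True)
class HoughConfig:
    """Parameters of the Hough tilt analysis.

    ``angular_window`` is the half-width in degrees around each reference
    orientation (must stay below 22.5° so windows do not overlap);
    ``angle_resolution`` the Hough bin width in degrees; ``min_line_len``
    and ``fill_gap`` the segment reconstruction parameters in px;
    ``num_peaks`` the maximum accumulator peaks kept per reference window.
    ``min_distance``/``min_angle`` are the peak non-maximum-suppression
    radii in accumulator bins.
    """

    angular_window: float = 10.0
    angle_resolution: float = 0.5
    min_line_len: int = 50
    fill_gap: int = 10
    num_peaks: int = 100
    ref_orientations: tuple[float, ...] = REF_ORIENTATIONS
    min_distance: int = 9
    min_angle: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.angular_window < 22.5:
            raise ValueError("angular_window must lie in (0, 22.5) degrees")
        if self.angle_resolution <= 0:
            raise ValueError("angle_resolution must be > 0")
        if self.min_line_len < 2:
            raise ValueError("min_line_len must be >= 2")
        if self.fill_gap < 0:
            raise ValueError("fill_gap must be >= 0")
        if self.num_peaks < 1:
            raise ValueError("num_peaks must be >= 1")

    @classmethod
    def for_spec(cls, spec: StimulusSpec, **overrides: Any) -> "HoughConfig":
        """Stimulus-adapted defaults.

        A segment only evidences grouping *across* pattern elements (e.g.
        a mortar-line cue joining tiles of adjacent rows) if it is longer
        than a single tile, so ``min_line_len = 1.5 * tile_px``; gaps are
        bridged only when much smaller than a tile (``fill_gap =
        tile_px / 10``), which closes the blur-scale breaks inside one cord
        without chaining distinct elements together.
        """
        params: dict[str, Any] = {
            "min_line_len": max(2, (3 * spec.tile_px) // 2),
            "fill_gap": max(1, spec.tile_px // 10),
        }
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class LineSegment:
    """A detected straight segment with its orientation bookkeeping.

    ``endpoints`` are two (row, col) pixel pairs; ``theta`` the segment
    orientation in degrees in [0, 180); ``ref`` the nearest reference
    orientation and ``deviation`` the signed angular deviation from it
    (|deviation| <= angular_window by construction).
    """

    endpoints: tuple[tuple[int, int], tuple[int, int]]
    theta: float
    length: float
    ref: float
    deviation: float


def _theta_grid(ref: float, config: HoughConfig) -> np.ndarray:
    """Hough normal angles (radians) covering ref +/- angular_window."""
    n = int(round(2 * config.angular_window / config.angle_resolution)) + 1
    phis = ref + np.linspace(-config.angular_window, config.angular_window, n)
    thetas = 90.0 - phis  # segment orientation phi -> normal angle theta
    thetas = (thetas + 90.0) % 180.0 - 90.0  # wrap into [-90, 90)
    return np.deg2rad(thetas)


def _trace_segments(
    binary: np.ndarray,
    angle: float,
    dist: float,
    ref: float,
    config: HoughConfig,
) -> list[LineSegment]:
    """Walk along the Hough line and cut it into on-pixel runs.

    The line is sampled at unit steps; at each step the nearest pixel and
    its two perpendicular neighbours are probed so 1-px-wide rasterized
    lines are followed robustly.  Runs separated by more than ``fill_gap``
    off samples are split; runs shorter than ``min_line_len`` are dropped.
    """
    height, width = binary.shape
    sin_t, cos_t = np.sin(angle), np.cos(angle)
    # point on line: (x, y) = dist * (cos, sin) + t * (-sin, cos)
    corners_t = [
        -x * sin_t + y * cos_t for x in (0.0, width - 1.0) for y in (0.0, height - 1.0)
    ]
    t = np.arange(np.floor(min(corners_t)), np.ceil(max(corners_t)) + 1.0)
    xs = dist * cos_t - t * sin_t
    ys = dist * sin_t + t * cos_t
    on = np.zeros(t.shape, dtype=bool)
    pix_r = np.zeros(t.shape, dtype=np.int64)
    pix_c = np.zeros(t.shape, dtype=np.int64)
    for off in (0.0, -1.0, 1.0):  # centre first, then perpendicular neighbours
        ci = np.rint(xs + off * cos_t).astype(np.int64)
        ri = np.rint(ys + off * sin_t).astype(np.int64)
        valid = (ri >= 0) & (ri < height) & (ci >= 0) & (ci < width)
        hit = np.zeros(t.shape, dtype=bool)
        hit[valid] = binary[ri[valid], ci[valid]]
        new = hit & ~on
        pix_r[new] = ri[new]
        pix_c[new] = ci[new]
        on |= hit
    idx = np.flatnonzero(on)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > config.fill_gap + 1)
    segments = []
    for chunk in np.split(idx, breaks + 1):
        p0 = (int(pix_r[chunk[0]]), int(pix_c[chunk[0]]))
        p1 = (int(pix_r[chunk[-1]]), int(pix_c[chunk[-1]]))
        length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
        if length < config.min_line_len:
            continue
        # orientation from the traced endpoints, not the accumulator bin:
        # a line grazing an exactly-horizontal edge reconstructs a run with
        # both endpoints on that edge and so reports 0 deg, while a run that
        # genuinely follows a tilted structure reports its true slope
        phi = float(np.degrees(np.arctan2(-(p1[0] - p0[0]), p1[1] - p0[1])) % 180.0)
        deviation = _wrap_deviation(phi - ref)
        if abs(deviation) > config.angular_window:
            continue
        segments.append(
            LineSegment(
                endpoints=(p0, p1),
                theta=phi,
                length=length,
                ref=ref,
                deviation=deviation,
            )
        )
    return segments


def detect_lines(binary: np.ndarray, config: HoughConfig | None = None) -> list[LineSegment]:
    """Detect line segments near the reference orientations.

    Runs a (rho, theta) Hough accumulation restricted to each reference
    orientation's angular window, extracts up to ``num_peaks`` peaks per
    window and reconstructs segments along each peak line.  Deterministic;
    an empty image yields an empty list.
    """
    config = config or HoughConfig()
    binary = np.asarray(binary) > 0
    if binary.ndim != 2:
        raise ValueError("binary image must be 2-D")
    if not binary.any():
        return []
    segments: list[LineSegment] = []
    for ref in config.ref_orientations:
        thetas = _theta_grid(ref, config)
        accum, angles, dists = hough_line(binary.astype(np.uint8), theta=thetas)
        # a peak with fewer votes than min_line_len cannot yield a
        # qualifying segment, so that is the natural accumulator threshold
        peaks = hough_line_peaks(
            accum,
            angles,
            dists,
            num_peaks=config.num_peaks,
            threshold=float(config.min_line_len),
            min_distance=config.min_distance,
            min_angle=config.min_angle,
        )
        for _, angle, dist in zip(*peaks):
            segments.extend(_trace_segments(binary, float(angle), float(dist), ref, config))
    return segments


@dataclass(frozen=True)
class TiltReport:
    """Per-scale, per-orientation tilt statistics of an edge-map stack."""

    scales: tuple[float, ...]
    segments: Mapping[float, tuple[LineSegment, ...]]
    config: HoughConfig

    def group(self, scale: float, ref: float) -> list[LineSegment]:
        """Segments of a scale assigned to one reference orientation."""
        return [seg for seg in self.segments[scale] if seg.ref == ref]

    def count(self, scale: float, ref: float) -> int:
        return len(self.group(scale, ref))

    def mean_abs_deviation(self, scale: float, ref: float) -> float:
        """Mean absolute tilt in degrees (NaN for an empty group)."""
        group = self.group(scale, ref)
        if not group:
            return float("nan")
        return float(np.mean([abs(seg.deviation) for seg in group]))

    def longest_index(self, scale: float) -> int | None:
        """Index (within the scale's list) of the longest segment."""
        segs = self.segments[scale]
        if not segs:
            return None
        return int(np.argmax([seg.length for seg in segs]))

    def longest(self, scale: float) -> LineSegment | None:
        idx = self.longest_index(scale)
        return None if idx is None else self.segments[scale][idx]

    def to_frame(self) -> pd.DataFrame:
        """One row per segment: scale, ref, theta, deviation, length, endpoints."""
        rows = []
        for scale in self.scales:
            longest = self.longest_index(scale)
            for i, seg in enumerate(self.segments[scale]):
                (r0, c0), (r1, c1) = seg.endpoints
                rows.append(
                    {
                        "scale": scale,
                        "ref": seg.ref,
                        "theta": seg.theta,
                        "deviation": seg.deviation,
                        "length": seg.length,
                        "r0": r0,
                        "c0": c0,
                        "r1": r1,
                        "c1": c1,
                        "is_longest": i == longest,
                    }
                )
        columns = ["scale", "ref", "theta", "deviation", "length", "r0", "c0", "r1", "c1", "is_longest"]
        return pd.DataFrame(rows, columns=columns)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def summary(self) -> dict[str, Any]:
        """Nested per-scale, per-orientation statistics (JSON-friendly)."""
        out: dict[str, Any] = {"scales": list(self.scales), "per_scale": {}}
        for scale in self.scales:
            per_ref = {}
            for ref in self.config.ref_orientations:
                group = self.group(scale, ref)
                mad = self.mean_abs_deviation(scale, ref)
                per_ref[f"{ref:g}"] = {
                    "count": len(group),
                    "mean_abs_deviation_deg": None if not group else mad,
                }
            longest = self.longest(scale)
            out["per_scale"][f"{scale:g}"] = {
                "orientations": per_ref,
                "longest": None
                if longest is None
                else {
                    "ref": longest.ref,
                    "theta": longest.theta,
                    "deviation": longest.deviation,
                    "length": longest.length,
                    "endpoints": [list(longest.endpoints[0]), list(longest.endpoints[1])],
                },
            }
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), sort_keys=True, indent=2))
        return path


def tilt_report(stack: EdgeMapStack, config: HoughConfig | None = None) -> TiltReport:
    """Run :func:`detect_lines` on every scale of an edge-map stack."""
    config = config or HoughConfig()
    segments = {
        scale: tuple(detect_lines(binary, config))
        for scale, binary in zip(stack.scales, stack.binaries)
    }
    return TiltReport(scales=stack.scales, segments=segments, config=config)
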