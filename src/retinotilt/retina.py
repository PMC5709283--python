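"""Centre-surround receptive-field filtering at multiple scales.

A retinal ganglion cell with a classical (circular, isotropic) receptive
field is modelled as a linear Difference-of-Gaussians operator: an
excitatory centre Gaussian of scale ``sigma_c`` minus a broader inhibitory
surround Gaussian of scale ``s * sigma_c``, where ``s > 1`` is the
*surround ratio*.  Convolving a luminance image with this zero-DC kernel
implements lateral inhibition: the signed response is positive where the
centre sees more light than its surround (ON-centre activation) and
negative in the opposite case.

The kernel is truncated to a square window of side ``h * sigma_c + 1``
(the *window ratio* ``h`` keeps the significant mass of both Gaussians
inside the window), and each truncated Gaussian is renormalized to unit
sum before subtraction so that the kernel sums exactly to zero.

Filtering the same stimulus over a strictly increasing ladder of centre
scales yields the model's retinal encoding: an :class:`EdgeMapStack` of
signed responses and their binarized (response > 0) forms, one per scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import signal
from skimage import measure

from .stimuli import LuminanceImage, StimulusSpec, mortar_bands

__all__ = [
    "DoGParams",
    "DoGKernel",
    "EdgeMapStack",
    "window_size",
    "normalized_gaussian",
    "dog_kernel",
    "apply_dog",
    "binarize",
    "edge_map",
    "suggest_scales",
    "mortar_bridging_labels",
    "has_twisted_cord",
]

BOUNDARY_MODES = {"replicate": "edge", "reflect": "reflect", "zero": "constant"}

#: Default surround ratio sigma_surround / sigma_centre.
DEFAULT_SURROUND_RATIO = 2.0
#: Default window ratio (kernel side = h * sigma_c + 1).
DEFAULT_WINDOW_RATIO = 8.0


@dataclass(frozen=True)
class DoGParams:
    """Parameters of a single DoG receptive field.

    ``sigma_c`` is the centre-Gaussian scale in px, ``s`` the surround
    ratio (sigma_s / sigma_c, dimensionless, > 1) and ``h`` the window
    ratio (dimensionless, >= 2 so the window covers at least the centre
    lobe).
    """

    sigma_c: float
    s: float = DEFAULT_SURROUND_RATIO
    h: float = DEFAULT_WINDOW_RATIO

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be > 0")
        if self.s <= 1:
            raise ValueError("surround ratio s must be > 1")
        if self.h < 2:
            raise ValueError("window ratio h must be >= 2")

    @property
    def sigma_s(self) -> float:
        return self.s * self.sigma_c


@dataclass(frozen=True)
class DoGKernel:
    """A realized DoG filter: ``weights`` on a square odd-sided grid."""

    params: DoGParams
    side: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.side, self.side) or self.side % 2 == 0:
            raise ValueError("kernel weights must be square with odd side")
        object.__setattr__(self, "weights", w)


def window_size(sigma_c: float, h: float = DEFAULT_WINDOW_RATIO) -> int:
    """Side length in px of the DoG window: ``h * sigma_c + 1``.

    When ``h * sigma_c`` is not an even integer it is rounded to the
    nearest even integer so the side is odd and the kernel has a unique
    centre pixel.
    """
    if sigma_c <= 0:
        raise ValueError("sigma_c must be > 0")
    if h < 2:
        raise ValueError("window ratio h must be >= 2")
    span = float(h) * float(sigma_c)
    even = 2 * int(np.floor(span / 2.0 + 0.5))
    return even + 1


def normalized_gaussian(sigma: float, side: int) -> np.ndarray:
    """Discrete isotropic Gaussian on an odd ``side`` x ``side`` grid.

    Sampled at integer offsets from the centre pixel and renormalized to
    sum exactly 1, so a pair of such kernels subtracts to an exactly
    zero-DC filter regardless of truncation.
    """
    if side < 1 or side % 2 == 0:
        raise ValueError("side must be a positive odd integer")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    offsets = np.arange(side, dtype=np.float64) - side // 2
    g1 = np.exp(-(offsets**2) / (2.0 * sigma * sigma))
    g = np.outer(g1, g1)
    return g / g.sum()


def dog_kernel(params: DoGParams) -> DoGKernel:
    """Build the DoG kernel: centre Gaussian minus surround Gaussian."""
    side = window_size(params.sigma_c, params.h)
    weights = normalized_gaussian(params.sigma_c, side) - normalized_gaussian(
        params.sigma_s, side
    )
    return DoGKernel(params=params, side=side, weights=weights)


def surround_coverage(params: DoGParams) -> float:
    """Fraction of the surround Gaussian's 1-D marginal mass inside the window.

    The window half-width is ``h * sigma_c / 2``; for the defaults
    ``s = 2, h = 8`` this is ``2 * sigma_s``, i.e. ~95.4% of the marginal
    mass, which is what keeps the inhibitory lobe inside the filter.
    """
    from scipy.stats import norm

    half_width = params.h * params.sigma_c / 2.0
    z = half_width / params.sigma_s
    return float(norm.cdf(z) - norm.cdf(-z))


def _image_values(image: LuminanceImage | np.ndarray) -> np.ndarray:
    vals = getattr(image, "values", image)
    arr = np.asarray(vals, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    return arr


def apply_dog(
    image: LuminanceImage | np.ndarray,
    params: DoGParams,
    boundary: str = "replicate",
) -> np.ndarray:
    """Signed DoG response of ``image``, same shape as the input.

    The image is padded by half the kernel side with the requested
    boundary rule (``replicate``, ``reflect`` or ``zero``) and correlated
    with the kernel; the kernel's 4-fold symmetry makes correlation and
    convolution coincide.  Equivalent to ``blur(image, sigma_c) -
    blur(image, s * sigma_c)`` with matching truncation.
    """
    if boundary not in BOUNDARY_MODES:
        raise ValueError(f"boundary must be one of {sorted(BOUNDARY_MODES)}, got {boundary!r}")
    values = _image_values(image)
    kernel = dog_kernel(params)
    if kernel.side > 4 * max(values.shape):
        warnings.warn(
            f"DoG window ({kernel.side} px) exceeds 4x the image extent "
            f"{values.shape}; truncation effects dominate the response",
            stacklevel=2,
        )
    pad = kernel.side // 2
    padded = np.pad(values, pad, mode=BOUNDARY_MODES[boundary])
    return signal.convolve(padded, kernel.weights, mode="valid", method="auto")


def binarize(response: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """ON-centre activation map: True where the signed response is > 0.

    The threshold is strict, so an exactly-zero response (e.g. from a
    constant image) binarizes to all-False.  ``rtol`` guards the zero
    crossing against floating-point dust: values within ``rtol * max
    |response|`` of zero — e.g. FFT round-off inside perfectly uniform
    regions, where the zero-DC kernel's exact response is 0 — count as no
    activation rather than as sign noise.
    """
    resp = np.asarray(response)
    peak = np.max(np.abs(resp)) if resp.size else 0.0
    return resp > rtol * peak


@dataclass(frozen=True)
class EdgeMapStack:
    """Multiscale retinal encoding: per-scale DoG responses and binaries.

    ``scales`` is strictly increasing; ``responses[i]`` and ``binaries[i]``
    are congruent with the input image and correspond to ``scales[i]``.
    """

    scales: tuple[float, ...]
    responses: tuple[np.ndarray, ...]
    binaries: tuple[np.ndarray, ...]
    s: float = DEFAULT_SURROUND_RATIO
    h: float = DEFAULT_WINDOW_RATIO
    boundary: str = "replicate"
    source_spec: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValueError("EdgeMapStack requires at least one scale")
        if not all(a < b for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if not (len(self.scales) == len(self.responses) == len(self.binaries)):
            raise ValueError("scales, responses and binaries must be congruent")

    def __len__(self) -> int:
        return len(self.scales)

    def level(self, sigma_c: float) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(response, binary)`` for the given centre scale."""
        for sc, resp, binary in zip(self.scales, self.responses, self.binaries):
            if sc == sigma_c:
                return resp, binary
        raise KeyError(f"no level with sigma_c = {sigma_c}")

    def save(self, directory: str | Path) -> dict[str, Any]:
        """Persist as per-scale PNGs plus a JSON manifest.

        Responses are min-max scaled to 8-bit grayscale with the affine
        parameters recorded in a JSON sidecar; binaries are written as
        1-bit PNGs.  Returns the manifest mapping.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files: list[dict[str, Any]] = []
        for sigma_c, resp, binary in zip(self.scales, self.responses, self.binaries):
            tag = f"{sigma_c:g}"
            lo, hi = float(resp.min()), float(resp.max())
            scaled = np.zeros_like(resp) if hi == lo else (resp - lo) / (hi - lo)
            resp_name = f"response_sigma{tag}.png"
            Image.fromarray(np.rint(scaled * 255).astype(np.uint8), mode="L").save(
                directory / resp_name
            )
            sidecar = {"sigma_c": sigma_c, "min": lo, "max": hi}
            sidecar_name = f"response_sigma{tag}.json"
            (directory / sidecar_name).write_text(json.dumps(sidecar, sort_keys=True))
            bin_name = f"binary_sigma{tag}.png"
            Image.fromarray(binary.astype(np.uint8) * 255, mode="L").convert("1").save(
                directory / bin_name
            )
            files.append(
                {"sigma_c": sigma_c, "response": resp_name, "sidecar": sidecar_name, "binary": bin_name}
            )
        manifest = {
            "scales": list(self.scales),
            "s": self.s,
            "h": self.h,
            "boundary": self.boundary,
            "source_spec": dict(self.source_spec) if self.source_spec else None,
            "files": files,
        }
        (directory / "edgemap_manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
        return manifest


def edge_map(
    image: LuminanceImage | np.ndarray,
    scales: Sequence[float],
    s: float = DEFAULT_SURROUND_RATIO,
    h: float = DEFAULT_WINDOW_RATIO,
    boundary: str = "replicate",
    source_spec: Mapping[str, Any] | None = None,
) -> EdgeMapStack:
    """Multiscale DoG edge map: one (response, binary) pair per scale."""
    scales = tuple(float(sc) for sc in scales)
    if len(scales) == 0:
        raise ValueError("scales must be nonempty")
    if not all(a < b for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")
    responses = []
    binaries = []
    for sigma_c in scales:
        resp = apply_dog(image, DoGParams(sigma_c=sigma_c, s=s, h=h), boundary=boundary)
        responses.append(resp)
        binaries.append(binarize(resp))
    return EdgeMapStack(
        scales=scales,
        responses=tuple(responses),
        binaries=tuple(binaries),
        s=s,
        h=h,
        boundary=boundary,
        source_spec=source_spec,
    )


def suggest_scales(
    min_feature_px: float,
    max_feature_px: float,
    h: float = DEFAULT_WINDOW_RATIO,
    step: float = 1.0,
) -> list[float]:
    """Scale ladder tuned to the pattern's feature sizes.

    The ladder starts at the finest integer scale whose window fits within
    the smallest feature (``window_size(sigma, h) <= min_feature_px``) and
    extends in steps of ``step`` while the window stays within twice the
    largest feature.  For 10 px dots and 36 px tiles with ``h = 8`` this
    yields sigma_c = 1..8 in steps of 1.
    """
    if not 0 < min_feature_px <= max_feature_px:
        raise ValueError("need 0 < min_feature_px <= max_feature_px")
    if step <= 0:
        raise ValueError("step must be > 0")
    start = 1.0
    if window_size(start, h) > min_feature_px:
        raise ValueError(
            f"window_size(1, {h}) = {window_size(start, h)} px already exceeds the "
            f"smallest feature ({min_feature_px} px); no admissible start scale"
        )
    bound = 2.0 * max_feature_px
    scales: list[float] = []
    k = 0
    while True:
        sigma = start + k * step
        if window_size(sigma, h) > bound:
            break
        scales.append(sigma)
        k += 1
    return scales


def mortar_bridging_labels(
    binary: np.ndarray,
    spec: StimulusSpec,
    dark_junctions_only: bool = False,
    connectivity: int = 2,
) -> set[int]:
    """Connected components that bridge adjacent tile rows through mortar.

    Labels the binary map and returns the labels of components that
    contain at least one pixel inside a mortar strip together with pixels
    in both adjacent tile rows — the "twisted cord" grouping of mortar
    line and tiles.  With ``dark_junctions_only`` the mortar pixel must be
    the centre of a dark-dark junction run (tiles above and below the
    strip both dark), i.e. a point where only the mortar line itself — not
    the blur of an adjacent light tile — can carry the positive response.
    """
    binary = np.asarray(binary) > 0
    bands = mortar_bands(spec)
    if not bands:
        return set()
    labels = measure.label(binary, connectivity=connectivity)
    from .stimuli import generate_cafe_wall

    img = generate_cafe_wall(replace(spec, kind="cafe_wall")).values
    bridging: set[int] = set()
    t = spec.tile_px
    for top, bottom in bands:
        if dark_junctions_only:
            # centres of the dark-dark junction runs: the mortar-line pixels
            # farthest from any light tile, where only the mortar's own
            # (intermediate) luminance can drive a positive response
            dark = (img[top - 1] == spec.lum_dark) & (img[bottom] == spec.lum_dark)
            idx = np.flatnonzero(dark)
            if idx.size == 0:
                continue
            runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            mid_row = (top + bottom) // 2
            in_band = {int(labels[mid_row, run[len(run) // 2]]) for run in runs} - {0}
        else:
            in_band = set(np.unique(labels[top:bottom])) - {0}
        above = set(np.unique(labels[max(0, top - t) : top])) - {0}
        below = set(np.unique(labels[bottom : bottom + t])) - {0}
        bridging |= in_band & above & below
    return bridging


def has_twisted_cord(binary: np.ndarray, spec: StimulusSpec) -> bool:
    """True when the binary map groups mortar-line and tile responses.

    The twisted-cord element of the Café Wall illusion is the grouping of
    a mortar-line segment (visible where it runs between two dark tiles)
    with the tiles of the rows above and below.  It is present at fine
    scales (centre scale up to about the mortar height) and dissolves at
    coarse scales, where only same-coloured tiles group.
    """
    return bool(mortar_bridging_labels(binary, spec, dark_junctions_only=True))
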