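"""End-to-end pipeline: stimulus -> multiscale edge map -> tilt report.

A :class:`RunConfig` bundles everything one run needs — the stimulus (a
parametric spec or an input image path), the DoG parameters, the scale
ladder (explicit or derived from feature sizes), the Hough configuration
and the output directory.  :func:`run_pipeline` executes the stages,
writes every artifact (PNGs, CSV, JSON) and returns a manifest listing
each written file with the parameters that produced it.  The pipeline is
deterministic: re-running the same config writes byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import retina, stimuli, viz
from .retina import edge_map, suggest_scales
from .stimuli import LuminanceImage, StimulusSpec, spec_from_mapping
from .tiltmetry import HoughConfig, tilt_report

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("retinotilt")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``stimulus`` / ``image_path`` selects the input, and
    exactly one of ``scales`` / ``suggest`` selects the scale ladder
    (``suggest`` maps to :func:`retinotilt.retina.suggest_scales` inputs:
    ``min_feature_px``, ``max_feature_px``, ``step``).  ``seed`` is
    reserved; the pipeline is deterministic.
    """

    output_dir: str
    stimulus: StimulusSpec | None = None
    image_path: str | None = None
    s: float = retina.DEFAULT_SURROUND_RATIO
    h: float = retina.DEFAULT_WINDOW_RATIO
    boundary: str = "replicate"
    scales: tuple[float, ...] | None = None
    suggest: Mapping[str, float] | None = None
    hough: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.stimulus is None) == (self.image_path is None):
            raise ValueError("config error: exactly one of 'stimulus' / 'image_path' must be given")
        if (self.scales is None) == (self.suggest is None):
            raise ValueError("config error: exactly one of 'scales' / 'suggest' must be given")
        if self.scales is not None:
            object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        data = dict(mapping)
        stim = data.get("stimulus")
        if isinstance(stim, Mapping):
            data["stimulus"] = spec_from_mapping(stim)
        dog = data.pop("dog", None)
        if dog:
            for key in ("s", "h", "boundary"):
                if key in dog:
                    data[key] = dog[key]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ValueError(f"config error: {path} does not hold a mapping")
        return cls.from_mapping(data)


def _resolve_scales(config: RunConfig) -> list[float]:
    if config.scales is not None:
        return list(config.scales)
    kwargs = dict(config.suggest)
    return suggest_scales(
        kwargs.pop("min_feature_px"),
        kwargs.pop("max_feature_px"),
        h=kwargs.pop("h", config.h),
        step=kwargs.pop("step", 1.0),
    )


def _hough_config(config: RunConfig, spec: StimulusSpec | None) -> HoughConfig:
    overrides = dict(config.hough)
    if spec is not None:
        return HoughConfig.for_spec(spec, **overrides)
    return HoughConfig(**overrides)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if config.stimulus is not None:
        spec: StimulusSpec | None = config.stimulus
        image = stimuli.generate(spec)
        source: dict[str, Any] = {"stimulus": spec.to_mapping()}
    else:
        spec = None
        image = LuminanceImage.from_file(config.image_path)
        source = {"image_path": str(config.image_path)}
    logger.info("stimulus ready: %dx%d px", image.height, image.width)

    files: list[str] = []
    image.to_png(out / "stimulus.png")
    files.append("stimulus.png")

    scales = _resolve_scales(config)
    stack = edge_map(
        image,
        scales,
        s=config.s,
        h=config.h,
        boundary=config.boundary,
        source_spec=source,
    )
    logger.info(
        "edge map: %d scales in %.2f s", len(stack), time.perf_counter() - t0
    )
    stack_manifest = stack.save(out)
    for entry in stack_manifest["files"]:
        files.extend([entry["response"], entry["sidecar"], entry["binary"]])
    files.append("edgemap_manifest.json")

    jet_panels = []
    for sigma_c, resp in zip(stack.scales, stack.responses):
        rgb = viz.render_jetwhite(resp)
        name = f"jetwhite_sigma{sigma_c:g}.png"
        viz.save_rgb(rgb, out / name)
        files.append(name)
        jet_panels.append(rgb)
    viz.save_rgb(viz.montage(jet_panels), out / "montage_jetwhite.png")
    files.append("montage_jetwhite.png")
    bin_panels = [(b > 0).astype(float) for b in stack.binaries]
    viz.save_rgb(viz.montage(bin_panels), out / "montage_binary.png")
    files.append("montage_binary.png")

    hough = _hough_config(config, spec)
    report = tilt_report(stack, hough)
    report.to_csv(out / "tilt_segments.csv")
    report.to_json(out / "tilt_summary.json")
    files.extend(["tilt_segments.csv", "tilt_summary.json"])
    for sigma_c, binary in zip(stack.scales, stack.binaries):
        overlay = viz.overlay_segments(
            binary, report.segments[sigma_c], report.longest_index(sigma_c)
        )
        name = f"houghlines_sigma{sigma_c:g}.png"
        viz.save_rgb(overlay, out / name)
        files.append(name)
    logger.info("tilt report: %d scales in %.2f s", len(stack), time.perf_counter() - t0)

    manifest = {
        "parameters": {
            "source": source,
            "s": config.s,
            "h": config.h,
            "boundary": config.boundary,
            "scales": list(scales),
            "hough": dataclasses.asdict(hough),
            "seed": config.seed,
        },
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    manifest["output_dir"] = str(out)
    return manifest
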