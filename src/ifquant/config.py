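"""Pipeline configuration: a single YAML file drives the whole run.

Every interactive step of the original workflow (channel naming,
background-AOI drawing) is a config entry here, so runs are headless and
reproducible.

Example::

    input:
      paths: [roi_ch1.tif, roi_ch2.tif]     # or: stack: roi.tif
      # or: tiles: {dir: tiles/, pattern: '\\[(\\d+),(\\d+)\\]', fill_missing: true}
    channels: [DAPI, CD4]
    segmentation_channel: DAPI
    pixel_size_um: 1.0
    preprocess:
      rolling_ball_radius: 50
      clahe: {block_size: 30, bins: 256, max_slope: 3.0, enabled: true}
    segmentation:
      sigma_low: 2.362        # or: radius_um: 7.5 (converted)
      sigma_ratio: 1.4
      fill_holes: true
      min_area_px: 0
      connectivity: 8
    background:
      mode: auto-darkest      # or manual-rect with rect: [x0, y0, w, h]
      window_px: 30
    export:
      formats: [tsv, xlsx, fcs]
      out_dir: out/
    measure_raw: false
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .preprocess import ClaheParams, RollingBallParams
from .segmentation import SegmentationParams, sigma_from_radius
from .tiling import DEFAULT_TILE_PATTERN

__all__ = ["PipelineConfig", "ConfigError", "load_config"]

_EXPORT_FORMATS = ("tsv", "xlsx", "fcs")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    input_paths: list[Path] = field(default_factory=list)
    input_stack: Path | None = None
    tiles_dir: Path | None = None
    tile_pattern: str = DEFAULT_TILE_PATTERN
    fill_missing: bool = True
    channels: list[str] = field(default_factory=list)
    segmentation_channel: str = ""
    pixel_size_um: float = 1.0
    rolling_ball: RollingBallParams = field(default_factory=RollingBallParams)
    clahe: ClaheParams = field(default_factory=ClaheParams)
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(sigma_low=2.362))
    background_mode: str = "auto-darkest"
    background_rect: tuple[int, int, int, int] | None = None
    background_window_px: int = 30
    export_formats: list[str] = field(default_factory=lambda: ["tsv", "xlsx", "fcs"])
    out_dir: Path = Path("ifquant_out")
    roi_name: str = "ROI"
    measure_raw: bool = False
    seed: int = 0

    def validate(self) -> None:
        n_sources = sum(
            x is not None and x != []
            for x in (self.input_paths or None, self.input_stack, self.tiles_dir)
        )
        if n_sources != 1:
            raise ConfigError(
                "exactly one input source required: paths, stack or tiles"
            )
        if not self.segmentation_channel:
            raise ConfigError("segmentation_channel is required")
        if self.channels and self.segmentation_channel not in self.channels:
            raise ConfigError(
                f"segmentation channel {self.segmentation_channel!r} not in "
                f"channels {self.channels}"
            )
        bad = set(self.export_formats) - set(_EXPORT_FORMATS)
        if bad:
            raise ConfigError(f"unknown export format(s): {sorted(bad)}")
        if self.background_mode == "manual-rect" and self.background_rect is None:
            raise ConfigError("manual-rect background mode requires a rect")
        if self.background_mode not in ("manual-rect", "auto-darkest"):
            raise ConfigError(f"unknown background mode {self.background_mode!r}")


def _build_segmentation(seg: dict[str, Any], pixel_size_um: float) -> SegmentationParams:
    seg = dict(seg)
    if "sigma_low" not in seg:
        if "radius_um" in seg:
            seg["sigma_low"] = sigma_from_radius(seg.pop("radius_um"), pixel_size_um)
        else:
            raise ConfigError("segmentation needs sigma_low or radius_um")
    seg.pop("radius_um", None)
    try:
        return SegmentationParams(**seg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid segmentation parameters: {exc}") from exc


def load_config(path: str | Path | dict[str, Any]) -> PipelineConfig:
    """Parse and validate a YAML config file (or an equivalent dict)."""
    if isinstance(path, dict):
        raw = path
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    inp = raw.get("input", {}) or {}
    pixel_size = float(raw.get("pixel_size_um", 1.0))
    pre = raw.get("preprocess", {}) or {}
    cl = pre.get("clahe", {}) or {}
    bg = raw.get("background", {}) or {}
    exp = raw.get("export", {}) or {}
    tiles = inp.get("tiles", {}) or {}

    try:
        cfg = PipelineConfig(
            input_paths=[Path(p) for p in inp.get("paths", [])],
            input_stack=Path(inp["stack"]) if "stack" in inp else None,
            tiles_dir=Path(tiles["dir"]) if "dir" in tiles else None,
            tile_pattern=tiles.get("pattern", DEFAULT_TILE_PATTERN),
            fill_missing=bool(tiles.get("fill_missing", True)),
            channels=list(raw.get("channels", [])),
            segmentation_channel=raw.get("segmentation_channel", ""),
            pixel_size_um=pixel_size,
            rolling_ball=RollingBallParams(
                float(pre.get("rolling_ball_radius", 50.0))),
            clahe=ClaheParams(
                block_size_px=int(cl.get("block_size", 30)),
                histogram_bins=int(cl.get("bins", 256)),
                max_slope=float(cl.get("max_slope", 3.0)),
                enabled=bool(cl.get("enabled", True)),
            ),
            segmentation=_build_segmentation(
                raw.get("segmentation", {"sigma_low": 2.362}), pixel_size),
            background_mode=bg.get("mode", "auto-darkest"),
            background_rect=tuple(bg["rect"]) if "rect" in bg else None,
            background_window_px=int(bg.get("window_px", 30)),
            export_formats=list(exp.get("formats", ["tsv", "xlsx", "fcs"])),
            out_dir=Path(exp.get("out_dir", "ifquant_out")),
            roi_name=str(raw.get("roi_name", "ROI")),
            measure_raw=bool(raw.get("measure_raw", False)),
            seed=int(raw.get("seed", 0)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg
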