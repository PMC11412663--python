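"""End-to-end orchestration: load/stitch -> preprocess -> segment ->
measure -> export, with a JSON run log for provenance.

Stage order is fixed: background subtraction precedes CLAHE, CLAHE
precedes the DoG segmentation of the chosen channel, measurement follows
segmentation, and the FCS merge comes last. Reruns on identical inputs
and config are bit-identical for integer outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .exporters import merge_to_fcs, write_tsv, write_xlsx
from .image_io import ImageStack, read_stack, write_label_mask, write_stack
from .measurement import build_cell_table, select_background_aoi
from .preprocess import preprocess_channel
from .segmentation import segment_cells
from .tiling import fill_missing_tiles, load_tile_grid, stitch

logger = logging.getLogger(__name__)

__all__ = ["run", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_input(config: PipelineConfig) -> ImageStack:
    names = config.channels or None
    if config.tiles_dir is not None:
        grid = load_tile_grid(config.tiles_dir, config.tile_pattern,
                              names, config.pixel_size_um)
        if config.fill_missing:
            grid = fill_missing_tiles(grid)
        return stitch(grid)
    paths = config.input_stack or config.input_paths
    return read_stack(paths, names, config.pixel_size_um)


def run(config: PipelineConfig) -> dict[str, object]:
    """Execute the full pipeline; returns a manifest of outputs and counts."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict[str, object] = {
        "version": __version__,
        "config": _config_summary(config),
        "stages": [],
    }
    stages: list[str] = log["stages"]  # type: ignore[assignment]

    def stage(name: str):
        stages.append(name)
        logger.info("stage: %s", name)

    try:
        stage("load")
        raw = _load_input(config)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        stage("preprocess")
        processed = ImageStack(
            [preprocess_channel(ch, config.rolling_ball, config.clahe)
             for ch in raw.channels],
            list(raw.channel_names),
            raw.pixel_size_um,
        )
        write_stack(processed, out_dir / "processed_stack.tif",
                    compression="lzw")
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    try:
        stage("segment")
        seg_channel = processed.channel(config.segmentation_channel)
        mask = segment_cells(seg_channel, config.segmentation)
        write_label_mask(mask.labels, out_dir / "label_mask.tif")
        log["n_cells"] = mask.n_objects
    except Exception as exc:
        raise PipelineError("segment", exc) from exc

    try:
        stage("background")
        background = select_background_aoi(
            processed, config.background_mode, config.background_window_px,
            config.background_rect, mask)
        log["background"] = {
            "region": list(background.region),
            "per_channel_mean": background.per_channel_mean,
        }
    except Exception as exc:
        raise PipelineError("background", exc) from exc

    try:
        stage("measure")
        table = build_cell_table(
            mask, processed, background,
            measure_raw_stack=raw if config.measure_raw else None)
        log["n_records"] = len(table)
    except Exception as exc:
        raise PipelineError("measure", exc) from exc

    outputs: dict[str, str] = {}
    try:
        stage("export")
        if "tsv" in config.export_formats:
            outputs["tsv"] = str(write_tsv(table, out_dir / "cells.tsv"))
        if "xlsx" in config.export_formats:
            outputs["xlsx"] = str(write_xlsx(table, out_dir / "cells.xlsx"))
        if "fcs" in config.export_formats and len(table):
            outputs["fcs"] = str(
                merge_to_fcs(table, config.roi_name, out_dir / "cells.fcs"))
    except Exception as exc:
        raise PipelineError("export", exc) from exc

    log["outputs"] = outputs
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log


def _config_summary(config: PipelineConfig) -> dict[str, object]:
    return {
        "segmentation_channel": config.segmentation_channel,
        "pixel_size_um": config.pixel_size_um,
        "rolling_ball": asdict(config.rolling_ball),
        "clahe": asdict(config.clahe),
        "segmentation": asdict(config.segmentation),
        "background_mode": config.background_mode,
        "export_formats": list(config.export_formats),
        "seed": config.seed,
    }
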