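"""Tile-grid parsing, black-tile filling and mosaic stitching.

Tile filenames carry their grid position as a bracketed ``[col,row]``
token (the convention of Vectra-exported tiles); the pattern is
overridable. Coordinates are shifted so minima land at 0 but numbering
gaps are preserved — a gap becomes a black tile column/row after
:func:`fill_missing_tiles`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .image_io import ImageStack, read_stack

__all__ = [
    "DEFAULT_TILE_PATTERN",
    "TileGrid",
    "parse_tile_positions",
    "fill_missing_tiles",
    "stitch",
    "load_tile_grid",
]

#: matches a "[col,row]" token anywhere in the filename
DEFAULT_TILE_PATTERN = r"\[(\d+),(\d+)\]"


def parse_tile_positions(
    filenames: Sequence[str], pattern: str = DEFAULT_TILE_PATTERN
) -> dict[str, tuple[int, int]]:
    """Map each filename to its (col, row) grid position.

    ``pattern`` must contain two integer capture groups, read as
    (column, row). Positions are shifted so the minimum of each axis is 0;
    gaps are left as-is.
    """
    rx = re.compile(pattern)
    if rx.groups != 2:
        raise ValueError(
            f"tile pattern must have exactly 2 capture groups, got {rx.groups}"
        )
    raw: dict[str, tuple[int, int]] = {}
    for name in filenames:
        m = rx.search(name)
        if m is None:
            raise ValueError(f"no coordinates found in filename {name!r} "
                             f"(pattern {pattern!r})")
        raw[name] = (int(m.group(1)), int(m.group(2)))

    seen: dict[tuple[int, int], str] = {}
    for name, pos in raw.items():
        if pos in seen:
            raise ValueError(
                f"duplicate tile coordinates {pos}: {seen[pos]!r} and {name!r}"
            )
        seen[pos] = name

    min_col = min(c for c, _ in raw.values())
    min_row = min(r for _, r in raw.values())
    return {name: (c - min_col, r - min_row) for name, (c, r) in raw.items()}


@dataclass
class TileGrid:
    """Tiles keyed by (row, col); each tile is (H, W) or (C, H, W)."""

    tiles: dict[tuple[int, int], np.ndarray]
    n_rows: int = 0
    n_cols: int = 0
    channel_names: list[str] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.tiles:
            raise ValueError("TileGrid needs at least one tile")
        shapes = {t.shape for t in self.tiles.values()}
        if len(shapes) > 1:
            raise ValueError(f"non-uniform tile shapes: {sorted(shapes)}")
        if not self.n_rows:
            self.n_rows = max(r for r, _ in self.tiles) + 1
        if not self.n_cols:
            self.n_cols = max(c for _, c in self.tiles) + 1
        for (r, c) in self.tiles:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"tile position {(r, c)} outside "
                                 f"{self.n_rows}x{self.n_cols} grid")

    @property
    def tile_shape(self) -> tuple[int, ...]:
        return next(iter(self.tiles.values())).shape

    @property
    def tile_height(self) -> int:
        return self.tile_shape[-2]

    @property
    def tile_width(self) -> int:
        return self.tile_shape[-1]

    @property
    def is_complete(self) -> bool:
        return len(self.tiles) == self.n_rows * self.n_cols


def fill_missing_tiles(grid: TileGrid) -> TileGrid:
    """Complete the grid rectangle with all-zero ("black") tiles."""
    template = next(iter(grid.tiles.values()))
    tiles = dict(grid.tiles)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if (r, c) not in tiles:
                tiles[(r, c)] = np.zeros_like(template)
    return TileGrid(tiles, grid.n_rows, grid.n_cols,
                    list(grid.channel_names), grid.pixel_size_um)


def stitch(grid: TileGrid) -> ImageStack:
    """Abut tiles into one mosaic; tile (r, c) occupies the block
    ``[r*H:(r+1)*H, c*W:(c+1)*W]`` with pixel values copied unchanged.

    Raises if the grid is not rectangular-complete; run
    :func:`fill_missing_tiles` first for sparse grids.
    """
    if not grid.is_complete:
        missing = [(r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)
                   if (r, c) not in grid.tiles]
        raise ValueError(
            f"grid has {len(missing)} missing tiles (e.g. {missing[:3]}); "
            "call fill_missing_tiles first"
        )
    shape = grid.tile_shape
    n_ch = shape[0] if len(shape) == 3 else 1
    H, W = grid.tile_height, grid.tile_width
    dtype = next(iter(grid.tiles.values())).dtype
    mosaic = np.zeros((n_ch, grid.n_rows * H, grid.n_cols * W), dtype=dtype)
    for (r, c), tile in grid.tiles.items():
        block = tile if tile.ndim == 3 else tile[None]
        mosaic[:, r * H:(r + 1) * H, c * W:(c + 1) * W] = block
    names = list(grid.channel_names) or None
    return ImageStack(list(mosaic), names or [], grid.pixel_size_um)


def load_tile_grid(
    directory: str | Path,
    pattern: str = DEFAULT_TILE_PATTERN,
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float = 1.0,
    glob: str = "*.tif*",
) -> TileGrid:
    """Read a directory of TIFF tiles into a TileGrid.

    Each tile file may be single- or multi-page; pages become channels.
    """
    directory = Path(directory)
    files = sorted(directory.glob(glob))
    if not files:
        raise FileNotFoundError(f"no TIFF tiles matching {glob!r} in {directory}")
    positions = parse_tile_positions([f.name for f in files], pattern)
    tiles: dict[tuple[int, int], np.ndarray] = {}
    names: list[str] = []
    for f in files:
        stack = read_stack(f, channel_names, pixel_size_um)
        names = stack.channel_names
        col, row = positions[f.name]
        arr = stack.asarray()
        tiles[(row, col)] = arr[0] if arr.shape[0] == 1 else arr
    return TileGrid(tiles, channel_names=names, pixel_size_um=pixel_size_um)
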