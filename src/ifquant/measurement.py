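"""Per-cell geometry and intensity measurement.

Produces a long-format table (one row per cell x channel) with the
columns Cell, Label, Area, Mean, X, Y, Circ., IntDen, RawIntDen, AR,
Round, Solidity, CTCF.

Conventions (fixed and documented because downstream plots depend on
them): coordinates are 0-based pixel centers, x = column (rightward),
y = row (downward), origin top-left; the perimeter is the length of the
8-connected outer boundary chain with straight steps counting 1 and
diagonal steps sqrt(2); circularity is clamped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .image_io import ImageStack
from .segmentation import LabelMask

__all__ = [
    "CELL_TABLE_COLUMNS",
    "BackgroundAOI",
    "measure_geometry",
    "shape_descriptors",
    "measure_intensity",
    "compute_ctcf",
    "select_background_aoi",
    "build_cell_table",
    "chain_perimeter",
]

#: output schema, in fixed order
CELL_TABLE_COLUMNS = [
    "Cell", "Label", "Area", "Mean", "X", "Y", "Circ.",
    "IntDen", "RawIntDen", "AR", "Round", "Solidity", "CTCF",
]

# clockwise Moore neighborhood in image coordinates (row down)
_DIRS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_STEP = [1.0, math.sqrt(2.0)] * 4  # even index straight, odd diagonal


def chain_perimeter(mask: np.ndarray) -> float:
    """Length of the outer boundary chain of a single connected object.

    Moore-neighbor tracing over the 8-connected outline; straight moves
    count 1, diagonal moves sqrt(2). A single isolated pixel has no chain
    and returns 0 (its shape descriptors are then flagged undefined).
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        raise ValueError("empty object")
    if pts.shape[0] == 1:
        return 0.0
    padded = np.pad(mask, 1)
    start = (int(pts[0, 0]) + 1, int(pts[0, 1]) + 1)  # topmost-leftmost

    perimeter = 0.0
    cur = start
    # entered the start pixel moving east, i.e. backtrack points west
    back_dir = 4
    first_state: tuple[tuple[int, int], int] | None = None
    for _ in range(4 * padded.size):
        found = None
        for k in range(1, 9):
            d = (back_dir + k) % 8
            nxt = (cur[0] + _DIRS[d][0], cur[1] + _DIRS[d][1])
            if padded[nxt]:
                found = (nxt, d)
                break
        if found is None:  # isolated pixel (cannot happen: size > 1, connected)
            return 0.0
        nxt, d = found
        state = (cur, d)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        perimeter += _STEP[d % 2]
        back_dir = (d + 4 + 1) % 8  # neighbor scanned before `nxt`, one step back
        # standard Moore backtrack: direction from new pixel to previous
        # scan restart position = direction back to cur, rotated one step
        cur = nxt
    return perimeter


def measure_geometry(mask: LabelMask, pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Geometry per labeled object.

    Returns columns cell, area, x, y, perimeter, major_axis, minor_axis,
    convex_area. Area-like quantities are calibrated by
    ``pixel_size_um**2`` and lengths by ``pixel_size_um``; centroids stay
    in pixel coordinates. Axes come from the moment-matched ellipse
    (same area and second central moments as the object).
    """
    if mask.n_objects == 0:
        return pd.DataFrame(
            columns=["cell", "area", "x", "y", "perimeter",
                     "major_axis", "minor_axis", "convex_area"]
        )
    ps, ps2 = pixel_size_um, pixel_size_um ** 2
    rows = []
    for prop in regionprops(mask.labels):
        r0, c0, r1, c1 = prop.bbox
        sub = mask.labels[r0:r1, c0:c1] == prop.label
        cy, cx = prop.centroid
        rows.append({
            "cell": int(prop.label),
            "area": prop.area * ps2,
            "x": cx,
            "y": cy,
            "perimeter": chain_perimeter(sub) * ps,
            "major_axis": prop.axis_major_length * ps,
            "minor_axis": prop.axis_minor_length * ps,
            "convex_area": prop.area_convex * ps2,
        })
    return pd.DataFrame(rows).sort_values("cell", ignore_index=True)


def shape_descriptors(
    area: float, perimeter: float, major_axis: float,
    minor_axis: float, convex_area: float,
) -> tuple[float, float, float, float]:
    """(circularity, aspect ratio, roundness, solidity).

    circ = min(1, 4*pi*area / perimeter^2); ar = major/minor;
    round = 4*area / (pi*major^2); solidity = area/convex_area.
    Undefined descriptors (zero perimeter, minor axis, ...) come back as
    NaN so the record can be flagged rather than dropped.
    """
    circ = min(1.0, 4.0 * math.pi * area / perimeter ** 2) if perimeter > 0 else math.nan
    ar = major_axis / minor_axis if minor_axis > 0 else math.nan
    rnd = 4.0 * area / (math.pi * major_axis ** 2) if major_axis > 0 else math.nan
    solidity = area / convex_area if convex_area > 0 else math.nan
    return circ, ar, rnd, solidity


def measure_intensity(
    mask: LabelMask, channel: np.ndarray, channel_name: str,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Per-object mean, RawIntDen (pixel sum) and IntDen (area x mean)."""
    channel = np.asarray(channel)
    if channel.shape != mask.shape:
        raise ValueError(
            f"channel shape {channel.shape} != mask shape {mask.shape}"
        )
    n = mask.n_objects
    if n == 0:
        return pd.DataFrame(columns=["cell", "label", "mean", "raw_int_den", "int_den"])
    flat = mask.labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    sums = np.bincount(flat, weights=channel.astype(np.float64).ravel(),
                       minlength=n + 1)[1:]
    mean = sums / counts
    area = counts * pixel_size_um ** 2
    return pd.DataFrame({
        "cell": np.arange(1, n + 1),
        "label": channel_name,
        "mean": mean,
        "raw_int_den": sums,
        "int_den": area * mean,
    })


@dataclass
class BackgroundAOI:
    """A signal-free reference region and its per-channel mean intensity."""

    region: tuple[int, int, int, int]  # (x0, y0, width, height)
    per_channel_mean: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        x0, y0, w, h = self.region
        if w <= 0 or h <= 0:
            raise ValueError("background region must be non-empty")
        if x0 < 0 or y0 < 0:
            raise ValueError("background region origin must be non-negative")


def select_background_aoi(
    stack: ImageStack,
    mode: str = "auto-darkest",
    window_px: int = 30,
    rect: tuple[int, int, int, int] | None = None,
    mask: LabelMask | None = None,
) -> BackgroundAOI:
    """Pick the background reference region used for CTCF.

    ``manual-rect`` takes ``rect = (x0, y0, width, height)`` from the
    configuration; ``auto-darkest`` scans every ``window_px`` square
    window and keeps the one with the lowest summed intensity across all
    channels. Either way the region must not overlap any segmented cell.
    """
    H, W = stack.shape
    if mode == "manual-rect":
        if rect is None:
            raise ValueError("manual-rect mode requires rect=(x0, y0, w, h)")
        x0, y0, w, h = rect
        if x0 + w > W or y0 + h > H:
            raise ValueError(f"rect {rect} does not fit in image {W}x{H}")
        if mask is not None and np.any(mask.labels[y0:y0 + h, x0:x0 + w] > 0):
            raise ValueError(f"background rect {rect} overlaps segmented cells")
    elif mode == "auto-darkest":
        if window_px > min(H, W):
            raise ValueError(f"window_px {window_px} exceeds image {W}x{H}")
        total = np.zeros((H, W), dtype=np.float64)
        for ch in stack.channels:
            total += ch
        win_sum = _window_sums(total, window_px)
        if mask is not None:
            occupied = _window_sums((mask.labels > 0).astype(np.float64), window_px)
            win_sum = np.where(occupied > 0, np.inf, win_sum)
            if not np.isfinite(win_sum).any():
                raise ValueError(
                    "every candidate window overlaps segmented cells; "
                    "use manual-rect mode"
                )
        iy, ix = np.unravel_index(np.argmin(win_sum), win_sum.shape)
        x0, y0, w, h = int(ix), int(iy), window_px, window_px
    else:
        raise ValueError(f"unknown background mode {mode!r}")

    means = {
        name: float(np.mean(ch[y0:y0 + h, x0:x0 + w]))
        for name, ch in zip(stack.channel_names, stack.channels)
    }
    return BackgroundAOI((x0, y0, w, h), means)


def _window_sums(img: np.ndarray, k: int) -> np.ndarray:
    """Sums over every k x k window (valid positions), via integral image."""
    integral = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    integral[1:, 1:] = np.cumsum(np.cumsum(img, axis=0), axis=1)
    return (integral[k:, k:] - integral[:-k, k:]
            - integral[k:, :-k] + integral[:-k, :-k])


def compute_ctcf(records: pd.DataFrame, background: BackgroundAOI) -> pd.DataFrame:
    """Fill the CTCF column: IntDen - Area x background mean of the channel."""
    out = records.copy()
    missing = set(out["Label"]) - set(background.per_channel_mean)
    if missing:
        raise ValueError(
            f"background mean missing for channel(s): {sorted(missing)}"
        )
    bg = out["Label"].map(background.per_channel_mean)
    out["CTCF"] = out["IntDen"] - out["Area"] * bg
    return out


def build_cell_table(
    mask: LabelMask,
    stack: ImageStack,
    background: BackgroundAOI | None = None,
    measure_raw_stack: ImageStack | None = None,
) -> pd.DataFrame:
    """Assemble the full long-format cell table for every channel.

    Geometry is measured once on the mask and repeated per channel;
    intensities are measured per channel (on ``measure_raw_stack``
    instead when given, for the raw-intensity alternative). CTCF is
    filled when a background AOI is supplied, otherwise left as NaN.
    """
    ps = stack.pixel_size_um
    geo = measure_geometry(mask, ps)
    source = measure_raw_stack if measure_raw_stack is not None else stack
    frames = []
    for name, ch in zip(source.channel_names, source.channels):
        inten = measure_intensity(mask, ch, name, ps)
        merged = inten.merge(geo, on="cell", how="left")
        desc = merged.apply(
            lambda r: shape_descriptors(
                r["area"], r["perimeter"], r["major_axis"],
                r["minor_axis"], r["convex_area"]),
            axis=1, result_type="expand",
        ) if len(merged) else pd.DataFrame(columns=range(4))
        frames.append(pd.DataFrame({
            "Cell": merged["cell"],
            "Label": merged["label"],
            "Area": merged["area"],
            "Mean": merged["mean"],
            "X": merged["x"],
            "Y": merged["y"],
            "Circ.": desc[0] if len(merged) else [],
            "IntDen": merged["int_den"],
            "RawIntDen": merged["raw_int_den"],
            "AR": desc[1] if len(merged) else [],
            "Round": desc[2] if len(merged) else [],
            "Solidity": desc[3] if len(merged) else [],
        }))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=CELL_TABLE_COLUMNS[:-1])
    table["CTCF"] = np.nan
    if background is not None and len(table):
        table = compute_ctcf(table, background)
    return table[CELL_TABLE_COLUMNS]
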