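"""TIFF reading/writing with named channels and pixel-size metadata."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "ImageFormatError"]

#: compression keywords accepted by write_stack, mapped to tifffile codecs
_COMPRESSIONS = {"none": None, "lzw": "lzw", "zlib": "zlib"}


class ImageFormatError(ValueError):
    """Raised when an input file is not a readable grayscale TIFF stack."""


@dataclass
class ImageStack:
    """A named multi-channel 2D image.

    Parameters
    ----------
    channels : list of 2D ndarray
        One intensity array per channel; all share the same shape.
        Unsigned 8/16-bit integers or floats, values >= 0.
    channel_names : list of str
        Unique, non-empty names aligned with ``channels``.
    pixel_size_um : float
        Microns per pixel. Defaults to 1.0 so that areas are reported in
        pixel units when no calibration is known.
    """

    channels: list[np.ndarray]
    channel_names: list[str] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.channels = [np.asarray(c) for c in self.channels]
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(len(self.channels))]
        if len(self.channel_names) != len(self.channels):
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if any(not n for n in self.channel_names):
            raise ValueError("channel names must be non-empty")
        shape = self.channels[0].shape
        for name, ch in zip(self.channel_names, self.channels):
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D (shape {ch.shape})")
            if ch.shape != shape:
                raise ValueError(
                    f"channel {name!r} has shape {ch.shape}, expected {shape}"
                )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def dtype(self) -> np.dtype:
        return self.channels[0].dtype

    @property
    def bit_depth(self) -> str:
        """'8', '16' or 'float' depending on the channel dtype."""
        dt = self.dtype
        if np.issubdtype(dt, np.floating):
            return "float"
        return str(dt.itemsize * 8)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(
                f"no channel named {name!r}; available: {self.channel_names}"
            ) from None

    def asarray(self) -> np.ndarray:
        """Channels stacked along axis 0, shape (C, H, W)."""
        return np.stack(self.channels, axis=0)


def _read_pages(path: str | os.PathLike) -> list[np.ndarray]:
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise ImageFormatError(f"cannot read TIFF {path}: {exc}") from exc
    out = []
    for arr in pages:
        if arr.ndim != 2:
            raise ImageFormatError(
                f"{path}: expected grayscale 2D pages, got shape {arr.shape}"
            )
        out.append(arr)
    return out


def read_stack(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float = 1.0,
) -> ImageStack:
    """Read one multi-page TIFF or several single-page TIFFs as a stack.

    Channel order follows page order (single file) or the order of
    ``paths``. When ``channel_names`` is omitted, channels are named
    ``ch1..chN``.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input paths given")

    channels: list[np.ndarray] = []
    sources: list[Path] = []
    for p in paths:
        for page in _read_pages(p):
            channels.append(page)
            sources.append(p)

    shape = channels[0].shape
    for arr, src in zip(channels, sources):
        if arr.shape != shape:
            raise ImageFormatError(
                f"dimension mismatch: {src} has shape {arr.shape}, "
                f"expected {shape} (from {sources[0]})"
            )

    if channel_names is not None:
        channel_names = list(channel_names)
        if len(channel_names) != len(channels):
            raise ValueError(
                f"{len(channel_names)} channel names given for "
                f"{len(channels)} channels"
            )
    return ImageStack(channels, channel_names or [], pixel_size_um)


def write_stack(
    stack: ImageStack,
    path: str | os.PathLike,
    as_single_stack: bool = True,
    compression: str = "none",
) -> list[Path]:
    """Write an ImageStack as a multi-page TIFF or one file per channel.

    With ``as_single_stack=False``, ``path`` is used as a stem and each
    channel goes to ``<stem>_<channel>.tif``. Channel names are stored in
    the page description so that round-trips preserve them. Returns the
    list of written files.
    """
    comp = compression.lower() if compression else "none"
    if comp not in _COMPRESSIONS:
        raise ValueError(
            f"unknown compression {compression!r}; choose from {sorted(_COMPRESSIONS)}"
        )
    codec = _COMPRESSIONS[comp]
    path = Path(path)
    written: list[Path] = []
    if as_single_stack:
        path.parent.mkdir(parents=True, exist_ok=True)
        with tifffile.TiffWriter(path) as tw:
            for name, ch in zip(stack.channel_names, stack.channels):
                tw.write(ch, compression=codec, description=name,
                         resolution=(1e4 / stack.pixel_size_um,) * 2,
                         resolutionunit="CENTIMETER")
        written.append(path)
    else:
        stem = path.with_suffix("") if path.suffix else path
        stem.parent.mkdir(parents=True, exist_ok=True)
        for name, ch in zip(stack.channel_names, stack.channels):
            out = stem.parent / f"{stem.name}_{name}.tif"
            tifffile.imwrite(out, ch, compression=codec, description=name,
                             resolution=(1e4 / stack.pixel_size_um,) * 2,
                             resolutionunit="CENTIMETER")
            written.append(out)
    return written


def read_label_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a 2D integer label image from TIFF."""
    pages = _read_pages(path)
    if len(pages) != 1:
        raise ImageFormatError(f"{path}: expected a single-page label image")
    arr = pages[0]
    if not np.issubdtype(arr.dtype, np.integer):
        raise ImageFormatError(f"{path}: label image must be integer-typed")
    return arr


def write_label_mask(labels: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a label image as 16- or 32-bit TIFF depending on label range."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint16 if labels.max(initial=0) < 2 ** 16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    return path
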