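"""Export of cell tables: TSV, XLSX and merged FCS 3.1.

The FCS file carries one event per cell. Parameters are the geometry
columns (Area, X, Y, Circ, AR, Round, Solidity) plus, for every channel,
<name>_Mean, <name>_IntDen, <name>_RawIntDen and <name>_CTCF — i.e. one
wide row pivoted from the long measurement table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["write_tsv", "write_xlsx", "merge_to_fcs", "pivot_wide", "write_fcs"]

_GEOMETRY = ["Area", "X", "Y", "Circ", "AR", "Round", "Solidity"]
_PER_CHANNEL = ["Mean", "IntDen", "RawIntDen", "CTCF"]


def write_tsv(records: pd.DataFrame, path: str | Path) -> Path:
    """Tab-separated export with header, UTF-8, '.' decimal separator."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if records.empty:
        logger.warning("writing header-only TSV: no records")
    records.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def write_xlsx(records: pd.DataFrame, path: str | Path) -> Path:
    """XLSX export: one sheet per channel label plus a merged sheet."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pd.ExcelWriter(path, engine="openpyxl") as xw:
        records.to_excel(xw, sheet_name="merged", index=False)
        if "Label" in records.columns:
            for label, sub in records.groupby("Label", sort=False):
                # Excel sheet names are capped at 31 chars
                sub.to_excel(xw, sheet_name=str(label)[:31], index=False)
    return path


def pivot_wide(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long cell table to one row per cell.

    Geometry columns are taken from the first channel's rows after
    asserting they agree across channels (they are measured once on the
    mask, so they must).
    """
    if records.empty:
        raise ValueError("cannot pivot an empty record set")
    channels = list(dict.fromkeys(records["Label"]))
    cells = np.sort(records["Cell"].unique())
    by_channel = {}
    for ch in channels:
        sub = records[records["Label"] == ch].set_index("Cell").sort_index()
        missing = set(cells) - set(sub.index)
        if missing:
            raise ValueError(
                f"cell(s) {sorted(missing)[:5]} missing a row for channel {ch!r}"
            )
        by_channel[ch] = sub
    first = by_channel[channels[0]]
    geo_map = {"Circ": "Circ."}
    wide = pd.DataFrame({"Cell": cells}).set_index("Cell")
    for col in _GEOMETRY:
        src = geo_map.get(col, col)
        wide[col] = first[src]
        for ch in channels[1:]:
            if not np.allclose(by_channel[ch][src], first[src], equal_nan=True):
                raise AssertionError(
                    f"geometry column {src} differs between channels "
                    f"{channels[0]!r} and {ch!r}"
                )
    for ch in channels:
        for col in _PER_CHANNEL:
            wide[f"{ch}_{col}"] = by_channel[ch][col]
    return wide.reset_index()


def write_fcs(
    path: str | Path,
    data: np.ndarray,
    short_names: list[str],
    long_names: list[str] | None = None,
    extra_keywords: dict[str, str] | None = None,
) -> Path:
    """Write a minimal single-dataset FCS 3.1 file.

    Little-endian 32-bit float list-mode data; ``data`` has shape
    (n_events, n_params). Short names go to $PnN, display names to $PnS.
    """
    data = np.ascontiguousarray(data, dtype="<f4")
    if data.ndim != 2:
        raise ValueError("data must be 2D (events x parameters)")
    n_events, n_params = data.shape
    if len(short_names) != n_params:
        raise ValueError("one short name per parameter required")
    long_names = long_names or short_names

    delim = "/"

    def esc(v: str) -> str:
        return str(v).replace(delim, delim + delim)

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_params),
        "$TOT": str(n_events),
    }
    for i, (sn, ln) in enumerate(zip(short_names, long_names), start=1):
        col = data[:, i - 1]
        finite = col[np.isfinite(col)]
        top = float(finite.max()) if finite.size else 1.0
        rng = max(1, int(np.ceil(top)) + 1)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = sn
        keywords[f"$P{i}S"] = ln
        keywords[f"$P{i}R"] = str(rng)
    if extra_keywords:
        keywords.update({k: str(v) for k, v in extra_keywords.items()})

    # fixed-width offsets so TEXT length does not depend on their digits
    begin_data_key, end_data_key = "$BEGINDATA", "$ENDDATA"
    placeholder = "0" * 12

    def render_text(begin_data: str, end_data: str) -> bytes:
        parts = [delim]
        items = dict(keywords)
        items[begin_data_key] = begin_data
        items[end_data_key] = end_data
        for k in sorted(items):
            parts.append(f"{esc(k)}{delim}{esc(items[k])}{delim}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text_start = 64
    text = render_text(placeholder, placeholder)
    text_end = text_start + len(text) - 1
    data_start = text_start + len(text)
    data_end = data_start + data.nbytes - 1
    text = render_text(str(data_start).zfill(12), str(data_end).zfill(12))
    assert text_start + len(text) == data_start

    def off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_start) + off(text_end)
    header += off(data_start if data_end <= 99_999_999 else 0)
    header += off(data_end if data_end <= 99_999_999 else 0)
    header += off(0) + off(0)
    assert len(header) == header_len

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - header_len))
        fh.write(text)
        fh.write(data.tobytes())
    return path


def merge_to_fcs(records: pd.DataFrame, roi_name: str, path: str | Path) -> Path:
    """Merge the long cell table into one FCS 3.1 file for the ROI."""
    wide = pivot_wide(records)
    param_cols = [c for c in wide.columns if c != "Cell"]
    data = wide[param_cols].to_numpy(dtype=np.float64)
    # FCS readers dislike NaN; flagged-undefined descriptors become 0
    data = np.nan_to_num(data, nan=0.0)
    return write_fcs(
        path,
        data.astype(np.float32),
        short_names=param_cols,
        long_names=param_cols,
        extra_keywords={"$FIL": str(Path(path).name), "$SRC": roi_name},
    )
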