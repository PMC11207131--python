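"""Stack and table I/O.

Intensity and label stacks travel as multi-page TIFF (T pages of H x W,
unsigned 16-bit on disk). Tables travel as CSV with leading ``#`` comment
lines declaring units and the coordinate convention; read them back with
``read_table`` (or ``pandas.read_csv(..., comment="#")``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

_CONVENTION = ("coordinates: x=column, y=row, 0-based, pixel centers at "
               "integers; time in frames (0-based)")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a T x H x W array (T=1 for single pages)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages, got array of shape {arr.shape}")
    return arr


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a stack as unsigned 16-bit multi-page TIFF (values clipped)."""
    path = Path(path)
    arr = np.asarray(stack)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(np.rint(arr), 0, 65535)
    arr = arr.astype(np.uint16)
    tifffile.imwrite(str(path), arr, photometric="minisblack")
    return path


def write_table(df: pd.DataFrame, path: str | Path,
                units: str = "px, px^2, counts, frames") -> Path:
    """Write a CSV with a metadata comment header (units + convention)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {_CONVENTION}\n# units: {units}\n")
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
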