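"""TIFF stack and CSV I/O.

Pixel size is always taken from configuration, never from TIFF tags, whose
dialects are unreliable across acquisition software; a notice is logged
whenever a stack is read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)


def read_image_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF as a (T, H, W) array, bit depth preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise IOError(f"{path}: expected a 2D image or a stack, got shape {arr.shape}")
    logger.info("read %s: %d frame(s) of %dx%d; pixel size comes from config, "
                "TIFF tags are ignored", path, *arr.shape)
    return arr


def write_image_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) or (H, W) array as a multi-page TIFF.

    Float data are rounded and clipped into uint16; integer data are written
    as-is.
    """
    stack = np.asarray(stack)
    if np.issubdtype(stack.dtype, np.floating):
        stack = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, stack)


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with header row, '.' decimal, UTF-8, no index column."""
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    return pd.read_csv(path)
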