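"""File-format helpers: 16-bit TIFF channels/masks and documented CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


def save_tiff_u16(path: str | Path, array: np.ndarray) -> None:
    """Write an intensity image or label mask as 16-bit grayscale TIFF.

    Float intensities are rounded and clipped to the uint16 range.
    """
    arr = np.asarray(array)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max)
    arr = arr.astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def load_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))
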