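"""TIFF stack I/O helpers (16-bit grayscale, single- or multi-frame)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack"]


def read_stack(path) -> np.ndarray:
    """Read a TIFF as a float array: (h, w) or (frames, h, w)."""
    arr = tifffile.imread(str(path))
    return np.asarray(arr, dtype=float)


def write_stack(path, stack: np.ndarray) -> Path:
    """Write a float stack as 16-bit grayscale TIFF (values clipped to uint16)."""
    path = Path(path)
    arr = np.clip(np.asarray(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)
    return path
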