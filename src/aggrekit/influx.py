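"""Per-liposome calcium-influx quantification.

A membrane-permeabilization assay images surface-tethered, dye-loaded
liposomes three times: before sample addition (blank), after incubation
with the sample, and after full activation with the ionophore ionomycin.
Each stack is averaged, the three frames are registered by integer-pixel
cross-correlation, liposomes are located in the ionomycin frame with a
maximum filter, and per-liposome influx is

    %Influx = (F_sample - F_blank) / (F_ionomycin - F_blank) * 100

with F_* integrated over a radius-3-px disk around each peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "InfluxTriplet",
    "LiposomeRecord",
    "average_stack",
    "align_by_crosscorr",
    "find_liposome_peaks",
    "measure_influx",
    "records_to_frame",
]

#: pixels with centre distance <= 3.0 px from the peak (29 pixels)
DISK_RADIUS = 3.0


@dataclass
class InfluxTriplet:
    """Averaged and co-registered blank / sample / ionomycin frames."""

    f_blank: np.ndarray
    f_sample: np.ndarray
    f_ionomycin: np.ndarray
    shifts: dict = field(default_factory=dict)   # name -> (dx, dy) applied

    @classmethod
    def from_stacks(cls, blank, sample, ionomycin, max_shift: int = 20) -> "InfluxTriplet":
        """Average each stack and align sample/ionomycin to the blank."""
        fb = average_stack(blank)
        fs = average_stack(sample)
        fi = average_stack(ionomycin)
        fs, sh_s = align_by_crosscorr(fb, fs, max_shift=max_shift)
        fi, sh_i = align_by_crosscorr(fb, fi, max_shift=max_shift)
        return cls(fb, fs, fi, shifts={"blank": (0, 0), "sample": sh_s, "ionomycin": sh_i})


@dataclass
class LiposomeRecord:
    """One liposome's peak position, integrated intensities, and influx."""

    peak: tuple[int, int]       # (x, y) px
    i_blank: float
    i_sample: float
    i_ionomycin: float
    influx_percent: float
    valid: bool = True


def average_stack(stack: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean over frames; a single 2-D frame passes through."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, h, w) array")
    return stack.mean(axis=0)


def align_by_crosscorr(reference: np.ndarray, moving: np.ndarray,
                       max_shift: int = 20) -> tuple[np.ndarray, tuple[int, int]]:
    """Integer-pixel registration maximizing normalized cross-correlation.

    Returns the translated moving frame (vacated edges filled with the
    frame median) and the (dx, dy) shift applied. Flat inputs (zero
    variance) return shift (0, 0).
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("frames must share a shape")
    a = ref - ref.mean()
    b = mov - mov.mean()
    if a.std() == 0 or b.std() == 0:
        return mov.copy(), (0, 0)
    # cross-correlation via FFT; circular wrap is irrelevant within max_shift
    cc = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape)
    h, w = a.shape
    dys = np.r_[np.arange(0, max_shift + 1), np.arange(-max_shift, 0)]
    dxs = dys.copy()
    sub = cc[np.ix_(dys % h, dxs % w)]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    dy, dx = int(dys[iy]), int(dxs[ix])
    shifted = ndimage.shift(mov, (dy, dx), order=0, mode="constant",
                            cval=float(np.median(mov)))
    return shifted, (dx, dy)


def find_liposome_peaks(ionomycin_frame: np.ndarray, threshold: float,
                        window: int = 5) -> list[tuple[int, int]]:
    """Locate liposomes as maximum-filter peaks above background + threshold.

    Background is the frame median. Peaks closer than the window are
    merged to the brighter one. Returns (x, y) integer pixel positions.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    frame = np.asarray(ionomycin_frame, dtype=float)
    background = float(np.median(frame))
    mf = ndimage.maximum_filter(frame, size=window, mode="nearest")
    cand = np.argwhere((frame == mf) & (frame > background + threshold))
    if cand.size == 0:
        return []
    # merge near-duplicates (plateaus / close peaks) keeping the brighter
    vals = frame[cand[:, 0], cand[:, 1]]
    order = np.argsort(-vals, kind="stable")
    kept: list[tuple[int, int]] = []
    for i in order:
        y, x = cand[i]
        if all((x - kx) ** 2 + (y - ky) ** 2 >= window**2 for kx, ky in kept):
            kept.append((int(x), int(y)))
    return kept


def _disk_indices(shape, cx, cy, radius=DISK_RADIUS):
    h, w = shape
    r = int(np.ceil(radius))
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return yy[inside], xx[inside]


def measure_influx(triplet: InfluxTriplet, peaks, floor: float = 10.0,
                   clip: bool = False) -> list[LiposomeRecord]:
    """Integrate the three frames over each peak's disk and apply the formula.

    Records whose ionomycin-minus-blank denominator is below ``floor``
    counts are flagged invalid (influx_percent = nan) rather than divided.
    Influx is not clipped to [0, 100] unless ``clip`` is set: out-of-range
    values are meaningful noise.
    """
    records: list[LiposomeRecord] = []
    shape = triplet.f_blank.shape
    for (cx, cy) in peaks:
        ys, xs = _disk_indices(shape, int(cx), int(cy))
        ib = float(triplet.f_blank[ys, xs].sum())
        is_ = float(triplet.f_sample[ys, xs].sum())
        ii = float(triplet.f_ionomycin[ys, xs].sum())
        denom = ii - ib
        if abs(denom) < floor:
            records.append(LiposomeRecord((int(cx), int(cy)), ib, is_, ii,
                                          float("nan"), valid=False))
            continue
        influx = (is_ - ib) / denom * 100.0
        if clip:
            influx = float(np.clip(influx, 0.0, 100.0))
        records.append(LiposomeRecord((int(cx), int(cy)), ib, is_, ii, influx))
    return records


def records_to_frame(records: list[LiposomeRecord]) -> pd.DataFrame:
    """Tabulate liposome records (one row per liposome)."""
    return pd.DataFrame(
        {
            "x": [r.peak[0] for r in records],
            "y": [r.peak[1] for r in records],
            "I_blank": [r.i_blank for r in records],
            "I_sample": [r.i_sample for r in records],
            "I_iono": [r.i_ionomycin for r in records],
            "influx_percent": [r.influx_percent for r in records],
            "valid": [r.valid for r in records],
        }
    )
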