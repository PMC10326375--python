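"""Minimal single-molecule localizer, drift correction, and table I/O.

The localizer is intentionally small: per frame, local-maximum candidates
above mean + k*SD are refined by least-squares 2-D Gaussian fitting (with
an intensity-weighted centroid fallback) in a 7x7 window, and sub-pixel
positions are converted to nanometres. Users with tables from full-featured
localization software bypass it entirely via :func:`read_localizations`,
which understands the common CSV dialects (native, ThunderSTORM-style
"[nm]" headers, GDSC-style pixel columns).

Drift correction identifies fiducial markers as localization chains that
persist in >= 90% of frames within one camera pixel, averages their
per-frame displacement from the first frame (smoothed by a 10-frame moving
average), subtracts it from every localization, and drops the fiducials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "Localization",
    "FiducialTrack",
    "LocalizeParams",
    "localize_stack",
    "find_fiducials",
    "correct_drift",
    "read_localizations",
    "write_localizations",
    "locs_to_frame",
    "frame_to_locs",
]


@dataclass
class Localization:
    """One emitter fix: frame index, position in nm, intensity, fit width."""

    frame: int
    x: float            # nm
    y: float            # nm
    intensity: float    # counts
    sigma: float = 0.0  # nm
    id: int = -1


@dataclass
class FiducialTrack:
    """An always-on landmark: anchor position and per-frame displacements."""

    site: tuple[float, float]         # (x, y) nm, first-frame position
    frames: np.ndarray                # frame indices where seen
    displacements: np.ndarray         # (n_frames, 2) nm, nan where unseen


@dataclass
class LocalizeParams:
    threshold_k: float = 5.0          # candidate threshold: mean + k*SD
    pixel_nm: float = 100.0           # camera pixel size
    window: int = 7                   # fit window side (odd)
    min_separation: int = 3           # px between candidate maxima

    def validate(self) -> None:
        if self.threshold_k <= 0 or self.pixel_nm <= 0:
            raise ValueError("threshold_k and pixel_nm must be > 0")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset


def _fit_spot(patch: np.ndarray, x_off: float, y_off: float):
    """LSQ 2-D Gaussian fit in a window; centroid fallback on divergence.

    Returns (x, y, intensity, sigma) in px, or None if even the fallback
    is degenerate.
    """
    h, w = patch.shape
    yy, xx = np.mgrid[0:h, 0:w]
    offset0 = float(patch.min())
    amp0 = float(patch.max() - offset0)
    if amp0 <= 0:
        return None
    cy0, cx0 = np.unravel_index(np.argmax(patch), patch.shape)
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            patch.ravel(),
            p0=(amp0, float(cx0), float(cy0), 1.3, offset0),
            bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, w, h, w, np.inf]),
            maxfev=200,
        )
        amp, x0, y0, sigma, _ = popt
        if not (0 <= x0 < w and 0 <= y0 < h):
            raise RuntimeError("fit outside window")
        return x_off + x0, y_off + y0, float(amp), float(abs(sigma))
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        wgt = patch - offset0
        tot = wgt.sum()
        if tot <= 0:
            return None
        x0 = float((xx * wgt).sum() / tot)
        y0 = float((yy * wgt).sum() / tot)
        return x_off + x0, y_off + y0, amp0, 0.0


def localize_stack(stack: np.ndarray, params: LocalizeParams | None = None) -> list[Localization]:
    """Localize emitters in every frame of a stack.

    Candidates are local maxima above mean + k*SD of their frame; each is
    refined in a ``window``-sized patch. Candidates whose fit and fallback
    both degenerate are dropped.
    """
    params = params or LocalizeParams()
    params.validate()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    half = params.window // 2
    locs: list[Localization] = []
    next_id = 0
    for f in range(stack.shape[0]):
        frame = stack[f]
        thr = frame.mean() + params.threshold_k * frame.std()
        mf = ndimage.maximum_filter(frame, size=params.min_separation, mode="nearest")
        ys, xs = np.nonzero((frame == mf) & (frame > thr))
        h, w = frame.shape
        for y, x in zip(ys, xs):
            if not (half <= x < w - half and half <= y < h - half):
                continue
            patch = frame[y - half:y + half + 1, x - half:x + half + 1]
            res = _fit_spot(patch, x - half, y - half)
            if res is None:
                continue
            px, py, amp, sig = res
            locs.append(Localization(
                frame=f,
                x=px * params.pixel_nm,
                y=py * params.pixel_nm,
                intensity=amp,
                sigma=sig * params.pixel_nm,
                id=next_id,
            ))
            next_id += 1
    return locs


def find_fiducials(locs: list[Localization], n_frames: int,
                   pixel_nm: float = 100.0, occupancy: float = 0.9) -> list[FiducialTrack]:
    """Identify fiducials as chains persisting in >= ``occupancy`` of frames.

    Localizations are linked to a chain when they fall within one camera
    pixel of its running anchor. Detection is by persistence, not
    brightness, so no intensity convention is assumed of the data.
    """
    radius = pixel_nm
    # chains track a *running* anchor (last seen position) so slow drift
    # larger than one pixel in total does not break the chain
    chains: list[dict] = []   # {"last": (x, y), "frames": {f: (x, y)}}
    for loc in sorted(locs, key=lambda l: l.frame):
        placed = False
        for ch in chains:
            ax, ay = ch["last"]
            if (loc.x - ax) ** 2 + (loc.y - ay) ** 2 <= radius**2:
                if loc.frame not in ch["frames"]:
                    ch["frames"][loc.frame] = (loc.x, loc.y)
                    ch["last"] = (loc.x, loc.y)
                placed = True
                break
        if not placed:
            chains.append({"last": (loc.x, loc.y), "frames": {loc.frame: (loc.x, loc.y)}})
    tracks: list[FiducialTrack] = []
    for ch in chains:
        if len(ch["frames"]) < occupancy * n_frames:
            continue
        first_f = min(ch["frames"])
        fx, fy = ch["frames"][first_f]
        disp = np.full((n_frames, 2), np.nan)
        for f, (x, y) in ch["frames"].items():
            disp[f] = (x - fx, y - fy)
        tracks.append(FiducialTrack(site=(fx, fy),
                                    frames=np.array(sorted(ch["frames"])),
                                    displacements=disp))
    return tracks


def _moving_average(series: np.ndarray, window: int = 10) -> np.ndarray:
    """NaN-tolerant centered moving average along axis 0."""
    n = series.shape[0]
    out = np.empty_like(series)
    half = window // 2
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[i] = np.nanmean(series[lo:hi], axis=0)
    return np.nan_to_num(out)


def correct_drift(locs: list[Localization], fiducials: list[FiducialTrack],
                  n_frames: int | None = None, smooth_window: int = 10,
                  pixel_nm: float = 100.0) -> tuple[list[Localization], np.ndarray]:
    """Subtract fiducial-derived drift; remove fiducial localizations.

    Per-frame drift is the mean fiducial displacement from its first-frame
    position, smoothed with a moving average. Returns the corrected
    localizations and the estimated (n_frames, 2) drift trace in nm. With
    no fiducials, correction is skipped with a warning and the input
    (unchanged) is returned with a zero trace.
    """
    if n_frames is None:
        n_frames = max((l.frame for l in locs), default=0) + 1
    if not fiducials:
        warnings.warn("no fiducial found; drift correction skipped")
        return list(locs), np.zeros((n_frames, 2))
    disp = np.stack([f.displacements[:n_frames] for f in fiducials])  # (k, n, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        drift = np.nanmean(disp, axis=0)
    drift = _moving_average(drift, smooth_window)

    fid_sites = [f.site for f in fiducials]
    radius = pixel_nm
    out: list[Localization] = []
    for loc in locs:
        dx, dy = drift[loc.frame]
        is_fid = any((loc.x - dx - ax) ** 2 + (loc.y - dy - ay) ** 2 <= radius**2
                     for ax, ay in fid_sites)
        if is_fid:
            continue
        out.append(Localization(loc.frame, loc.x - dx, loc.y - dy,
                                loc.intensity, loc.sigma, loc.id))
    return out, drift


# ---------------------------------------------------------------------------
# CSV dialects

_NATIVE_COLS = ["frame", "x_nm", "y_nm", "intensity", "sigma_nm"]


def locs_to_frame(locs: list[Localization]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [l.frame for l in locs],
            "x_nm": [l.x for l in locs],
            "y_nm": [l.y for l in locs],
            "intensity": [l.intensity for l in locs],
            "sigma_nm": [l.sigma for l in locs],
        }
    )


def frame_to_locs(df: pd.DataFrame) -> list[Localization]:
    return [
        Localization(int(r.frame), float(r.x_nm), float(r.y_nm),
                     float(r.intensity), float(r.sigma_nm), id=i)
        for i, r in enumerate(df.itertuples(index=False))
    ]


def _find_col(df: pd.DataFrame, needles: list[str]) -> str | None:
    for col in df.columns:
        name = col.strip().strip('"').lower()
        for needle in needles:
            if needle in name:
                return col
    return None


def read_localizations(path, dialect: str = "native",
                       pixel_nm: float = 100.0) -> list[Localization]:
    """Read a localization table.

    dialects: ``native`` (frame, x_nm, y_nm, intensity, sigma_nm);
    ``thunderstorm`` — columns labelled with "[nm]" units, e.g.
    ``x [nm]``; ``gdsc`` — pixel-unit X/Y columns converted with
    ``pixel_nm``. Missing coordinate columns raise ValueError naming the
    field.
    """
    df = pd.read_csv(path)
    if dialect == "native":
        for col in ("frame", "x_nm", "y_nm"):
            if col not in df.columns:
                raise ValueError(f"native table missing column {col!r}")
        if "intensity" not in df.columns:
            df["intensity"] = 0.0
        if "sigma_nm" not in df.columns:
            df["sigma_nm"] = 0.0
        return frame_to_locs(df[_NATIVE_COLS])
    if dialect == "thunderstorm":
        xcol = _find_col(df, ["x [nm]"])
        ycol = _find_col(df, ["y [nm]"])
        if xcol is None or ycol is None:
            raise ValueError("ThunderSTORM table missing 'x [nm]' / 'y [nm]' columns")
        fcol = _find_col(df, ["frame"]) or "frame"
        icol = _find_col(df, ["intensity"])
        scol = _find_col(df, ["sigma [nm]", "sigma1 [nm]"])
        out = pd.DataFrame({
            "frame": df[fcol] if fcol in df.columns else 0,
            "x_nm": df[xcol],
            "y_nm": df[ycol],
            "intensity": df[icol] if icol else 0.0,
            "sigma_nm": df[scol] if scol else 0.0,
        })
        return frame_to_locs(out)
    if dialect == "gdsc":
        xcol = _find_col(df, ["origx", "x (px)", "x [px]"]) or ("X" if "X" in df.columns else None)
        ycol = _find_col(df, ["origy", "y (px)", "y [px]"]) or ("Y" if "Y" in df.columns else None)
        if xcol is None or ycol is None:
            raise ValueError("GDSC table missing X / Y pixel columns")
        fcol = _find_col(df, ["frame"])
        icol = _find_col(df, ["signal", "intensity"])
        out = pd.DataFrame({
            "frame": df[fcol] if fcol else 0,
            "x_nm": df[xcol] * pixel_nm,
            "y_nm": df[ycol] * pixel_nm,
            "intensity": df[icol] if icol else 0.0,
            "sigma_nm": 0.0,
        })
        return frame_to_locs(out)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_localizations(locs: list[Localization], path, dialect: str = "native") -> None:
    """Write a localization table; only the native dialect is written."""
    if dialect != "native":
        raise ValueError("only the native dialect is written")
    locs_to_frame(locs).to_csv(path, index=False)
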