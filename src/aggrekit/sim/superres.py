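"""Simulator for blinking super-resolution (PAINT-style) image stacks.

Dot- or line-shaped structures are rasterized on a fine canvas (default
2500x2500 px, 20 nm/px). Every occupied canvas pixel is a potential
blinking site: per frame, each site turns ON independently and renders a
diffraction-limited Gaussian spot on the coarse camera image (default
500x500 px, 100 nm/px; canvas coordinates divided by the scale factor).
Always-on fiducial markers at 5x the mean spot intensity and a cumulative
random-walk stage drift complete the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _bresenham_line

__all__ = ["SRSimParams", "SRGroundTruth", "simulate_structures", "simulate_blinking_stack"]


@dataclass
class SRSimParams:
    """Parameters of the super-resolution blinking-stack simulator."""

    canvas_size: int = 2500
    camera_size: int = 500
    scale_factor: int = 5
    n_frames: int = 1000
    structure_type: str = "line"                     # {"dot", "line"}
    n_structures: int = 10
    length_distribution: tuple[float, float] = (100.0, 20.0)       # canvas px, normal
    dot_diameter_distribution: tuple[float, float] = (4.0, 1.0)    # canvas px, normal
    on_probability: float = 0.005
    spot_intensity: tuple[float, float] = (1000.0, 100.0)          # counts, normal
    background: tuple[float, float] = (100.0, 10.0)                # counts, normal
    psf_sigma: float = 1.1                           # camera px
    n_fiducials: int = 3
    fiducial_intensity_factor: float = 5.0
    drift_per_frame: float = 0.0                     # camera px per step
    super_res_pixel_nm: float = 20.0
    camera_pixel_nm: float = 100.0
    seed: int | None = None

    def validate(self) -> None:
        if self.canvas_size != self.camera_size * self.scale_factor:
            raise ValueError("canvas_size must equal camera_size * scale_factor")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 <= self.on_probability < 1):
            raise ValueError("on_probability must be in [0, 1)")
        if self.fiducial_intensity_factor <= 0:
            raise ValueError("fiducial_intensity_factor must be > 0")
        if self.structure_type not in ("dot", "line"):
            raise ValueError("structure_type must be 'dot' or 'line'")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")


@dataclass
class SRGroundTruth:
    """Ground truth of one simulated stack.

    ``sites`` holds occupied canvas pixels as an (n, 2) integer array in
    (x, y) order; ``structure_id`` maps each site to its structure.
    ``true_lengths_nm`` is the Euclidean end-to-end length for lines and
    the diameter for dots. ``drift`` (filled by the stack simulator) is
    the per-frame cumulative (dx, dy) in camera px.
    """

    sites: np.ndarray
    structure_id: np.ndarray
    structure_type: str
    true_lengths_nm: np.ndarray
    super_res_pixel_nm: float = 20.0
    camera_pixel_nm: float = 100.0
    drift: np.ndarray | None = None
    fiducials: np.ndarray | None = None   # (k, 2) camera-px positions


def _sample_line(rng, canvas, length_px):
    """Random segment of given length fully inside the canvas."""
    for _ in range(200):
        theta = rng.uniform(0, np.pi)
        x0 = rng.uniform(0, canvas - 1)
        y0 = rng.uniform(0, canvas - 1)
        x1 = x0 + length_px * np.cos(theta)
        y1 = y0 + length_px * np.sin(theta)
        if 0 <= x1 <= canvas - 1 and 0 <= y1 <= canvas - 1:
            return (x0, y0, x1, y1)
    raise ValueError(f"cannot place a structure of length {length_px} inside the canvas")


def simulate_structures(params: SRSimParams) -> SRGroundTruth:
    """Place and rasterize ground-truth structures on the canvas.

    Lines are 1-px-wide Bresenham strokes; dots are filled disks. A
    requested structure larger than the canvas is resampled from the
    length distribution; an impossible request raises ValueError.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    canvas = params.canvas_size
    sites_x, sites_y, sid, lengths = [], [], [], []
    for i in range(params.n_structures):
        if params.structure_type == "line":
            mu, sd = params.length_distribution
            for _ in range(200):
                length = rng.normal(mu, sd)
                if 1.0 <= length <= canvas * 0.9:
                    break
            else:
                raise ValueError("cannot draw a feasible structure length")
            x0, y0, x1, y1 = _sample_line(rng, canvas, length)
            rr, cc = _bresenham_line(int(round(y0)), int(round(x0)),
                                     int(round(y1)), int(round(x1)))
            true_len = np.hypot(x1 - x0, y1 - y0) * params.super_res_pixel_nm
        else:
            mu, sd = params.dot_diameter_distribution
            for _ in range(200):
                diam = rng.normal(mu, sd)
                if 1.0 <= diam <= canvas * 0.9:
                    break
            else:
                raise ValueError("cannot draw a feasible dot diameter")
            r = diam / 2.0
            cx = rng.uniform(r + 1, canvas - r - 2)
            cy = rng.uniform(r + 1, canvas - r - 2)
            yy, xx = np.mgrid[int(cy - r) - 1:int(cy + r) + 2, int(cx - r) - 1:int(cx + r) + 2]
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            rr, cc = yy[inside], xx[inside]
            if rr.size == 0:   # sub-pixel dot still occupies its centre pixel
                rr = np.array([int(round(cy))]); cc = np.array([int(round(cx))])
            true_len = diam * params.super_res_pixel_nm
        keep = (rr >= 0) & (rr < canvas) & (cc >= 0) & (cc < canvas)
        rr, cc = rr[keep], cc[keep]
        sites_x.append(cc)
        sites_y.append(rr)
        sid.append(np.full(rr.size, i, dtype=int))
        lengths.append(true_len)
    if sites_x:
        sites = np.column_stack([np.concatenate(sites_x), np.concatenate(sites_y)]).astype(int)
        structure_id = np.concatenate(sid)
    else:
        sites = np.zeros((0, 2), dtype=int)
        structure_id = np.zeros(0, dtype=int)
    return SRGroundTruth(
        sites=sites,
        structure_id=structure_id,
        structure_type=params.structure_type,
        true_lengths_nm=np.asarray(lengths, dtype=float),
        super_res_pixel_nm=params.super_res_pixel_nm,
        camera_pixel_nm=params.camera_pixel_nm,
    )


def _stamp_spots(frame, xs, ys, amps, sigma):
    """Accumulate Gaussian spots (camera-px coordinates) into frame."""
    size = frame.shape[0]
    half = max(int(np.ceil(3.5 * sigma)), 2)
    for cx, cy, amp in zip(xs, ys, amps):
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, size)
        y0c, y1c = max(y0, 0), min(y1, size)
        if x0c >= x1c or y0c >= y1c:
            continue
        gx = np.exp(-((np.arange(x0c, x1c) - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((np.arange(y0c, y1c) - cy) ** 2) / (2 * sigma**2))
        frame[y0c:y1c, x0c:x1c] += amp * np.outer(gy, gx)


def simulate_blinking_stack(truth: SRGroundTruth, params: SRSimParams) -> np.ndarray:
    """Render the blinking camera stack for a set of ground-truth sites.

    Returns an (n_frames, camera_size, camera_size) float array. Side
    effects on ``truth``: stores the per-frame cumulative drift trace and
    the fiducial camera positions, so downstream drift correction can be
    validated against the exact truth.
    """
    params.validate()
    rng = np.random.default_rng(None if params.seed is None else params.seed + 1)
    cam = params.camera_size
    nf = params.n_frames
    bg_mu, bg_sd = params.background
    sp_mu, sp_sd = params.spot_intensity

    # always-on fiducials at 5x the mean spot intensity, away from edges
    fid = rng.uniform(cam * 0.1, cam * 0.9, size=(params.n_fiducials, 2))
    truth.fiducials = fid

    # cumulative random walk: each step moves one axis by +-drift_per_frame or 0
    steps = np.zeros((nf, 2))
    if params.drift_per_frame > 0:
        axis = rng.integers(0, 2, size=nf)
        mag = rng.choice([-params.drift_per_frame, 0.0, params.drift_per_frame], size=nf)
        steps[np.arange(nf), axis] = mag
        steps[0] = 0.0
    drift = np.cumsum(steps, axis=0)
    truth.drift = drift

    site_cam = truth.sites.astype(float) / params.scale_factor  # (n, 2) x, y
    stack = np.empty((nf, cam, cam), dtype=float)
    for f in range(nf):
        frame = rng.normal(bg_mu, bg_sd, size=(cam, cam))
        dx, dy = drift[f]
        if site_cam.shape[0]:
            on = rng.random(site_cam.shape[0]) < params.on_probability
            if on.any():
                amps = np.clip(rng.normal(sp_mu, sp_sd, size=int(on.sum())), 0, None)
                _stamp_spots(frame, site_cam[on, 0] + dx, site_cam[on, 1] + dy,
                             amps, params.psf_sigma)
        if params.n_fiducials:
            famps = np.full(params.n_fiducials, params.fiducial_intensity_factor * sp_mu)
            _stamp_spots(frame, fid[:, 0] + dx, fid[:, 1] + dy, famps, params.psf_sigma)
        stack[f] = frame
    return stack
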