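"""DBSCAN clustering of localizations and per-aggregate morphometrics.

Localizations belonging to one aggregate are grouped with DBSCAN
(radius eps in nm, minimum neighbour count min_pts, self included);
un-clustered points are noise and discarded. Each cluster is reported
with its localization count, rendered area, convex-hull area, covariance
major-axis length, eccentricity, and a skeleton-based length: the cluster
is rasterized at the super-resolution pixel size (default 20 nm/px),
thinned to a one-pixel skeleton, and traversed by nearest-neighbour hops,
summing 1 px per axial step and sqrt(2) px per diagonal step over all
branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy import ndimage
from skimage.morphology import skeletonize
from sklearn.cluster import DBSCAN

__all__ = [
    "DBSCANParams",
    "ClusterMetrics",
    "dbscan",
    "render_cluster",
    "skeleton_length",
    "cluster_metrics",
    "analyze_clusters",
]


@dataclass
class DBSCANParams:
    """eps: search radius in nm; min_pts: minimum neighbours (self included)."""

    eps: float = 60.0       # 3 x render pixel (20 nm) by default
    min_pts: int = 5

    def validate(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class ClusterMetrics:
    """Structure report of one aggregate."""

    cluster_id: int
    n_localizations: int
    area_nm2: float
    convex_hull_area_nm2: float
    major_axis_nm: float
    eccentricity: float
    skeleton_length_nm: float


def dbscan(points: np.ndarray, params: DBSCANParams | None = None) -> np.ndarray:
    """Standard DBSCAN labels; -1 marks noise.

    A core point has >= min_pts neighbours within eps, counting itself.
    Deterministic given input order (border-point ties resolve to the
    first-reached cluster).
    """
    params = params or DBSCANParams()
    params.validate()
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return np.zeros(0, dtype=int)
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    return DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(points)


def render_cluster(points: np.ndarray, render_pixel_nm: float = 20.0) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize a point cluster to a binary occupancy grid.

    The grid covers the bounding box plus a 1-px pad; a pixel is ON when
    at least one localization falls in it. A single 3x3 binary closing
    fills 1-px gaps. Returns (mask, origin) with origin the nm coordinate
    of pixel (0, 0).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise ValueError("render_cluster needs at least one point")
    ix = np.floor(points[:, 0] / render_pixel_nm).astype(int)
    iy = np.floor(points[:, 1] / render_pixel_nm).astype(int)
    x0, y0 = ix.min() - 1, iy.min() - 1
    w = ix.max() - x0 + 2
    h = iy.max() - y0 + 2
    mask = np.zeros((h, w), dtype=bool)
    mask[iy - y0, ix - x0] = True
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
    return mask, (x0 * render_pixel_nm, y0 * render_pixel_nm)


def skeleton_length(mask: np.ndarray, render_pixel_nm: float = 20.0) -> float:
    """Total branch length of the thinned mask, in nm.

    The mask is thinned to a 1-px topological skeleton; skeleton pixels
    are then traversed by repeated nearest-neighbour hops (axial hop = 1
    pixel, diagonal hop = sqrt(2) pixels; axial preferred on ties),
    restarting at a new branch when the current one is exhausted, so a
    Y-shaped skeleton sums all three arms. A single-pixel skeleton has
    length one render pixel — the minimum resolvable size.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no ON pixel")
    # thinning is idempotent on unit-width chains: a mask with no 2x2 ON
    # block is already a skeleton, and re-thinning it would clip corners
    thick = (mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]).any()
    skel = skeletonize(mask) if thick else mask
    if not skel.any():               # thinning can erase a tiny blob
        skel = mask
    pix = {(int(y), int(x)) for y, x in np.argwhere(skel)}
    if len(pix) == 1:
        return float(render_pixel_nm)

    neighbors = {}
    for (y, x) in pix:
        nb = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                if (y + dy, x + dx) in pix:
                    nb.append((y + dy, x + dx))
        neighbors[(y, x)] = nb

    # start at an endpoint when one exists (degree 1), else anywhere
    start = min((p for p in pix if len(neighbors[p]) == 1), default=min(pix))
    visited = {start}
    frontier = [start]     # visited pixels that may still have unvisited neighbours
    current = start
    total = 0.0
    while len(visited) < len(pix):
        nxt = None
        best = 3.0
        for (ny, nx) in neighbors[current]:
            if (ny, nx) in visited:
                continue
            d = 1.0 if (ny == current[0] or nx == current[1]) else np.sqrt(2.0)
            if d < best:
                best, nxt = d, (ny, nx)
        if nxt is not None:
            total += best
            visited.add(nxt)
            frontier.append(nxt)
            current = nxt
            continue
        # branch exhausted: restart from a visited pixel with unvisited
        # neighbours (a junction); the restart hop itself adds length,
        # measured from that junction
        current = None
        while frontier:
            cand = frontier[-1]
            if any(n not in visited for n in neighbors[cand]):
                current = cand
                break
            frontier.pop()
        if current is None:
            # disconnected skeleton component: jump without adding length
            rest = pix - visited
            current = min(rest)
            visited.add(current)
            frontier.append(current)
    return float(total * render_pixel_nm)


def cluster_metrics(points: np.ndarray, cluster_id: int = 0,
                    render_pixel_nm: float = 20.0) -> ClusterMetrics:
    """Compute the structure report of one cluster of (x, y) nm points.

    - area: ON-pixel count of the rendered mask x (render pixel)^2;
    - convex-hull area: exact hull of the point set (0 when degenerate);
    - major axis and eccentricity from the point covariance eigenvalues
      (ellipse-equivalent: major axis = 4*sqrt(lambda_max),
      ecc = sqrt(1 - lambda_min/lambda_max));
    - skeleton length via render + thinning + traversal.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 1:
        raise ValueError("cluster_metrics needs at least one point")

    mask, _ = render_cluster(points, render_pixel_nm)
    area = float(mask.sum()) * render_pixel_nm**2
    length = skeleton_length(mask, render_pixel_nm)

    hull_area = 0.0
    if n >= 3:
        try:
            hull_area = float(ConvexHull(points).volume)   # 2-D volume = area
        except QhullError:
            hull_area = 0.0

    if n >= 2:
        cov = np.cov(points, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))
        lam_min, lam_max = max(evals[0], 0.0), max(evals[1], 0.0)
        major = 4.0 * np.sqrt(lam_max)
        ecc = np.sqrt(1.0 - lam_min / lam_max) if lam_max > 0 else 0.0
    else:
        major, ecc = 0.0, 0.0

    return ClusterMetrics(
        cluster_id=cluster_id,
        n_localizations=n,
        area_nm2=area,
        convex_hull_area_nm2=hull_area,
        major_axis_nm=float(major),
        eccentricity=float(ecc),
        skeleton_length_nm=float(length),
    )


def analyze_clusters(points: np.ndarray, params: DBSCANParams | None = None,
                     render_pixel_nm: float = 20.0) -> pd.DataFrame:
    """Cluster points and tabulate per-cluster metrics (noise discarded)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        return pd.DataFrame(columns=["cluster_id", "n_locs", "area_nm2",
                                     "hull_area_nm2", "major_axis_nm",
                                     "eccentricity", "length_nm"])
    labels = dbscan(points, params)
    rows = []
    for lab in sorted(set(labels) - {-1}):
        m = cluster_metrics(points[labels == lab], cluster_id=int(lab),
                            render_pixel_nm=render_pixel_nm)
        rows.append({
            "cluster_id": m.cluster_id,
            "n_locs": m.n_localizations,
            "area_nm2": m.area_nm2,
            "hull_area_nm2": m.convex_hull_area_nm2,
            "major_axis_nm": m.major_axis_nm,
            "eccentricity": m.eccentricity,
            "length_nm": m.skeleton_length_nm,
        })
    return pd.DataFrame(rows)
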