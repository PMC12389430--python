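"""Point-cloud pre-processing: crop, thin, denoise, ground model, normalize.

The chain mirrors standard mobile-LiDAR forestry practice: clip the tile to
the surveyed plot, randomly thin to 80% to speed up segmentation,
statistical-outlier-removal (SOR) denoising, ground/non-ground
classification, a TIN digital elevation model (DEM) from the ground points,
and height normalization so that z becomes height above ground.

The ground classifier here is a grid-lowest-point + tolerance envelope, a
deliberately simple stand-in for cloth-simulation filtering; it is adequate
for the smooth synthetic terrain used throughout this project.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay, QhullError, cKDTree

from .cloud import LAS_GROUND, LAS_UNCLASSIFIED, PointCloud


def crop_to_plot(cloud: PointCloud, corners) -> PointCloud:
    """Keep exactly the points inside (boundary inclusive) the plot polygon.

    ``corners`` are the four surveyed marker points (x, y).
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise ValueError("corners must be four (x, y) points")
    poly = shapely.Polygon(corners)
    if (not poly.is_valid) or poly.area <= 0:
        raise ValueError("corners form a degenerate quadrilateral")
    pts = shapely.points(cloud.x, cloud.y)
    keep = shapely.covers(poly, pts)  # covers => boundary inclusive
    return cloud.subset(np.flatnonzero(keep))


def random_sample(
    cloud: PointCloud, retain_fraction: float = 0.8, seed: int = 0
) -> PointCloud:
    """Uniform random thinning without replacement.

    Retains ``round(retain_fraction * n)`` points (banker's rounding);
    survivors keep their input order so reruns are reproducible.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    n = len(cloud)
    if n == 0:
        raise ValueError("empty cloud")
    m = int(round(retain_fraction * n))
    if m == n:
        return cloud.subset(np.arange(n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    return cloud.subset(idx)


def sor_denoise(
    cloud: PointCloud, k: int = 10, n_sigma: float = 2.0
) -> tuple[PointCloud, int]:
    """Statistical outlier removal.

    Each point's mean distance to its ``k`` nearest neighbours is compared
    with the global mean + ``n_sigma`` * sd of that statistic; points
    strictly above the threshold are removed.  Returns (survivors, number
    of points removed).
    """
    n = len(cloud)
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=k + 1)  # first column is self (0)
    mean_d = dist[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + n_sigma * mean_d.std()
    # relative slack so a cloud whose statistics are all equal up to
    # floating-point jitter (sd ~ ulp) loses nothing
    keep = mean_d <= threshold + 1e-9 * mean_d.mean()
    return cloud.subset(np.flatnonzero(keep)), int((~keep).sum())


def classify_ground(
    cloud: PointCloud, cell_size: float = 0.5, height_tolerance: float = 0.2
) -> PointCloud:
    """Label every point ground / non-ground.

    The lowest point in each ``cell_size`` grid cell seeds a lower-envelope
    surface (linear TIN over the seeds, nearest-neighbour outside its hull);
    points within ``height_tolerance`` of the envelope are ground.  The
    result carries a ``classification`` attribute (LAS codes: 2 ground,
    1 unclassified).
    """
    n = len(cloud)
    if n == 0:
        raise ValueError("empty cloud")
    if n == 1:
        return cloud.with_attribute(
            "classification", np.array([LAS_GROUND], dtype=np.int64)
        )
    ix = np.floor((cloud.x - cloud.x.min()) / cell_size).astype(np.int64)
    iy = np.floor((cloud.y - cloud.y.min()) / cell_size).astype(np.int64)
    cell = ix * (iy.max() + 1) + iy
    order = np.lexsort((cloud.z, cell))
    cell_sorted = cell[order]
    first = np.ones(n, dtype=bool)
    first[1:] = cell_sorted[1:] != cell_sorted[:-1]
    seed_idx = order[first]  # lowest point per occupied cell

    seeds = cloud.xyz[seed_idx]
    envelope = _surface_interpolator(seeds)
    dz = cloud.z - envelope(cloud.x, cloud.y)
    label = np.where(dz <= height_tolerance, LAS_GROUND, LAS_UNCLASSIFIED)
    label[seed_idx] = LAS_GROUND
    return cloud.with_attribute("classification", label.astype(np.int64))


def _surface_interpolator(points: np.ndarray):
    """Linear interpolation over (x, y) -> z with nearest fallback."""
    xy, z = points[:, :2], points[:, 2]
    nearest = NearestNDInterpolator(xy, z)
    try:
        linear = LinearNDInterpolator(xy, z)
    except QhullError:
        return lambda x, y: nearest(np.column_stack([x, y])) if np.ndim(x) else nearest([[x, y]])[0]

    def interp(x, y):
        scalar = np.ndim(x) == 0
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        val = linear(pts)
        bad = np.isnan(val)
        if bad.any():
            val[bad] = nearest(pts[bad])
        return val[0] if scalar else val

    return interp


@dataclass
class GroundModel:
    """TIN DEM: Delaunay triangulation of ground points with linear
    interpolation inside the hull and nearest-point extrapolation outside."""

    ground_points: np.ndarray
    triangulation: Delaunay

    def elevation(self, x, y):
        return self._interp(x, y)

    def __call__(self, x, y):
        return self._interp(x, y)


def build_dem(ground: PointCloud) -> GroundModel:
    """Build a TIN DEM from classified ground points.

    Raises ``ValueError`` on fewer than 3 or collinear ground points.
    """
    if "classification" in ground.attributes:
        mask = ground.attributes["classification"] == LAS_GROUND
        pts = ground.xyz[mask]
    else:
        pts = ground.xyz
    if len(pts) < 3:
        raise ValueError("need at least 3 ground points")
    try:
        tri = Delaunay(pts[:, :2])
    except QhullError as exc:
        raise ValueError(f"degenerate ground geometry: {exc}") from exc
    model = GroundModel(pts, tri)
    model._interp = _surface_interpolator(pts)
    return model


def normalize_heights(cloud: PointCloud, dem: GroundModel) -> PointCloud:
    """Replace z with height above the DEM; x and y are untouched."""
    z_ground = dem.elevation(cloud.x, cloud.y)
    xyz = cloud.xyz.copy()
    xyz[:, 2] = cloud.z - z_ground
    return PointCloud(xyz, dict(cloud.attributes))
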