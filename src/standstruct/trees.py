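"""Individual-tree segmentation and parameter extraction.

From a height-normalized plot cloud: detect trunks by density-clustering a
1-2 m height band (DBSCAN), assign every point to the nearest trunk axis,
then per tree fit a least-squares circle to the 1.25-1.35 m slice for DBH,
take the vertical extent for total height (TH), and the stem-base centroid
for the relative coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.cluster import DBSCAN

from .cloud import PointCloud
from .simulate import MIN_DBH_CM

DBH_SLICE_LOW = 1.25
DBH_SLICE_HIGH = 1.35


@dataclass
class TreeCloud:
    """One segmented tree: its id and its normalized point cloud."""

    tree_id: int
    cloud: PointCloud

    def __post_init__(self) -> None:
        if len(self.cloud) == 0:
            raise ValueError("tree cloud is empty")
        if self.cloud.z.min() < -0.1:
            raise ValueError("tree cloud looks unnormalized (z < -0.1 m)")


def segment_trees(
    cloud: PointCloud,
    band: tuple[float, float] = (1.0, 2.0),
    cluster_radius: float = 0.3,
    min_cluster: int = 15,
) -> list[TreeCloud]:
    """Split a normalized (non-ground) cloud into per-tree clouds.

    Trunk detection clusters the horizontal coordinates of points whose
    height falls in ``band``; every point is then assigned to the trunk
    with the nearest horizontal axis.  Tree ids are assigned 1..n_trunks
    in order of increasing trunk (x, y).
    """
    z = cloud.z
    in_band = (z >= band[0]) & (z <= band[1])
    if not in_band.any():
        raise ValueError("no points in the trunk-detection band")
    band_xy = cloud.xyz[in_band, :2]
    labels = DBSCAN(eps=cluster_radius, min_samples=min_cluster).fit_predict(
        band_xy
    )
    trunk_labels = np.unique(labels[labels >= 0])
    if trunk_labels.size == 0:
        raise ValueError("no trunk clusters found")
    axes = np.array(
        [band_xy[labels == lab].mean(axis=0) for lab in trunk_labels]
    )
    order = np.lexsort((axes[:, 1], axes[:, 0]))
    axes = axes[order]

    d2 = ((cloud.xyz[:, None, :2] - axes[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1)
    trees = []
    for i in range(len(axes)):
        idx = np.flatnonzero(assignment == i)
        trees.append(TreeCloud(tree_id=i + 1, cloud=cloud.subset(idx)))
    return trees


def fit_circle(xy: np.ndarray, refine: bool = False) -> tuple[float, float, float]:
    """Least-squares circle fit; returns (cx, cy, r).

    The default is the algebraic (Kasa) fit — closed form, exact on
    noiseless circles.  ``refine=True`` polishes it by minimising true
    geometric residuals.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 points to fit a circle")
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate (collinear) slice")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    r = float(np.sqrt(r2))
    if refine:
        res = least_squares(
            lambda p: np.hypot(x - p[0], y - p[1]) - p[2],
            x0=[cx, cy, r],
        )
        cx, cy, r = res.x
    return float(cx), float(cy), float(r)


def extract_dbh(
    tree: TreeCloud,
    slice_low: float = DBH_SLICE_LOW,
    slice_high: float = DBH_SLICE_HIGH,
    min_points: int = 10,
    refine: bool = False,
) -> float:
    """DBH (cm) from a least-squares circle fit of the breast-height slice."""
    z = tree.cloud.z
    mask = (z >= slice_low) & (z <= slice_high)
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} slice points (< {min_points})"
        )
    _, _, r = fit_circle(tree.cloud.xyz[mask, :2], refine=refine)
    return 2.0 * r * 100.0  # m radius -> cm diameter


def extract_height(tree: TreeCloud) -> float:
    """Total height (m): vertical extent of the tree's cloud."""
    z = tree.cloud.z
    return float(z.max() - z.min())


def extract_position(
    tree: TreeCloud, base_band: float = 0.3
) -> tuple[float, float]:
    """Stem-base coordinates: centroid of the lowest ``base_band`` metres,
    falling back to the breast-height circle centre for crown-only clouds."""
    z = tree.cloud.z
    mask = z <= z.min() + base_band
    if mask.sum() >= 3:
        xy = tree.cloud.xyz[mask, :2].mean(axis=0)
        return float(xy[0]), float(xy[1])
    zmask = (z >= DBH_SLICE_LOW) & (z <= DBH_SLICE_HIGH)
    cx, cy, _ = fit_circle(tree.cloud.xyz[zmask, :2])
    return cx, cy


def extract_tree_records(
    trees: list[TreeCloud],
    species: dict[int, str] | None = None,
    min_dbh: float = MIN_DBH_CM,
    **dbh_kwargs,
) -> pd.DataFrame:
    """Tree table (source='bls') from segmented clouds.

    Trees whose fitted DBH falls below the census minimum (5 cm) are
    dropped, mirroring the field protocol; failures to fit a slice are
    dropped with the same rule.
    """
    rows = []
    for tree in trees:
        try:
            dbh = extract_dbh(tree, **dbh_kwargs)
        except ValueError:
            continue
        if dbh < min_dbh:
            continue
        x, y = extract_position(tree)
        rows.append(
            {
                "tree_id": tree.tree_id,
                "species": None if species is None else species.get(tree.tree_id),
                "x_m": x,
                "y_m": y,
                "dbh_cm": dbh,
                "height_m": extract_height(tree),
                "source": "bls",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tree_id", "species", "x_m", "y_m", "dbh_cm", "height_m", "source"],
    )
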