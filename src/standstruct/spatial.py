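"""Stand spatial structure: structure units and the W / M / U / CI indices.

A spatial structure unit is a central tree plus its four nearest neighbours.
Central trees are restricted to the plot core (a 2.5 m edge buffer excludes
margin trees from centrality, though they still serve as neighbours), which
removes edge bias from the neighbour statistics.

Indices, each computed per structure unit:

* uniform angle index ``W``  — fraction of the four angular gaps between
  azimuth-sorted neighbours that are smaller than the 72 deg standard
  angle; ~0.5 for a random pattern, lower for regular, higher for clumped;
* mingling ``M`` — fraction of neighbours of a different species;
* dominance ``U`` — fraction of neighbours with strictly larger DBH;
* Hegyi competition index ``CI`` — sum over neighbours of
  (neighbour DBH / subject DBH) / distance.

With four neighbours, W, M and U take values on {0, 0.25, 0.5, 0.75, 1},
summarised as proportions over those five grades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

DEFAULT_BUFFER_M = 2.5
DEFAULT_NEIGHBORS = 4
STANDARD_ANGLE_DEG = 72.0
GRADES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class StructureUnit:
    """A central tree with its nearest neighbours.

    Azimuths follow the surveying convention: 0 deg = north (+y),
    clockwise positive, so due east is 90 deg.
    """

    center_id: int
    neighbor_ids: np.ndarray
    distances: np.ndarray
    azimuths: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.distances <= 0):
            raise ValueError("neighbour distances must be positive")


def apply_edge_buffer(
    stand: pd.DataFrame, plot_size: float, buffer: float = DEFAULT_BUFFER_M
) -> pd.Series:
    """Boolean core flag per tree: True inside the inner square.

    Core trees are eligible as central trees; buffer trees only ever act
    as neighbours.
    """
    if buffer >= plot_size / 2:
        raise ValueError("buffer must be smaller than half the plot side")
    x, y = stand["x_m"], stand["y_m"]
    core = (
        (x >= buffer)
        & (x <= plot_size - buffer)
        & (y >= buffer)
        & (y <= plot_size - buffer)
    )
    return pd.Series(core.to_numpy(), index=stand.index, name="core")


def _azimuth_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def find_neighbors(
    stand: pd.DataFrame, central: int, k: int = DEFAULT_NEIGHBORS
) -> StructureUnit:
    """The ``k`` nearest neighbours of one tree by horizontal distance.

    Ties are broken by tree id; coincident stems are rejected.
    """
    if len(stand) < k + 1:
        raise ValueError(f"need at least {k + 1} trees")
    ids = stand["tree_id"].to_numpy()
    xy = stand[["x_m", "y_m"]].to_numpy(float)
    (c_idx,) = np.flatnonzero(ids == central)
    d = np.hypot(xy[:, 0] - xy[c_idx, 0], xy[:, 1] - xy[c_idx, 1])
    d[c_idx] = np.inf
    if np.any(d == 0):
        raise ValueError(f"coincident stem positions near tree {central}")
    order = np.lexsort((ids, d))[:k]
    dx = xy[order, 0] - xy[c_idx, 0]
    dy = xy[order, 1] - xy[c_idx, 1]
    return StructureUnit(
        center_id=int(central),
        neighbor_ids=ids[order],
        distances=d[order],
        azimuths=_azimuth_deg(dx, dy),
    )


def voronoi_units(stand: pd.DataFrame) -> dict[int, set[int]]:
    """Voronoi (Delaunay) adjacency per tree — the alternative neighbour
    definition in which adjacent Voronoi polygons define the unit."""
    ids = stand["tree_id"].to_numpy()
    xy = stand[["x_m", "y_m"]].to_numpy(float)
    if len(xy) < 4:
        raise ValueError("need at least 4 trees")
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise ValueError(f"degenerate stand geometry: {exc}") from exc
    adj: dict[int, set[int]] = {int(i): set() for i in ids}
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    adj[int(ids[a])].add(int(ids[b]))
    return adj


def uniform_angle(
    unit: StructureUnit,
    alpha0: float = STANDARD_ANGLE_DEG,
    fold_reflex: bool = True,
) -> float:
    """Uniform angle index W of one structure unit.

    Neighbours are sorted by azimuth; the circular gaps between successive
    neighbours are folded to <= 180 deg and compared (strictly) with the
    standard angle alpha0.
    """
    az = np.sort(np.asarray(unit.azimuths) % 360.0)
    gaps = np.diff(az, append=az[0] + 360.0)
    if fold_reflex:
        gaps = np.minimum(gaps, 360.0 - gaps)
    return float(np.mean(gaps < alpha0))


def mingling(unit: StructureUnit, species: dict[int, str]) -> float:
    """Mingling M: fraction of neighbours of a different species."""
    center_sp = species[unit.center_id]
    if center_sp is None:
        raise ValueError("central tree has no species label")
    diffs = [species[int(j)] != center_sp for j in unit.neighbor_ids]
    return float(np.mean(diffs))


def dominance(unit: StructureUnit, dbh: dict[int, float]) -> float:
    """Dominance U: fraction of neighbours with strictly larger DBH."""
    di = dbh[unit.center_id]
    if not di > 0:
        raise ValueError("central tree DBH must be positive")
    return float(np.mean([dbh[int(j)] > di for j in unit.neighbor_ids]))


def hegyi(unit: StructureUnit, dbh: dict[int, float]) -> float:
    """Hegyi competition index CI = sum_j (d_j / d_i) / L_ij."""
    di = dbh[unit.center_id]
    if not di > 0:
        raise ValueError("central tree DBH must be positive")
    dj = np.array([dbh[int(j)] for j in unit.neighbor_ids], dtype=float)
    return float(np.sum((dj / di) / unit.distances))


def compute_indices(
    stand: pd.DataFrame,
    plot_size: float,
    buffer: float = DEFAULT_BUFFER_M,
    k: int = DEFAULT_NEIGHBORS,
    alpha0: float = STANDARD_ANGLE_DEG,
) -> pd.DataFrame:
    """Per-tree index table (W, U, M, CI) over core central trees.

    Neighbours come from the whole stand (core + buffer); only core trees
    are central.  Returns one row per core tree with the four indices and
    the tree's species/DBH carried along for summaries.
    """
    core = apply_edge_buffer(stand, plot_size, buffer)
    ids = stand["tree_id"].to_numpy()
    xy = stand[["x_m", "y_m"]].to_numpy(float)
    species = dict(zip(ids, stand["species"]))
    dbh = dict(zip(ids, stand["dbh_cm"].astype(float)))

    tree = cKDTree(xy)
    rows = []
    for idx in np.flatnonzero(core.to_numpy()):
        d, nb = tree.query(xy[idx], k=k + 1)
        d, nb = d[1:], nb[1:]
        if np.any(d <= 0):
            raise ValueError(f"coincident stem positions near tree {ids[idx]}")
        # re-sort with id tie-break to match find_neighbors exactly
        order = np.lexsort((ids[nb], d))
        d, nb = d[order], nb[order]
        unit = StructureUnit(
            center_id=int(ids[idx]),
            neighbor_ids=ids[nb],
            distances=d,
            azimuths=_azimuth_deg(xy[nb, 0] - xy[idx, 0], xy[nb, 1] - xy[idx, 1]),
        )
        rows.append(
            {
                "tree_id": int(ids[idx]),
                "species": species[ids[idx]],
                "dbh_cm": dbh[ids[idx]],
                "W": uniform_angle(unit, alpha0=alpha0),
                "M": mingling(unit, species),
                "U": dominance(unit, dbh),
                "CI": hegyi(unit, dbh),
            }
        )
    return pd.DataFrame(
        rows, columns=["tree_id", "species", "dbh_cm", "W", "M", "U", "CI"]
    )


def grade_distribution(values) -> pd.Series:
    """Proportion of index values in each of the five 0.25-wide grades."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no index values")
    if np.any((values < -1e-9) | (values > 1 + 1e-9)):
        raise ValueError("index values must lie in [0, 1]")
    grid = np.array(GRADES)
    snapped = grid[np.abs(values[:, None] - grid[None, :]).argmin(axis=1)]
    if not np.allclose(snapped, values, atol=1e-9):
        raise ValueError("index values must lie on the 0.25 grade grid")
    counts = pd.Series(snapped).value_counts().reindex(GRADES, fill_value=0)
    return counts / counts.sum()


def class_competition(
    indices: pd.DataFrame,
    class_labels: pd.Series,
    species: str | None = None,
) -> tuple[pd.Series, float]:
    """Total Hegyi CI per diameter class (optionally for one species) and
    the mean CI over the selected central trees.

    ``class_labels`` is the per-tree diameter-class label aligned with
    ``indices``.  Empty classes total 0.
    """
    df = indices.copy()
    df["dclass"] = class_labels.to_numpy()
    if species is not None:
        df = df[df["species"] == species]
    if df.empty:
        return pd.Series(dtype=float), float("nan")
    totals = df.groupby("dclass", observed=True)["CI"].sum()
    return totals, float(df["CI"].mean())


def plot_summary(indices: pd.DataFrame) -> dict:
    """Per-plot summary: mean W/U/M, mean CI, and grade distributions."""
    return {
        "n_central": len(indices),
        "mean_W": float(indices["W"].mean()),
        "mean_U": float(indices["U"].mean()),
        "mean_M": float(indices["M"].mean()),
        "mean_CI": float(indices["CI"].mean()),
        "grades_W": grade_distribution(indices["W"]),
        "grades_U": grade_distribution(indices["U"]),
        "grades_M": grade_distribution(indices["M"]),
    }
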