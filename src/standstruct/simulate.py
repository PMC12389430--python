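"""Synthetic stand and stem-cloud generators with known ground truth.

The study system is a set of 25 m x 25 m mountain forest plots dominated by
*Camellia taliensis*, censused down to 5 cm diameter at breast height (DBH).
No field data are distributable, so these generators emulate the salient
statistical features instead: clustered-to-random stem patterns, strongly
uneven multi-species composition (one dominant species, 7-28 species per
plot), inverse-J DBH distributions truncated at 5 cm, and noisy cylindrical
stem point clouds whose true DBH and height are known exactly.

Every generator is a pure function of its spec and seed: identical inputs
give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cloud import PointCloud

MIN_DBH_CM = 5.0  # census rule: trees below 5 cm DBH are not recorded
BREAST_HEIGHT_M = 1.3

STAND_COLUMNS = ["tree_id", "species", "x_m", "y_m", "dbh_cm", "height_m"]


@dataclass
class StandSpec:
    """Parameters of a simulated stand.

    Attributes
    ----------
    plot_size : side of the square plot in metres.
    pattern : ``poisson`` (complete spatial randomness), ``cluster``
        (Thomas parent-offspring process) or ``grid`` (square lattice).
    n_trees : number of stems (all with DBH >= 5 cm).
    cluster_parents, cluster_sd : Thomas-process parent count and isotropic
        Gaussian offspring dispersal (m); offspring are reflected at the
        plot edges so density is conserved.
    species_count : number of species in the pool.
    species_abundance_model : ``geometric`` (one dominant species, mimicking
        the tea-tree community) or ``uniform``.
    geometric_ratio : common ratio of the geometric abundance series.
    dbh_rate : exponential rate per cm; DBH = 5 + Exp(rate), the classic
        inverse-J (negative exponential) diameter distribution.
    height_a, height_b, height_noise_sd : allometry H = a * DBH^b + noise.
    """

    plot_size: float = 25.0
    pattern: str = "poisson"
    n_trees: int = 100
    cluster_parents: int = 8
    cluster_sd: float = 2.0
    species_count: int = 12
    species_abundance_model: str = "geometric"
    geometric_ratio: float = 0.65
    dbh_rate: float = 0.08
    height_a: float = 1.3
    height_b: float = 0.6
    height_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.plot_size <= 0:
            raise ValueError("plot_size must be positive")
        if self.pattern not in ("poisson", "cluster", "grid"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.species_abundance_model not in ("geometric", "uniform"):
            raise ValueError(
                f"unknown abundance model {self.species_abundance_model!r}"
            )
        if self.species_count < 1 or self.cluster_parents < 1:
            raise ValueError("counts must be positive")
        if self.dbh_rate <= 0:
            raise ValueError("dbh_rate must be positive")


@dataclass
class StemCloudSpec:
    """Parameters of one synthetic stem point cloud.

    The stem is a vertical cylinder of diameter ``dbh_true`` (cm) from z = 0
    to ``height_true`` (m), optionally tapering, with Gaussian radial noise.
    ``points_per_m`` controls vertical sampling density.  An optional
    ellipsoidal crown blob can be added; ``top_truncation`` removes the top
    of the stem to emulate occlusion of the tree top in real scans.
    """

    dbh_true: float = 30.0
    height_true: float = 12.0
    taper: float = 0.0  # fractional radius decrease per metre of height
    radial_noise_sd: float = 0.0
    points_per_m: float = 500.0
    lean_deg: float = 0.0  # stem lean from vertical, in the +x direction
    crown: dict | None = None  # {"z": m, "rx": m, "rz": m, "n": count}
    top_truncation: float = 0.0  # metres removed from the top
    base_xy: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.dbh_true < MIN_DBH_CM:
            raise ValueError(f"dbh_true must be >= {MIN_DBH_CM} cm")
        if self.height_true <= 1.35:
            raise ValueError("height_true must exceed the 1.35 m slice top")
        if self.radial_noise_sd < 0:
            raise ValueError("radial_noise_sd must be >= 0")
        if self.points_per_m <= 0:
            raise ValueError("points_per_m must be positive")


def _positions(spec: StandSpec, rng: np.random.Generator) -> np.ndarray:
    L = spec.plot_size
    n = spec.n_trees
    if spec.pattern == "poisson":
        return rng.uniform(0.0, L, size=(n, 2))
    if spec.pattern == "grid":
        side = int(np.ceil(np.sqrt(n)))
        spacing = L / side
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        pts = (np.column_stack([gx.ravel(), gy.ravel()]) + 0.5) * spacing
        return pts[:n]
    # Thomas cluster process: uniform parents, Gaussian offspring,
    # reflected at the plot edges to stay inside the square.
    parents = rng.uniform(0.0, L, size=(spec.cluster_parents, 2))
    assignment = rng.integers(0, spec.cluster_parents, size=n)
    offsets = rng.normal(0.0, spec.cluster_sd, size=(n, 2))
    pts = parents[assignment] + offsets
    # reflect into [0, L] (repeat in case of large excursions)
    for _ in range(8):
        pts = np.where(pts < 0, -pts, pts)
        pts = np.where(pts > L, 2 * L - pts, pts)
        if np.all((pts >= 0) & (pts <= L)):
            break
    return np.clip(pts, 0.0, L)


def _species_probs(spec: StandSpec) -> np.ndarray:
    s = spec.species_count
    if spec.species_abundance_model == "uniform":
        return np.full(s, 1.0 / s)
    w = spec.geometric_ratio ** np.arange(s)
    return w / w.sum()


def generate_stand(spec: StandSpec) -> pd.DataFrame:
    """Simulate a stand table (tree_id, species, x_m, y_m, dbh_cm, height_m)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pts = _positions(spec, rng)
    n = spec.n_trees

    probs = _species_probs(spec)
    species_idx = rng.choice(spec.species_count, size=n, p=probs)
    species = np.array([f"sp{i + 1:02d}" for i in range(spec.species_count)])[
        species_idx
    ]

    dbh = MIN_DBH_CM + rng.exponential(1.0 / spec.dbh_rate, size=n)
    height = spec.height_a * dbh**spec.height_b + rng.normal(
        0.0, spec.height_noise_sd, size=n
    )
    height = np.maximum(height, 1.5)  # keep every stem above the DBH slice

    return pd.DataFrame(
        {
            "tree_id": np.arange(1, n + 1),
            "species": species,
            "x_m": pts[:, 0],
            "y_m": pts[:, 1],
            "dbh_cm": dbh,
            "height_m": height,
        }
    )


def generate_stem_cloud(spec: StemCloudSpec) -> PointCloud:
    """Simulate the point cloud of a single stem.

    Points lie on the (possibly tapered, possibly leaning) cylinder surface
    with Gaussian radial noise.  With no crown, no truncation and no noise
    the highest point's z equals ``height_true`` exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h = spec.height_true - spec.top_truncation
    if h <= 0:
        raise ValueError("top_truncation removes the whole stem")
    n = max(int(round(spec.points_per_m * h)), 8)
    z = rng.uniform(0.0, h, size=n)
    if spec.top_truncation == 0.0:
        z[0] = spec.height_true  # pin the true top
        z[1] = 0.0
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    r0 = spec.dbh_true / 200.0  # cm diameter -> m radius
    radius = r0 * np.maximum(1.0 - spec.taper * z, 0.05)
    if spec.radial_noise_sd > 0:
        radius = radius + rng.normal(0.0, spec.radial_noise_sd, size=n)
    x = radius * np.cos(theta)
    y = radius * np.sin(theta)
    if spec.lean_deg:
        x = x + z * np.tan(np.radians(spec.lean_deg))
    pts = [np.column_stack([x, y, z])]
    if spec.crown is not None:
        c = spec.crown
        m = int(c.get("n", 500))
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rad = rng.uniform(0, 1, size=(m, 1)) ** (1 / 3)
        blob = u * rad * np.array([c["rx"], c["rx"], c["rz"]])
        blob[:, 2] += c["z"]
        pts.append(blob)
    xyz = np.concatenate(pts)
    xyz[:, 0] += spec.base_xy[0]
    xyz[:, 1] += spec.base_xy[1]
    return PointCloud(xyz)


def generate_plot_cloud(
    stand: pd.DataFrame,
    points_per_m: float = 300.0,
    radial_noise_sd: float = 0.003,
    ground_tilt: tuple[float, float] = (0.0, 0.0),
    ground_spacing: float = 0.25,
    plot_size: float = 25.0,
    seed: int = 0,
) -> PointCloud:
    """Assemble a full-plot cloud: tilted planar ground plus one stem per tree.

    Stem bases sit on the ground plane, so the cloud exercises the whole
    pre-processing chain (ground classification, DEM, height normalization)
    before tree parameters can be recovered.  Returns a cloud with a
    ``tree_id`` attribute (0 = ground) as segmentation ground truth.
    """
    rng = np.random.default_rng(seed)
    ax, ay = ground_tilt
    g = np.arange(0.0, plot_size + 1e-9, ground_spacing)
    gx, gy = np.meshgrid(g, g)
    ground = np.column_stack(
        [gx.ravel(), gy.ravel(), ax * gx.ravel() + ay * gy.ravel()]
    )
    clouds = [ground]
    ids = [np.zeros(len(ground), dtype=int)]
    for row in stand.itertuples(index=False):
        stem = generate_stem_cloud(
            StemCloudSpec(
                dbh_true=row.dbh_cm,
                height_true=row.height_m,
                radial_noise_sd=radial_noise_sd,
                points_per_m=points_per_m,
                base_xy=(row.x_m, row.y_m),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        xyz = stem.xyz.copy()
        xyz[:, 2] += ax * row.x_m + ay * row.y_m  # base on the ground plane
        clouds.append(xyz)
        ids.append(np.full(len(xyz), row.tree_id, dtype=int))
    return PointCloud(np.concatenate(clouds), {"tree_id": np.concatenate(ids)})


def generate_paired_measurements(
    stand: pd.DataFrame,
    bias_dbh: float = 0.0,
    bias_th: float = 0.0,
    noise_sd_dbh: float = 0.0,
    noise_sd_th: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair each field value with a simulated scanner estimate.

    The estimate is ``field - bias + noise``, so the evaluation bias
    statistic (mean of field minus estimate) recovers ``+bias`` in
    expectation: a positive injected bias means the scanner underestimates.
    """
    if len(stand) == 0:
        raise ValueError("stand is empty")
    if noise_sd_dbh < 0 or noise_sd_th < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(stand)
    out = stand[["tree_id"]].copy()
    out["dbh_field_cm"] = stand["dbh_cm"].to_numpy()
    out["dbh_bls_cm"] = (
        out["dbh_field_cm"] - bias_dbh + rng.normal(0.0, 1.0, n) * noise_sd_dbh
    )
    out["th_field_m"] = stand["height_m"].to_numpy()
    out["th_bls_m"] = (
        out["th_field_m"] - bias_th + rng.normal(0.0, 1.0, n) * noise_sd_th
    )
    return out


def reference_plot_specs(base_seed: int = 0) -> dict[str, StandSpec]:
    """Seven synthetic plots emulating the published censuses.

    Tree counts follow the published per-plot censuses (23, 52, 166, 112,
    51, 57, 74 stems on 25 m x 25 m); species counts span the reported
    10-28 range with the sparsest plot the least diverse.  Patterns are
    clustered, matching the aggregated distribution the community shows.
    """
    counts = [23, 52, 166, 112, 51, 57, 74]
    species = [12, 10, 28, 20, 16, 15, 18]
    return {
        f"plot{i + 1}": StandSpec(
            n_trees=n,
            species_count=s,
            pattern="cluster",
            cluster_parents=max(3, n // 20),
            cluster_sd=2.5,
            seed=base_seed + i,
        )
        for i, (n, s) in enumerate(zip(counts, species))
    }


def default_taxonomy(species: list[str], genera_per_family: int = 2,
                     species_per_genus: int = 2) -> pd.DataFrame:
    """Deterministic species -> genus -> family table for composition tests."""
    rows = []
    for i, sp in enumerate(sorted(set(species))):
        genus = i // species_per_genus
        family = genus // genera_per_family
        rows.append({"species": sp, "genus": f"gen{genus + 1:02d}",
                     "family": f"fam{family + 1:02d}"})
    return pd.DataFrame(rows)


def save_stand(stand: pd.DataFrame, path) -> None:
    stand.to_csv(path, index=False, float_format="%.6f")


def load_stand(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STAND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stand table lacks columns: {sorted(missing)}")
    if (df["dbh_cm"] < MIN_DBH_CM).any():
        warnings.warn("stand table contains trees below the 5 cm census rule")
    return df
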