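"""Point-cloud container and plain-text I/O.

A :class:`PointCloud` is a thin wrapper around an ``(n, 3)`` float array of
x/y/z coordinates in metres, plus optional per-point integer attributes
(``classification`` using the LAS convention ``2 = ground``, and ``tree_id``
for segmented clouds).  Clouds are read and written as XYZ CSV, the portable
text form of a LAS tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: LAS point-classification codes used throughout.
LAS_UNCLASSIFIED = 1
LAS_GROUND = 2


@dataclass
class PointCloud:
    """Set of 3-D points with optional per-point labels."""

    xyz: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        for name, values in self.attributes.items():
            values = np.asarray(values)
            if values.shape[0] != len(self):
                raise ValueError(f"attribute {name!r} must have one value per point")
            self.attributes[name] = values

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def subset(self, index: np.ndarray) -> "PointCloud":
        """Return the points selected by ``index`` (order preserved)."""
        return PointCloud(
            self.xyz[index],
            {k: v[index] for k, v in self.attributes.items()},
        )

    def with_attribute(self, name: str, values: np.ndarray) -> "PointCloud":
        attrs = dict(self.attributes)
        attrs[name] = np.asarray(values)
        return PointCloud(self.xyz.copy(), attrs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.xyz, columns=["x", "y", "z"])
        for name, values in self.attributes.items():
            df[name] = values
        return df


def read_xyz(path) -> PointCloud:
    """Read a cloud from XYZ CSV (columns x, y, z plus optional attributes)."""
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"XYZ CSV lacks columns: {sorted(missing)}")
    attrs = {
        c: df[c].to_numpy() for c in df.columns if c not in ("x", "y", "z")
    }
    return PointCloud(df[["x", "y", "z"]].to_numpy(float), attrs)


def write_xyz(cloud: PointCloud, path) -> None:
    cloud.to_frame().to_csv(path, index=False, float_format="%.6f")
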