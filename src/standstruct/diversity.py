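"""Non-spatial stand structure: composition, diversity, importance values,
diameter classes.

All diversity indices use natural logarithms.  Importance value is the
arithmetic mean of a species' relative abundance (share of stems), relative
frequency (share of occupied quadrats, from a square quadrat grid) and
relative dominance (share of basal area at breast height), each in percent.

Diameter classes are 10 cm wide, anchored at the 5 cm census minimum:
class I is [5, 15) cm, class II [15, 25), and so on.  A monotonically
decreasing class histogram is the "inverse J" shape that indicates active
regeneration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DBH_CLASS_WIDTH_CM = 10.0
DBH_CLASS_ORIGIN_CM = 5.0
DEFAULT_QUADRAT_M = 5.0


def abundance_profile(stand: pd.DataFrame) -> pd.DataFrame:
    """Per-species counts, proportions and basal-area totals (cm^2)."""
    if len(stand) == 0:
        raise ValueError("empty stand")
    df = stand.copy()
    df["basal_cm2"] = np.pi * (df["dbh_cm"] / 2.0) ** 2
    prof = df.groupby("species", observed=True).agg(
        count=("tree_id", "size"), basal_cm2=("basal_cm2", "sum")
    )
    prof["p"] = prof["count"] / prof["count"].sum()
    return prof


def patrick(profile: pd.DataFrame) -> int:
    """Patrick richness R: the number of species."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    return int(len(profile))


def margalef(s: int, n: int) -> float:
    """Margalef richness MA = (S - 1) / ln N."""
    if n < 2:
        raise ValueError("need at least 2 individuals")
    return (s - 1) / np.log(n)


def shannon(p) -> float:
    """Shannon-Wiener diversity H = -sum p_i ln p_i (0 ln 0 := 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson(p) -> float:
    """Simpson diversity D = 1 - sum p_i^2."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1")
    return float(1.0 - (p**2).sum())


def pielou(h: float, s: int) -> float:
    """Pielou evenness E = H / ln S; undefined (NaN) for a monoculture."""
    if s < 2:
        warnings.warn("Pielou evenness is undefined for a single species")
        return float("nan")
    return float(h / np.log(s))


def diversity_summary(stand: pd.DataFrame) -> dict:
    """R, MA, H, D and E of one plot's stand table."""
    prof = abundance_profile(stand)
    s, n = patrick(prof), int(prof["count"].sum())
    h = shannon(prof["p"])
    return {
        "richness_patrick": s,
        "richness_margalef": margalef(s, n),
        "shannon": h,
        "simpson": simpson(prof["p"]),
        "pielou": pielou(h, s),
        "n_trees": n,
    }


def importance_value_components(
    stand: pd.DataFrame,
    plot_size: float,
    quadrat_size: float = DEFAULT_QUADRAT_M,
) -> pd.DataFrame:
    """Relative abundance, frequency and dominance per species (percent).

    Frequency uses presence/absence over a square grid of
    ``quadrat_size`` m quadrats (25 per standard plot); the denominator is
    the total number of species-quadrat occupancies, so RF sums to 100.
    """
    prof = abundance_profile(stand)
    if prof["basal_cm2"].sum() <= 0:
        raise ValueError("zero total basal area")
    ra = 100.0 * prof["count"] / prof["count"].sum()
    rd = 100.0 * prof["basal_cm2"] / prof["basal_cm2"].sum()

    n_cells = int(np.ceil(plot_size / quadrat_size))
    qx = np.minimum((stand["x_m"] // quadrat_size).astype(int), n_cells - 1)
    qy = np.minimum((stand["y_m"] // quadrat_size).astype(int), n_cells - 1)
    occ = (
        pd.DataFrame(
            {"species": stand["species"], "quadrat": qx * n_cells + qy}
        )
        .drop_duplicates()
        .groupby("species", observed=True)
        .size()
        .reindex(prof.index, fill_value=0)
    )
    rf = 100.0 * occ / occ.sum()

    out = pd.DataFrame(
        {"n": prof["count"], "RA": ra, "RF": rf, "RD": rd}
    )
    out["IV"] = importance_value(out["RA"], out["RF"], out["RD"])
    return out.sort_values("IV", ascending=False)


def importance_value(ra, rf, rd):
    """Importance value IV = (RA + RF + RD) / 3, components in percent."""
    ra, rf, rd = (np.asarray(v, dtype=float) for v in (ra, rf, rd))
    for v in (ra, rf, rd):
        if np.any((v < 0) | (v > 100)):
            raise ValueError("components must be percentages in [0, 100]")
    out = (ra + rf + rd) / 3.0
    return float(out) if out.ndim == 0 else out


@dataclass
class DiameterClassDistribution:
    """Diameter-class histogram with the inverse-J (non-increasing) check."""

    edges_cm: np.ndarray
    labels: list[str]
    counts: pd.Series
    by_species: pd.DataFrame
    inverse_j: bool


def _roman(i: int) -> str:
    numerals = [
        (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = ""
    for val, sym in numerals:
        while i >= val:
            out += sym
            i -= val
    return out


def diameter_class_labels(
    dbh, width: float = DBH_CLASS_WIDTH_CM, origin: float = DBH_CLASS_ORIGIN_CM
) -> pd.Series:
    """Assign each DBH to its half-open class [origin + k*width, ...)."""
    dbh = pd.Series(dbh, dtype=float)
    if (dbh < origin).any():
        raise ValueError(f"DBH below the {origin} cm class origin")
    k = ((dbh - origin) // width).astype(int)
    return k.map(lambda i: _roman(i + 1))


def diameter_classes(
    stand: pd.DataFrame,
    width: float = DBH_CLASS_WIDTH_CM,
    origin: float = DBH_CLASS_ORIGIN_CM,
) -> DiameterClassDistribution:
    """Bin the stand's DBH values into labelled diameter classes."""
    dbh = stand["dbh_cm"].astype(float)
    labels = diameter_class_labels(dbh, width, origin)
    n_classes = int(((dbh.max() - origin) // width)) + 1
    all_labels = [_roman(i + 1) for i in range(n_classes)]
    counts = labels.value_counts().reindex(all_labels, fill_value=0)
    by_species = (
        pd.crosstab(stand["species"], labels)
        .reindex(columns=all_labels, fill_value=0)
    )
    edges = origin + width * np.arange(n_classes + 1)
    inv_j = bool(np.all(np.diff(counts.to_numpy()) <= 0))
    return DiameterClassDistribution(
        edges_cm=edges,
        labels=all_labels,
        counts=counts,
        by_species=by_species,
        inverse_j=inv_j,
    )


def composition_summary(
    stand: pd.DataFrame, taxonomy: pd.DataFrame | None = None
) -> dict:
    """Counts of families, genera and species present in the stand.

    Species missing from the taxonomy count as their own genus and family
    (with a warning), so the counts never silently shrink.
    """
    species = pd.Index(stand["species"].unique())
    if taxonomy is None or len(taxonomy) == 0:
        if taxonomy is not None:
            warnings.warn("empty taxonomy: species-level counts only")
        return {
            "families": None,
            "genera": None,
            "species": int(species.size),
        }
    tax = taxonomy.set_index("species")
    unknown = species.difference(tax.index)
    if unknown.size:
        warnings.warn(
            f"{unknown.size} species missing from taxonomy; "
            "counted as their own genus/family"
        )
    genus = {
        sp: (tax.loc[sp, "genus"] if sp in tax.index else f"unknown-genus:{sp}")
        for sp in species
    }
    family = {
        sp: (tax.loc[sp, "family"] if sp in tax.index else f"unknown-family:{sp}")
        for sp in species
    }
    return {
        "families": len(set(family.values())),
        "genera": len(set(genus.values())),
        "species": int(species.size),
    }
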