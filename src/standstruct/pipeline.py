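"""End-to-end orchestration: simulate/ingest -> preprocess -> extract ->
spatial -> diversity -> evaluate, with CSV/JSON report writers.

Every stage is skippable: a run can start from a raw plot cloud or jump
straight to a tree table.  All randomness flows from the seeds in the
config, so a rerun with the same config writes byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, evaluate, preprocess, simulate, spatial, trees
from .cloud import LAS_GROUND, PointCloud, read_xyz, write_xyz

logger = logging.getLogger("standstruct")

FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, serializable to YAML round-trip."""

    plot_size: float = 25.0
    buffer_m: float = 2.5
    # preprocessing
    retain_fraction: float = 0.8
    sor_k: int = 10
    sor_n_sigma: float = 2.0
    ground_cell_m: float = 0.5
    ground_tolerance_m: float = 0.2
    # extraction
    slice_low_m: float = 1.25
    slice_high_m: float = 1.35
    min_slice_points: int = 10
    trunk_band_m: tuple[float, float] = (1.0, 2.0)
    cluster_radius_m: float = 0.3
    min_cluster: int = 15
    # structure
    neighbors: int = 4
    alpha0_deg: float = 72.0
    quadrat_m: float = 5.0
    class_width_cm: float = 10.0
    class_origin_cm: float = 5.0
    # io / rng
    seed: int = 0
    cloud_path: str | None = None
    stand_path: str | None = None
    out_dir: str = "results"
    simulate_stand: dict | None = None  # StandSpec overrides, or None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["trunk_band_m"] = list(d["trunk_band_m"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "trunk_band_m" in d:
            d["trunk_band_m"] = tuple(d["trunk_band_m"])
        return cls(**d)


def summarize_plot(stand: pd.DataFrame) -> dict:
    """Plot census summary: count plus mean/max/min DBH and height."""
    if len(stand) == 0:
        raise ValueError("empty stand")
    dbh, th = stand["dbh_cm"], stand["height_m"]
    return {
        "n_trees": int(len(stand)),
        "mean_dbh_cm": float(dbh.mean()),
        "max_dbh_cm": float(dbh.max()),
        "min_dbh_cm": float(dbh.min()),
        "mean_th_m": float(th.mean()),
        "max_th_m": float(th.max()),
        "min_th_m": float(th.min()),
    }


def preprocess_cloud(cloud: PointCloud, config: PipelineConfig) -> PointCloud:
    """Thin, denoise, classify ground, build the DEM and normalize.

    Returns the normalized cloud with ground labels preserved.
    """
    thinned = preprocess.random_sample(
        cloud, config.retain_fraction, seed=config.seed
    )
    denoised, n_removed = preprocess.sor_denoise(
        thinned, k=config.sor_k, n_sigma=config.sor_n_sigma
    )
    logger.info("SOR removed %d points", n_removed)
    classified = preprocess.classify_ground(
        denoised, config.ground_cell_m, config.ground_tolerance_m
    )
    dem = preprocess.build_dem(classified)
    return preprocess.normalize_heights(classified, dem)


def extract_stand(cloud: PointCloud, config: PipelineConfig) -> pd.DataFrame:
    """Segment the normalized cloud and extract the scanner tree table."""
    nonground = cloud.subset(
        np.flatnonzero(cloud.attributes["classification"] != LAS_GROUND)
    )
    tree_clouds = trees.segment_trees(
        nonground,
        band=config.trunk_band_m,
        cluster_radius=config.cluster_radius_m,
        min_cluster=config.min_cluster,
    )
    return trees.extract_tree_records(
        tree_clouds,
        slice_low=config.slice_low_m,
        slice_high=config.slice_high_m,
        min_points=config.min_slice_points,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Writes (as applicable) stand tables, the per-tree spatial index table,
    grade distributions, the diversity summary, the importance-value table,
    the diameter-class histogram, the evaluation report, and a JSON
    manifest of every parameter used.  Returns the bundle as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    field_stand = None
    if config.simulate_stand is not None:
        spec = simulate.StandSpec(**{"seed": config.seed, **config.simulate_stand})
        field_stand = simulate.generate_stand(spec)
        field_stand["source"] = "field"
        simulate.save_stand(field_stand, out / "stand_field.csv")

    stand = None
    if config.cloud_path is not None or (
        field_stand is not None and config.stand_path is None
    ):
        if config.cloud_path is not None:
            cloud = read_xyz(config.cloud_path)
        else:  # simulate the plot cloud from the simulated stand
            cloud = simulate.generate_plot_cloud(
                field_stand,
                plot_size=config.plot_size,
                seed=config.seed,
            )
        normalized = preprocess_cloud(cloud, config)
        write_xyz(normalized, out / "cloud_normalized.csv")
        stand = extract_stand(normalized, config)
        stand.to_csv(out / "stand_bls.csv", index=False, float_format=FLOAT_FMT)
    if config.stand_path is not None:
        stand = simulate.load_stand(config.stand_path)

    if stand is None or len(stand) == 0:
        raise RuntimeError("pipeline produced no tree table (stage: extract)")

    bundle["plot_summary"] = summarize_plot(stand)
    pd.DataFrame([bundle["plot_summary"]]).to_csv(
        out / "plot_summary.csv", index=False, float_format=FLOAT_FMT
    )

    # species labels come from the field census (scanner clouds carry none);
    # structure analyses therefore use the field table when available
    structural = stand
    if structural["species"].isna().any() and field_stand is not None:
        structural = field_stand
    try:
        indices = spatial.compute_indices(
            structural,
            plot_size=config.plot_size,
            buffer=config.buffer_m,
            k=config.neighbors,
            alpha0=config.alpha0_deg,
        )
    except ValueError as exc:
        raise RuntimeError(f"spatial stage failed: {exc}") from exc
    indices.to_csv(out / "spatial_indices.csv", index=False, float_format=FLOAT_FMT)
    summary = spatial.plot_summary(indices)
    bundle["spatial_summary"] = {
        k: (v.to_dict() if isinstance(v, pd.Series) else v)
        for k, v in summary.items()
    }

    div = diversity.diversity_summary(structural)
    iv = diversity.importance_value_components(
        structural, plot_size=config.plot_size, quadrat_size=config.quadrat_m
    )
    classes = diversity.diameter_classes(
        structural, width=config.class_width_cm, origin=config.class_origin_cm
    )
    bundle["diversity"] = div
    bundle["importance_values"] = iv.reset_index().to_dict(orient="records")
    bundle["diameter_classes"] = classes.counts.to_dict()
    bundle["inverse_j"] = classes.inverse_j
    pd.DataFrame([div]).to_csv(out / "diversity.csv", index=False, float_format=FLOAT_FMT)
    iv.to_csv(out / "importance_values.csv", float_format=FLOAT_FMT)
    classes.counts.rename("count").to_csv(out / "diameter_classes.csv")

    if field_stand is not None and "source" in stand.columns and (
        stand["source"] == "bls"
    ).any():
        matched = evaluate.match_by_position(field_stand, stand, max_dist=1.0)
        if len(matched) >= 2:
            reports = evaluate.evaluate_paired_table(matched)
            bundle["evaluation"] = {
                k: r.to_dict() for k, r in reports.items()
            }
            with open(out / "evaluation.json", "w") as fh:
                json.dump(bundle["evaluation"], fh, indent=2)

    manifest = {"config": asdict(config)}
    manifest["config"]["trunk_band_m"] = list(config.trunk_band_m)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle
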