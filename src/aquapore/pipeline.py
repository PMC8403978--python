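"""Configuration-driven orchestration of the analysis stages.

A run is described by a YAML configuration (paths, pore geometry, grid and
criterion parameters); :func:`run_pipeline` executes the requested stages,
writes per-stage CSV outputs whose headers carry the layer boundaries for
provenance, and a single ``summary.json`` validated against the schema
shipped with the package.  Re-running with the same configuration and
inputs reproduces numerically identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import PoreGeometry, Trajectory, read_trajectory
from .density import (
    LayerPartition,
    axial_contact_density,
    density_map_2d,
    radial_density,
    segment_layers,
)
from .dynamics import (
    linear_distance,
    plateau_estimate,
    residence_ledger,
    restricted_msd,
    survival_function,
)
from .geometry import make_2d_grid, make_radial_grid
from .hbond import detect_hbonds, export_network, hbond_type_fractions, nhb_by_layer
from .orientation import orientation_profiles
from .tetrahedrality import layer_resolved_distributions, tetrahedral_records

logger = logging.getLogger("aquapore")

ALL_STAGES = ("density", "orientation", "tetra", "hbond", "dynamics")


class PipelineError(Exception):
    """A stage failed; earlier stage outputs are preserved on disk."""


@dataclass
class RunConfig:
    """Validated run configuration (units: Å, ps, degrees)."""

    input_path: Path
    output_dir: Path
    geometry: PoreGeometry
    format: str = "extended_xyz"
    seed: int = 0
    dr: float = 0.1
    dz: float = 0.2
    radial_margin: float = 0.0
    smoothing_window: int = 5
    min_prominence: float = 0.05
    override_boundaries: Optional[List[float]] = None
    override_labels: Optional[List[str]] = None
    d_oo_max: float = 3.5
    angle_max_deg: float = 30.0
    origin_stride: int = 10
    max_lag: Optional[int] = None

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.output_dir = Path(self.output_dir)
        if not self.input_path.exists():
            raise FileNotFoundError(f"input trajectory not found: {self.input_path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        geom_raw = dict(raw.get("geometry", {}))
        geom = PoreGeometry(
            radius_R=float(geom_raw.get("radius_R", 7.0)),
            length_L=float(geom_raw.get("length_L", 26.0)),
            axis_origin=np.asarray(geom_raw.get("axis_origin", [0.0, 0.0, 0.0]), dtype=float),
            axis_direction=np.asarray(
                geom_raw.get("axis_direction", [0.0, 0.0, 1.0]), dtype=float
            ),
            membrane_z_min=geom_raw.get("membrane_z_min"),
            membrane_z_max=geom_raw.get("membrane_z_max"),
            lattice_parameter_a=float(geom_raw.get("lattice_parameter_a", 3.5)),
            hydrophobicity_c=float(geom_raw.get("hydrophobicity_c", 1.0)),
            contact_angle_deg=geom_raw.get("contact_angle_deg"),
            temperature_K=geom_raw.get("temperature_K"),
        )
        grid = raw.get("grid", {})
        layers = raw.get("layers", {})
        hb = raw.get("hbond", {})
        dyn = raw.get("dynamics", {})
        return cls(
            input_path=Path(raw["input"]),
            output_dir=Path(raw.get("output", "aquapore_out")),
            geometry=geom,
            format=raw.get("format", "extended_xyz"),
            seed=int(raw.get("seed", 0)),
            dr=float(grid.get("dr", 0.1)),
            dz=float(grid.get("dz", 0.2)),
            radial_margin=float(grid.get("radial_margin", 0.0)),
            smoothing_window=int(layers.get("smoothing_window", 5)),
            min_prominence=float(layers.get("min_prominence", 0.05)),
            override_boundaries=layers.get("override_boundaries"),
            override_labels=layers.get("override_labels"),
            d_oo_max=float(hb.get("d_oo_max", 3.5)),
            angle_max_deg=float(hb.get("angle_max_deg", 30.0)),
            origin_stride=int(dyn.get("origin_stride", 10)),
            max_lag=dyn.get("max_lag"),
        )


def _config_hash(config: RunConfig) -> str:
    payload = {
        k: str(v)
        for k, v in sorted(vars(config).items())
        if k != "geometry"
    }
    payload["geometry"] = str(vars(config.geometry))
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, partition: Optional[LayerPartition]) -> None:
    """CSV with a provenance header carrying the layer boundaries."""
    with open(path, "w") as fh:
        if partition is not None:
            bounds = ",".join(f"{b:.4f}" for b in partition.boundaries_r)
            fh.write(f"# layer_boundaries_r={bounds} labels={'/'.join(partition.labels)}\n")
        df.to_csv(fh, index=False)


def load_summary_schema() -> Dict[str, Any]:
    with resources.files("aquapore").joinpath("summary_schema.json").open() as fh:
        return json.load(fh)


def validate_summary(summary: Dict[str, Any]) -> List[str]:
    """Check the summary against the shipped schema (required keys + types).

    Returns a list of violations; empty means valid.
    """
    schema = load_summary_schema()
    problems: List[str] = []
    type_map = {"object": dict, "array": list, "string": str, "number": (int, float), "integer": int}
    for key in schema.get("required", []):
        if key not in summary:
            problems.append(f"missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in summary and "type" in sub:
            expected = type_map[sub["type"]]
            if not isinstance(summary[key], expected):
                problems.append(f"key {key!r} is not of type {sub['type']}")
    return problems


def _get_partition(
    traj: Trajectory, config: RunConfig
) -> LayerPartition:
    if config.override_boundaries is not None:
        labels = config.override_labels
        if labels is None:
            n = len(config.override_boundaries) + 1
            labels = (
                ["inner", "contact"]
                if n == 2
                else ["inner"] + ["middle"] * (n - 2) + ["contact"]
            )
        return LayerPartition(
            boundaries_r=np.asarray(config.override_boundaries, dtype=float), labels=labels
        )
    grid = make_radial_grid(config.geometry, config.dr, config.radial_margin)
    profile = radial_density(traj, config.geometry, grid, config.radial_margin)
    return segment_layers(profile, config.smoothing_window, config.min_prominence)


def run_pipeline(
    config: RunConfig, stages: Sequence[str] = ALL_STAGES
) -> Path:
    """Run the requested stages; returns the output directory.

    The layer partition is computed once from the radial density (or taken
    from the configuration override) and reused by every stage.  A failed
    stage raises :class:`PipelineError`; outputs of completed stages remain
    on disk.
    """
    t_start = time.monotonic()
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        cfg_hash = _config_hash(config)
        logger.info("aquapore %s config_hash=%s stages=%s", __version__, cfg_hash, list(stages))
        traj = read_trajectory(config.input_path, config.format)
        geom = config.geometry
        margin = config.radial_margin
        partition = _get_partition(traj, config)
        summary: Dict[str, Any] = {
            "aquapore_version": __version__,
            "config_hash": cfg_hash,
            "seed": config.seed,
            "n_frames": traj.n_frames,
            "n_molecules": traj.frames[0].n_molecules,
            "layer_boundaries_r": [float(b) for b in partition.boundaries_r],
            "layer_labels": list(partition.labels),
            "stages_run": list(stages),
            "per_layer": {},
        }
        current = "setup"
        try:
            if "density" in stages:
                current = "density"
                grid = make_radial_grid(geom, config.dr, margin)
                profile = radial_density(traj, geom, grid, margin)
                _write_csv(
                    pd.DataFrame(
                        {"r_mid": grid.r_mid, "rho": profile.rho, "count": profile.counts}
                    ),
                    out / "radial_density.csv",
                    partition,
                )
                grid2 = make_2d_grid(geom, config.dr, config.dz, margin)
                map2d = density_map_2d(traj, geom, grid2, margin)
                rr, zz = np.meshgrid(grid2.r_mid, grid2.z_mid, indexing="ij")
                _write_csv(
                    pd.DataFrame(
                        {
                            "r_mid": rr.ravel(),
                            "z_mid": zz.ravel(),
                            "rho": map2d.rho.ravel(),
                        }
                    ),
                    out / "density_map_2d.csv",
                    partition,
                )
                if "contact" in partition.labels:
                    axial = axial_contact_density(traj, geom, partition, config.dz, margin)
                    _write_csv(
                        pd.DataFrame(
                            {"z_mid": axial.x, "rho": axial.y, "count": axial.counts}
                        ),
                        out / "axial_contact_density.csv",
                        partition,
                    )
            if "orientation" in stages:
                current = "orientation"
                grid = make_radial_grid(geom, config.dr, margin)
                mean_cb, mean_abs = orientation_profiles(traj, geom, grid, margin)
                _write_csv(
                    pd.DataFrame(
                        {
                            "r_mid": mean_cb.x,
                            "mean_cos_beta": mean_cb.y,
                            "mean_abs_cos_beta": mean_abs.y,
                            "n_samples": mean_cb.counts,
                        }
                    ),
                    out / "orientation_profiles.csv",
                    partition,
                )
            if "tetra" in stages:
                current = "tetra"
                dists = layer_resolved_distributions(
                    traj, geom, partition, radial_margin=margin
                )
                records = tetrahedral_records(traj, geom, partition, margin)
                for label, curves in dists.items():
                    for name in ("gamma", "q"):
                        c = curves[name]
                        _write_csv(
                            pd.DataFrame({f"{name}_mid": c.x, "pdf": c.y, "count": c.counts}),
                            out / f"{name}_{label}.csv",
                            partition,
                        )
                for label in partition.labels:
                    qs = np.array([r.q for r in records if r.layer == label])
                    entry = summary["per_layer"].setdefault(label, {})
                    entry["mean_q"] = float(qs.mean()) if len(qs) else None
                    entry["n_q_samples"] = int(len(qs))
                    curves = dists[label]
                    if curves["q"].counts.sum() > 0:
                        entry["q_peak"] = float(curves["q"].x[np.argmax(curves["q"].y)])
                        entry["gamma_peak_deg"] = float(
                            curves["gamma"].x[np.argmax(curves["gamma"].y)]
                        )
            if "hbond" in stages:
                current = "hbond"
                table = nhb_by_layer(
                    traj, geom, partition, config.d_oo_max, config.angle_max_deg, margin
                )
                _write_csv(table, out / "nhb_by_layer.csv", partition)
                for _, row in table.iterrows():
                    entry = summary["per_layer"].setdefault(row["layer"], {})
                    entry["mean_nhb"] = float(row["mean_nhb"])
                    entry["se_nhb"] = None if pd.isna(row["se_nhb"]) else float(row["se_nhb"])
                graph = detect_hbonds(
                    traj.frames[0], geom, partition,
                    config.d_oo_max, config.angle_max_deg, margin,
                )
                export_network(graph, out / "hbond_network_frame0.txt")
                frac_rows = []
                present = [l for l in partition.labels if l in set(table["layer"])]
                for src in present:
                    for dst in present:
                        fr = hbond_type_fractions(
                            traj, geom, partition, src, dst,
                            config.d_oo_max, config.angle_max_deg, margin,
                        )
                        for k, v in fr.items():
                            frac_rows.append(
                                {"source": src, "partner": dst, "k": k, "fraction": v}
                            )
                if frac_rows:
                    _write_csv(
                        pd.DataFrame(frac_rows), out / "hbond_type_fractions.csv", partition
                    )
            if "dynamics" in stages:
                current = "dynamics"
                ledger = residence_ledger(traj, geom, margin)
                surv = survival_function(ledger, config.origin_stride)
                _write_csv(
                    pd.DataFrame({"lag_ps": surv.lag_times, "S": surv.S}),
                    out / "survival.csv",
                    partition,
                )
                msd = restricted_msd(
                    traj, ledger, geom, config.origin_stride, max_lag=config.max_lag
                )
                _write_csv(
                    pd.DataFrame(
                        {
                            "lag_ps": msd.lag_times,
                            "msd_total": msd.msd_total,
                            "msd_z": msd.msd_z,
                            "msd_xy": msd.msd_xy,
                            "n_pairs": msd.n_pairs,
                        }
                    ),
                    out / "msd.csv",
                    partition,
                )
                plateaus = plateau_estimate(msd)
                lengths = [
                    (e - s + 1) * traj.frame_spacing
                    for runs in ledger.intervals.values()
                    for s, e in runs
                ]
                summary["dynamics"] = {
                    **plateaus,
                    "survival_n0": surv.n0,
                    "mean_residence_time_ps": float(np.mean(lengths)) if lengths else None,
                    "n_residence_intervals": len(lengths),
                }
        except Exception as exc:
            logger.error("stage %s failed: %s", current, exc)
            raise PipelineError(f"stage {current} failed: {exc}") from exc
        summary["wall_time_s"] = round(time.monotonic() - t_start, 3)
        problems = validate_summary(summary)
        if problems:
            raise PipelineError(f"summary schema violations: {problems}")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        logger.info("pipeline finished in %.2fs", summary["wall_time_s"])
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
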