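"""Scenario orchestration: single runs, metrics and condition sweeps.

`run_scenario` couples the continuum fields, the bead sources and the
endothelial agents into one reproducible simulation; `run_condition_sweep`
runs the seven standard conditions (control; CPO and HOG at 1/2/4% area
fraction) over replicate bead placements and aggregates the final
metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import continuum, vasculature
from .beads import BeadSet, bead_release_rate, place_beads
from .continuum import ContinuumFields, apply_boundary_conditions, initialize_fields, step_fields
from .params import ModelParameters, ScenarioConfig, oxygen_to_percent, validate_config
from .vasculature import (
    VascularNetwork,
    grow_and_anastomose,
    notch_step_all,
    seed_boundary_sprouts,
    select_tips,
)

log = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "time", "anoxic_fraction", "hypoxic_fraction", "mean_oxygen_percent",
    "total_vegf", "viable_cell_mass", "n_vessel_segments", "n_tips",
    "penetration_depth_mm", "full_thickness", "mean_bead_source",
]


@dataclass
class SimulationResult:
    """Per-timepoint metrics plus configuration echo and snapshots."""

    config: dict[str, Any]
    parameters: dict[str, Any]
    seed: int
    metrics: pd.DataFrame
    snapshots: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)
    network: VascularNetwork | None = None
    fields: ContinuumFields | None = None


def anoxic_fraction(oxygen_field: np.ndarray, p: ModelParameters) -> float:
    """Fraction of lattice sites below the anoxia bound (0.5% oxygen)."""
    arr = np.asarray(oxygen_field, float)
    if np.any(arr < 0):
        raise ValueError("oxygen must be >= 0")
    return float(np.mean(arr < p.c_anoxia))


def hypoxic_fraction(oxygen_field: np.ndarray, p: ModelParameters) -> float:
    """Fraction of sites in the hypoxic band [0.5%, 5%) dissolved oxygen."""
    arr = np.asarray(oxygen_field, float)
    return float(np.mean((arr >= p.c_anoxia) & (arr < p.c_hypoxia)))


def half_width_mm(cfg: ScenarioConfig) -> float:
    """Distance from the implant boundary to its center, in mm."""
    return (min(cfg.grid_nx, cfg.grid_ny) - 1) / 2.0 * cfg.dx


def penetration_depth(net: VascularNetwork | None, cfg: ScenarioConfig) -> float:
    """Deepest vessel reach: max over agents of the minimum lattice
    distance to any domain edge, times dx (mm).  Empty network -> 0."""
    if net is None or net.n_agents == 0:
        return 0.0
    d = np.minimum(
        np.minimum(net.rows, cfg.grid_nx - 1 - net.rows),
        np.minimum(net.cols, cfg.grid_ny - 1 - net.cols),
    )
    return float(d.max() * cfg.dx)


def is_full_thickness(net: VascularNetwork | None, cfg: ScenarioConfig) -> bool:
    """Vessels reaching >= 90% of the half-width count as full-thickness."""
    return penetration_depth(net, cfg) >= 0.9 * half_width_mm(cfg)


def _mean_bead_source(fields: ContinuumFields, beads: BeadSet | None) -> float:
    if beads is None or len(beads) == 0:
        return 0.0
    r, c = beads.sites[:, 0], beads.sites[:, 1]
    rates = bead_release_rate(fields.oxygen[r, c], fields.t, beads.params)
    return float(np.sum(rates) / fields.oxygen.size)


def _capture(fields: ContinuumFields, net: VascularNetwork,
             beads: BeadSet | None, cfg: ScenarioConfig,
             p: ModelParameters) -> dict[str, Any]:
    depth = penetration_depth(net, cfg)
    return {
        "time": fields.t,
        "anoxic_fraction": anoxic_fraction(fields.oxygen, p),
        "hypoxic_fraction": hypoxic_fraction(fields.oxygen, p),
        "mean_oxygen_percent": continuum.mean_oxygen_percent(fields),
        "total_vegf": float(fields.vegf.sum()),
        "viable_cell_mass": float((fields.progenitor + fields.fibroblast).sum()),
        "n_vessel_segments": len(net.segments),
        "n_tips": int(np.sum(net.role == vasculature.ROLE_TIP)),
        "penetration_depth_mm": depth,
        "full_thickness": depth >= 0.9 * half_width_mm(cfg),
        "mean_bead_source": _mean_bead_source(fields, beads),
    }


def run_scenario(
    cfg: ScenarioConfig,
    p: ModelParameters | None = None,
    keep_snapshots: bool = False,
) -> SimulationResult:
    """Run one scenario end to end; fully reproducible given (cfg, seed).

    Per step: boundary conditions, explicit field step, synchronous Notch
    update of every agent; every ``growth_interval`` days tips are
    reselected and advanced; metrics (and optionally field snapshots) are
    captured every ``output_interval`` days.
    """
    p = p or ModelParameters()
    violations = validate_config(cfg, p)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))

    log.info("run_scenario start: bead_type=%s fraction=%.3f seed=%d",
             cfg.bead_type, cfg.bead_fraction, cfg.seed)
    fields = initialize_fields(cfg, p)
    beads = (
        place_beads(cfg.grid_nx, cfg.grid_ny, cfg.bead_fraction,
                    cfg.bead_type, cfg.seed, p)
        if cfg.bead_type != "none" and cfg.bead_fraction > 0 else None
    )
    net = seed_boundary_sprouts(cfg, p)

    n_steps = int(round(cfg.t_end / cfg.dt))
    growth_every = max(1, int(round(p.growth_interval / cfg.dt)))
    output_every = max(1, int(round(cfg.output_interval / cfg.dt)))
    # perfusion flags are refreshed on a coarser clock than fusion events
    # (new loops take a few hours to lumenize and carry flow)
    perfusion_every = max(1, int(round(0.25 / cfg.dt)))

    rows = [_capture(fields, net, beads, cfg, p)]
    snapshots: dict[float, dict[str, np.ndarray]] = {}
    if keep_snapshots:
        snapshots[0.0] = _snapshot(fields)

    for step in range(1, n_steps + 1):
        apply_boundary_conditions(fields, cfg, p)
        try:
            step_fields(fields, beads, net, cfg, p)
        except continuum.StabilityError as err:
            raise continuum.StabilityError(
                f"{err} (failed at t = {fields.t:.4f} days)"
            ) from err
        notch_step_all(net, fields.vegf, p, cfg.dt, oxygen_field=fields.oxygen)
        if step % growth_every == 0:
            select_tips(net, fields.vegf, p)
            grow_and_anastomose(net, fields.vegf, cfg, p, update_perfusion=False)
        if net.perfusion_dirty and step % perfusion_every == 0:
            net.update_perfusion()
        if step % output_every == 0 or step == n_steps:
            if net.perfusion_dirty:
                net.update_perfusion()
            rows.append(_capture(fields, net, beads, cfg, p))
            if keep_snapshots:
                snapshots[round(fields.t, 9)] = _snapshot(fields)

    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    log.info("run_scenario done: final anoxic=%.3f depth=%.2f mm segments=%d",
             metrics["anoxic_fraction"].iloc[-1],
             metrics["penetration_depth_mm"].iloc[-1], len(net.segments))
    return SimulationResult(
        config=cfg.as_dict(), parameters=p.as_dict(), seed=cfg.seed,
        metrics=metrics, snapshots=snapshots, network=net, fields=fields,
    )


def _snapshot(fields: ContinuumFields) -> dict[str, np.ndarray]:
    return {
        "oxygen": fields.oxygen.copy(), "vegf": fields.vegf.copy(),
        "progenitor": fields.progenitor.copy(),
        "fibroblast": fields.fibroblast.copy(), "matrix": fields.matrix.copy(),
    }


STANDARD_CONDITIONS: tuple[tuple[str, float], ...] = (
    ("none", 0.0),
    ("CPO", 0.01), ("CPO", 0.02), ("CPO", 0.04),
    ("HOG", 0.01), ("HOG", 0.02), ("HOG", 0.04),
)

FINAL_METRICS = [
    "anoxic_fraction", "hypoxic_fraction", "mean_oxygen_percent",
    "total_vegf", "viable_cell_mass", "n_vessel_segments",
    "penetration_depth_mm",
]


def run_condition_sweep(
    base_cfg: ScenarioConfig,
    p: ModelParameters | None = None,
    conditions: tuple[tuple[str, float], ...] = STANDARD_CONDITIONS,
    cv_bound: float = 0.5,
) -> pd.DataFrame:
    """Run every condition for ``base_cfg.n_replicates`` seeds and aggregate.

    Replicate seeds are base seed + 0..n-1.  Returns one row per
    (condition, metric) with the replicate median, interquartile spread,
    coefficient of variation and a consistency flag (CV above
    ``cv_bound``; never flagged for a single replicate).
    """
    import dataclasses

    p = p or ModelParameters()
    records = []
    for bead_type, fraction in conditions:
        finals = []
        for rep in range(base_cfg.n_replicates):
            cfg = dataclasses.replace(
                base_cfg, bead_type=bead_type, bead_fraction=fraction,
                seed=base_cfg.seed + rep,
            )
            res = run_scenario(cfg, p)
            finals.append(res.metrics.iloc[-1])
        tbl = pd.DataFrame(finals)
        label = "control" if bead_type == "none" else f"{bead_type}-{fraction:.0%}"
        for metric in FINAL_METRICS:
            vals = tbl[metric].to_numpy(dtype=float)
            med = float(np.median(vals))
            q75, q25 = np.percentile(vals, [75, 25])
            cv = float(np.std(vals) / abs(med)) if med != 0 else 0.0
            records.append({
                "condition": label, "bead_type": bead_type,
                "bead_fraction": fraction, "metric": metric,
                "median": med, "iqr": float(q75 - q25), "cv": cv,
                "flagged": bool(base_cfg.n_replicates > 1 and cv > cv_bound),
            })
    return pd.DataFrame.from_records(records)


def write_metrics(metrics: pd.DataFrame, path: str) -> None:
    """Metric table as tab-delimited text."""
    metrics.to_csv(path, sep="\t", index=False)


def write_snapshots_hdf5(result: SimulationResult, path: str) -> None:
    """Field snapshots as a hierarchical container: one group per
    timepoint, one dataset per field, configuration echoed as attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        for key, val in result.config.items():
            fh.attrs[f"scenario/{key}"] = val
        for t, snap in result.snapshots.items():
            grp = fh.create_group(f"t_{t:08.3f}")
            for name, arr in snap.items():
                grp.create_dataset(name, data=arr)
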