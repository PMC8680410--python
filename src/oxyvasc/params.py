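"""Model parameters, scenario configuration, unit conventions and validation.

Single source of truth for every nondimensional constant of the implant
model.  Oxygen is nondimensional with 1.0 = 21% dissolved oxygen
(atmospheric normoxia), so the implant's initial tension of 3.7% is
``3.7/21`` and the anoxia / hypoxia classification bounds of 0.5% and 5%
dissolved oxygen are ``0.5/21`` and ``5/21``.  One nondimensional time
unit is one day, which puts the half-life of the sustained
(HOG, tau = 0.05/day) release at ~13.9 days and of the burst
(CPO, tau = 0.5/day) release at ~1.4 days.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: dissolved-oxygen percentage corresponding to nondimensional oxygen 1.0
NORMOXIA_PERCENT = 21.0

BEAD_TYPES = ("none", "CPO", "HOG")


def oxygen_to_percent(c: float) -> float:
    """Convert nondimensional oxygen to percent dissolved oxygen (21 * c)."""
    import numpy as np

    if np.any(np.asarray(c) < 0):
        raise ValueError("nondimensional oxygen must be >= 0")
    return c * NORMOXIA_PERCENT


def percent_to_nondim(pct: float) -> float:
    """Convert percent dissolved oxygen to the nondimensional scale."""
    import numpy as np

    if np.any(np.asarray(pct) < 0):
        raise ValueError("percent dissolved oxygen must be >= 0")
    return pct / NORMOXIA_PERCENT


@dataclass
class ModelParameters:
    """Every rate, threshold and nondimensional constant of the model.

    Bead release (printed values): peak rate ``G_n``, oxygen
    half-saturation ``H_n`` with Hill coefficient ``hill_h``, and decay
    rates ``tau_cpo`` / ``tau_hog`` per day.  The remaining constants are
    the package's own parameterization of the reduced 5-field tissue
    model and the 8-species endothelial Dll4-Notch system; see
    docs/methods.md for the calibration rationale.
    """

    # -- bead release law ------------------------------------------------
    G_n: float = 2.2              # peak nondimensional release rate
    H_n: float = 0.11             # oxygen half-saturation of release
    hill_h: float = 6.0           # Hill coefficient of the oxygen gate
    tau_cpo: float = 0.5          # burst-release decay rate (1/day)
    tau_hog: float = 0.05         # sustained-release decay rate (1/day)

    # -- oxygen levels (fraction of normoxia) ----------------------------
    c_init: float = 3.7 / 21.0    # implant initialized at 3.7% oxygen
    c_host: float = 6.0 / 21.0    # host-side boundary oxygen (capillary-like)
    c_vessel: float = 6.0 / 21.0  # capillary-like oxygen at perfused sites
    c_anoxia: float = 0.5 / 21.0  # <0.5% dissolved oxygen is anoxic
    c_hypoxia: float = 5.0 / 21.0  # <5% dissolved oxygen is hypoxic

    # -- continuum transport & reactions (mm^2/day, 1/day) ---------------
    D_oxygen: float = 0.05        # effective oxygen diffusivity (mm^2/day)
    D_vegf: float = 0.05          # VEGF diffusivity (mm^2/day)
    D_cell: float = 0.005         # cell random-motility coefficient
    k_consume: float = 0.3        # max oxygen consumption per unit cell (1/day)
    K_consume: float = 0.02       # oxygen Michaelis constant (nondim)
    p_vegf_progenitor: float = 0.6  # baseline VEGF production rate (1/day)
    fibroblast_vegf_multiplier: float = 10.0  # fibroblast rate = 10x baseline
    phi_max: float = 10.0         # max hypoxic amplification of VEGF output
    K_phi: float = 2.5 / 21.0     # oxygen scale of the amplification
    q_phi: float = 2.0            # steepness of the amplification
    lambda_vegf: float = 1.0      # VEGF decay rate (1/day)
    u_ec: float = 1.0             # VEGF uptake rate per endothelial site
    r_prolif: float = 0.6         # max cell proliferation rate (1/day)
    d_anoxic: float = 1.0         # death rate under anoxia (1/day)
    carrying_capacity: float = 1.0  # nondimensional cap on m + f
    r_matrix: float = 0.1         # fibrous-matrix deposition rate (1/day)
    vessel_relax_rate: float = 1.0  # oxygen relaxation toward c_vessel (1/day)

    # -- initial & boundary conditions -----------------------------------
    ic_mf: float = 0.1            # initial fibrous matrix density
    ic_msc: float = 0.1           # initial progenitor density
    bc_cell_value: float = 0.01   # Dirichlet cell density on the boundary
    bc_cell_duration: float = 3.0  # days the cell Dirichlet BC is held

    # -- endothelial agent kinetics (1/day) -------------------------------
    beta_v: float = 400.0         # VEGFR-2 logistic resupply rate
    k_act: float = 40.0           # VEGFR-2 activation rate per unit VEGF
    delta_va: float = 40.0        # active VEGFR-2 decay rate
    beta_n: float = 320.0         # Notch1 logistic resupply rate
    k_notch: float = 40.0         # Notch1 activation per unit neighbor Dll4
    delta_na: float = 40.0        # active Notch1 decay rate
    k_track: float = 80.0         # rate at which effective Notch rises with Na
    k_notch_release: float = 8.0  # slow release rate of effective Notch
    beta_d4: float = 80.0         # Dll4 production per unit effective VEGFR-2
    delta_d4: float = 40.0        # Dll4 decay rate
    k_inh: float = 12.0           # Notch inhibition strength on VEGFR-2
    inh_exponent: float = 2.0     # cooperativity of the inhibition
    k_actin: float = 40.0         # actin relaxation rate toward Ve
    ec_oxygen_K: float = 0.5 / 21.0  # oxygen half-activity of endothelial cells
    ec_oxygen_q: float = 2.0      # steepness of the metabolic gate

    # -- sprouting / growth -----------------------------------------------
    theta_tip: float = 0.15       # actin threshold for tip competence
    sprout_seed_spacing: int = 10  # boundary sites between seeded sprouts
    growth_interval: float = 0.05  # days between tip advances (~33 um/h)

    def tau(self, bead_type: str) -> float:
        """Release decay rate for a bead type ('CPO' or 'HOG')."""
        if bead_type == "CPO":
            return self.tau_cpo
        if bead_type == "HOG":
            return self.tau_hog
        raise ValueError(f"unknown bead type: {bead_type!r}")

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class ScenarioConfig:
    """One in-silico implantation scenario.

    The default geometry is a 100x100 lattice at dx = 0.04 mm (a 4 mm
    wide implant cross-section) simulated for 7 days, matching the
    construct size and explant horizon of the study this model emulates.
    """

    grid_nx: int = 100            # lattice rows
    grid_ny: int = 100            # lattice columns
    dx: float = 0.04              # site spacing (mm)
    t_end: float = 7.0            # simulated duration (days)
    dt: float = 1e-3              # time step (days)
    bead_type: str = "none"       # one of {none, CPO, HOG}
    bead_fraction: float = 0.0    # fraction of sites occupied by beads
    seed: int = 0                 # bead-placement seed
    n_replicates: int = 5         # replicate seeds per condition
    output_interval: float = 0.5  # days between metric rows / snapshots

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def default_parameters() -> ModelParameters:
    """Default parameter record (printed constants + documented choices)."""
    return ModelParameters()


def default_scenario(**overrides: Any) -> ScenarioConfig:
    """Default scenario, optionally overridden field-by-field."""
    return dataclasses.replace(ScenarioConfig(), **overrides)


def stability_bound(cfg: ScenarioConfig, p: ModelParameters) -> float:
    """Largest dt the explicit 5-point diffusion stencil tolerates."""
    d_max = max(p.D_oxygen, p.D_vegf, p.D_cell)
    if d_max <= 0:
        return float("inf")
    return cfg.dx**2 / (4.0 * d_max)


def validate_config(cfg: ScenarioConfig, p: ModelParameters) -> list[str]:
    """Check every invariant; violations are returned as data, not raised."""
    v: list[str] = []

    nonneg_params = (
        "G_n", "H_n", "tau_cpo", "tau_hog", "c_init", "c_host", "c_vessel",
        "c_anoxia", "c_hypoxia", "D_oxygen", "D_vegf", "D_cell", "k_consume",
        "K_consume", "p_vegf_progenitor", "fibroblast_vegf_multiplier",
        "phi_max", "K_phi", "q_phi", "lambda_vegf", "u_ec", "r_prolif",
        "d_anoxic", "carrying_capacity", "r_matrix", "vessel_relax_rate",
        "ic_mf", "ic_msc", "bc_cell_value", "bc_cell_duration",
        "beta_v", "k_act", "delta_va", "beta_n", "k_notch", "delta_na",
        "k_track", "k_notch_release", "beta_d4", "delta_d4", "k_inh", "k_actin", "theta_tip",
        "growth_interval", "ec_oxygen_K", "ec_oxygen_q",
    )
    for name in nonneg_params:
        if getattr(p, name) < 0:
            v.append(f"parameter {name} must be >= 0")
    if not (p.c_anoxia < p.c_hypoxia < 1.0):
        v.append("thresholds must satisfy c_anoxia < c_hypoxia < 1")
    if not (0.0 <= p.c_init <= 1.0):
        v.append("c_init must lie in [0, 1]")
    if p.hill_h < 1.0:
        v.append("hill_h must be >= 1")
    if p.sprout_seed_spacing < 1:
        v.append("sprout_seed_spacing must be >= 1")

    if cfg.grid_nx < 3 or cfg.grid_ny < 3:
        v.append("grid_nx and grid_ny must be >= 3")
    if cfg.dx <= 0:
        v.append("dx must be > 0")
    if cfg.t_end <= 0:
        v.append("t_end must be > 0")
    if cfg.dt <= 0:
        v.append("dt must be > 0")
    if cfg.output_interval <= 0:
        v.append("output_interval must be > 0")
    if cfg.n_replicates < 1:
        v.append("n_replicates must be >= 1")
    if cfg.bead_type not in BEAD_TYPES:
        v.append(f"bead_type must be one of {BEAD_TYPES}")
    if not (0.0 <= cfg.bead_fraction <= 0.1):
        v.append("bead_fraction must lie in [0, 0.1]")
    if cfg.bead_type != "none" and cfg.bead_fraction * cfg.grid_nx * cfg.grid_ny < 1:
        v.append("bead_fraction yields zero beads for bead_type != none")

    if cfg.dt > 0 and cfg.dt > stability_bound(cfg, p):
        v.append(
            f"dt = {cfg.dt} exceeds the diffusion stability bound "
            f"dx^2/(4 max D) = {stability_bound(cfg, p):.3g}"
        )
    return v


def load_config(path: str) -> tuple[ScenarioConfig, ModelParameters]:
    """Read a plain-text key/value (YAML) configuration file.

    Keys may be flat or grouped under ``scenario:`` / ``parameters:``;
    every default is overridable and unknown keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scen_keys = {f.name for f in dataclasses.fields(ScenarioConfig)}
    par_keys = {f.name for f in dataclasses.fields(ModelParameters)}

    scen_over: dict[str, Any] = dict(raw.get("scenario", {}))
    par_over: dict[str, Any] = dict(raw.get("parameters", {}))
    for key, val in raw.items():
        if key in ("scenario", "parameters"):
            continue
        if key in scen_keys:
            scen_over[key] = val
        elif key in par_keys:
            par_over[key] = val
        else:
            raise KeyError(f"unknown configuration key: {key!r}")
    for key in scen_over:
        if key not in scen_keys:
            raise KeyError(f"unknown scenario key: {key!r}")
    for key in par_over:
        if key not in par_keys:
            raise KeyError(f"unknown parameter key: {key!r}")

    cfg = dataclasses.replace(ScenarioConfig(), **scen_over)
    p = dataclasses.replace(ModelParameters(), **par_over)
    return cfg, p


def config_echo(cfg: ScenarioConfig, p: ModelParameters) -> str:
    """YAML echo of a full configuration, for provenance in outputs."""
    return yaml.safe_dump(
        {"scenario": cfg.as_dict(), "parameters": p.as_dict()},
        sort_keys=True,
    )
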