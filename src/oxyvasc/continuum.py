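"""Tissue-level taxis-diffusion-reaction fields.

Five coupled fields on the scenario lattice: oxygen ``c``, VEGF ``g``,
progenitor density ``m``, fibroblast density ``f`` and fibrous matrix
``mf``.  Explicit finite differences with a 5-point Laplacian; zero-flux
boundaries are implemented by edge (ghost-mirror) padding, with Dirichlet
values re-imposed on the edge sites where stated (oxygen at the host
level throughout; cell densities at 0.01 for the first 3 days).

Reactions:

    dc/dt  = D_c lap c - k (m+f) c/(c+K) + bead release + vessel relaxation
    dg/dt  = D_g lap g + (p m + 10 p f) phi(c) - lambda g - u_ec g [EC site]
    dm/dt  = D_m lap m + r rho(c) m (1 - (m+f)/cap) - d_anx [anoxic] m
    df/dt  = likewise (fibroblasts enter only via the boundary condition)
    dmf/dt = r_mx (m+f) (1 - mf)

with rho(c) = c/(c+K) and the hypoxic VEGF amplification
phi(c) = 1 + (phi_max - 1) K_phi^q / (c^q + K_phi^q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beads import BeadSet, bead_release_rate
from .params import ModelParameters, ScenarioConfig, oxygen_to_percent


class StabilityError(RuntimeError):
    """Raised when a field goes non-finite during an explicit step."""


@dataclass
class ContinuumFields:
    """Gridded scalar fields and the current simulation time (days)."""

    oxygen: np.ndarray
    vegf: np.ndarray
    progenitor: np.ndarray
    fibroblast: np.ndarray
    matrix: np.ndarray
    t: float = 0.0

    def copy(self) -> "ContinuumFields":
        return ContinuumFields(
            oxygen=self.oxygen.copy(), vegf=self.vegf.copy(),
            progenitor=self.progenitor.copy(), fibroblast=self.fibroblast.copy(),
            matrix=self.matrix.copy(), t=self.t,
        )


def initialize_fields(cfg: ScenarioConfig, p: ModelParameters) -> ContinuumFields:
    """Uniform initial state: oxygen at c_init, matrix and progenitors at
    their stated initial densities, no fibroblasts, no VEGF."""
    shape = (cfg.grid_nx, cfg.grid_ny)
    return ContinuumFields(
        oxygen=np.full(shape, p.c_init),
        vegf=np.zeros(shape),
        progenitor=np.full(shape, p.ic_msc),
        fibroblast=np.zeros(shape),
        matrix=np.full(shape, p.ic_mf),
        t=0.0,
    )


def classify_oxygen(c, p: ModelParameters | None = None):
    """Classify nondimensional oxygen as 'anoxic' / 'hypoxic' / 'normoxic'.

    Anoxic below 0.5% dissolved oxygen, hypoxic below 5%, normoxic above.
    Scalars return a string; arrays return an object array of strings.
    """
    p = p or ModelParameters()
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValueError("oxygen must be >= 0")
    out = np.where(arr < p.c_anoxia, "anoxic",
                   np.where(arr < p.c_hypoxia, "hypoxic", "normoxic"))
    return out if out.ndim else str(out)


def hypoxia_amplification(c, p: ModelParameters):
    """phi(c): VEGF output amplification, phi_max at anoxia down to 1."""
    q = p.q_phi
    return 1.0 + (p.phi_max - 1.0) * p.K_phi**q / (np.asarray(c, float) ** q + p.K_phi**q)


def vegf_production_rate(m, f, c, p: ModelParameters):
    """Per-site VEGF production: hypoxia-amplified output of progenitors
    plus fibroblasts (fibroblasts produce at 10x the progenitor rate)."""
    base = p.p_vegf_progenitor * (
        np.asarray(m, float) + p.fibroblast_vegf_multiplier * np.asarray(f, float)
    )
    return base * hypoxia_amplification(c, p)


def laplacian(a: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with zero-flux (edge-mirrored ghost) boundaries.

    Written in flux form (each inter-cell difference added antisymmetrically
    to both cells), so the discrete total is conserved to roundoff and the
    boundary flux is exactly zero.
    """
    out = np.zeros_like(a)
    d = a[1:, :] - a[:-1, :]
    out[:-1, :] += d
    out[1:, :] -= d
    d = a[:, 1:] - a[:, :-1]
    out[:, :-1] += d
    out[:, 1:] -= d
    return out / dx**2


def apply_boundary_conditions(
    fields: ContinuumFields, cfg: ScenarioConfig, p: ModelParameters
) -> ContinuumFields:
    """Impose Dirichlet edges: oxygen at the host level throughout; cell
    densities at bc_cell_value while t <= bc_cell_duration (afterwards the
    zero-flux padding of the Laplacian applies).  VEGF is always zero-flux."""
    for fld, val in ((fields.oxygen, p.c_host),):
        fld[0, :] = val; fld[-1, :] = val; fld[:, 0] = val; fld[:, -1] = val
    if fields.t <= p.bc_cell_duration:
        for fld in (fields.progenitor, fields.fibroblast):
            fld[0, :] = p.bc_cell_value; fld[-1, :] = p.bc_cell_value
            fld[:, 0] = p.bc_cell_value; fld[:, -1] = p.bc_cell_value
    return fields


def step_fields(
    fields: ContinuumFields,
    beads: BeadSet | None,
    network,
    cfg: ScenarioConfig,
    p: ModelParameters,
) -> ContinuumFields:
    """Advance every field by one explicit Euler step of length cfg.dt.

    ``network`` may be None (no endothelial agents) or a VascularNetwork,
    whose occupied sites take up VEGF and whose perfused sites relax
    oxygen toward c_vessel.  Updates in place and returns ``fields``.
    """
    dt, dx = cfg.dt, cfg.dx
    c, g = fields.oxygen, fields.vegf
    m, f, mf = fields.progenitor, fields.fibroblast, fields.matrix

    cells = m + f
    consumption = p.k_consume * cells * c / (c + p.K_consume)

    dc = p.D_oxygen * laplacian(c, dx) - consumption
    if beads is not None and len(beads) > 0:
        r, col = beads.sites[:, 0], beads.sites[:, 1]
        np.add.at(dc, (r, col), bead_release_rate(c[r, col], fields.t, beads.params))
    if network is not None and network.n_agents:
        perf = network.perfused_site_mask()
        if perf.any():
            dc += p.vessel_relax_rate * (p.c_vessel - c) * perf

    dg = (
        p.D_vegf * laplacian(g, dx)
        + vegf_production_rate(m, f, c, p)
        - p.lambda_vegf * g
    )
    if network is not None and network.n_agents:
        dg -= p.u_ec * g * network.occupied_site_mask()

    rho = c / (c + p.K_consume)
    crowd = 1.0 - cells / p.carrying_capacity
    anoxic = c < p.c_anoxia
    dm = (
        p.D_cell * laplacian(m, dx)
        + p.r_prolif * rho * m * crowd
        - p.d_anoxic * anoxic * m
    )
    df = (
        p.D_cell * laplacian(f, dx)
        + p.r_prolif * rho * f * crowd
        - p.d_anoxic * anoxic * f
    )
    dmf = p.r_matrix * cells * (1.0 - mf)

    np.clip(c + dt * dc, 0.0, None, out=c)
    np.clip(g + dt * dg, 0.0, None, out=g)
    np.clip(m + dt * dm, 0.0, None, out=m)
    np.clip(f + dt * df, 0.0, None, out=f)
    np.clip(mf + dt * dmf, 0.0, None, out=mf)

    total = c.sum() + g.sum() + m.sum() + f.sum() + mf.sum()
    if not np.isfinite(total):
        raise StabilityError(
            f"non-finite field value at t = {fields.t + dt:.4f} days; "
            f"dt = {dt} is too large for the configured rates"
        )
    fields.t += dt
    return fields


def mean_oxygen_percent(fields: ContinuumFields) -> float:
    """Spatial mean oxygen, in percent dissolved oxygen."""
    return float(oxygen_to_percent(float(fields.oxygen.mean())))


def write_field_txt(arr: np.ndarray, path: str) -> None:
    """Export one field as tab-delimited text (row-major grid)."""
    np.savetxt(path, arr, delimiter="\t", fmt="%.10g")
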