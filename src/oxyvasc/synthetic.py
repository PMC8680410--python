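"""Synthetic fixtures: release curves, VEGF ramps, endothelial rows.

Everything the pipeline consumes can be generated here without external
data: oxygen-generation time courses with the burst (CPO-like) versus
sustained (HOG-like) kinetics, linear VEGF gradients for tip-migration
tests, and short rows of endothelial agents for lateral-inhibition tests.
Noise is additive, homoscedastic and seeded; with ``noise_sd = 0`` the
output equals the analytic model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .beads import ReleaseCurve, ReleaseParams, bead_release_rate
from .vasculature import BASELINE_STATE, V, EndothelialAgent

KINDS = ("release_curve", "vegf_field", "ec_row", "bead_layout")


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic fixture."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_release_curve(
    G: float = 2.2,
    tau: float = 0.05,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    H_n: float = 0.11,
    hill_h: float = 6.0,
) -> ReleaseCurve:
    """Sample the zero-oxygen release law, optionally with additive noise.

    Defaults emulate the sustained (HOG-like) kinetics; ``tau = 0.5``
    gives the burst (CPO-like) curve.  Noisy rates are clipped at zero.
    """
    if times is None:
        times = np.linspace(0.0, 14.0, 57)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("sampling times must be non-empty")
    rp = ReleaseParams(G_n=G, H_n=H_n, hill_h=hill_h, tau=tau)
    rates = bead_release_rate(np.zeros_like(times), times, rp)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = np.clip(rates + rng.normal(0.0, noise_sd, size=times.shape), 0.0, None)
    return ReleaseCurve(times=times, rates=np.asarray(rates), noise_sd=noise_sd)


DIRECTIONS = ("north", "east", "south", "west")


def make_vegf_gradient(nx: int, ny: int, direction: str, peak: float) -> np.ndarray:
    """Linear VEGF ramp from 0 to ``peak`` along a compass direction.

    'east' increases with column index, 'south' with row index; 'west'
    and 'north' are their exact mirrors.
    """
    if peak < 0:
        raise ValueError("peak must be >= 0")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    ramp_col = np.linspace(0.0, peak, ny)
    ramp_row = np.linspace(0.0, peak, nx)
    if direction == "east":
        return np.tile(ramp_col, (nx, 1))
    if direction == "west":
        return np.tile(ramp_col[::-1], (nx, 1))
    if direction == "south":
        return np.tile(ramp_row[:, np.newaxis], (1, ny))
    return np.tile(ramp_row[::-1, np.newaxis], (1, ny))


def make_ec_row(
    n_cells: int, perturbation: float = 0.0, seed: int = 0, row: int = 0
) -> list[EndothelialAgent]:
    """A 1 x n row of quiescent agents with seeded VEGFR-2 perturbations.

    All agents share the baseline state; the VEGFR-2 pool of each is
    offset by a uniform draw in [-perturbation, +perturbation].
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    agents = []
    for j in range(n_cells):
        state = BASELINE_STATE.copy()
        if perturbation > 0:
            state[V] = max(0.0, state[V] + rng.uniform(-perturbation, perturbation))
        agents.append(EndothelialAgent(site=(row, j), role="quiescent", state=state))
    return agents


def generate(spec: SyntheticSpec):
    """Dispatch a SyntheticSpec to its generator."""
    if spec.kind == "release_curve":
        return make_release_curve(**spec.params, noise_sd=spec.noise_sd, seed=spec.seed)
    if spec.kind == "vegf_field":
        return make_vegf_gradient(**spec.params)
    if spec.kind == "ec_row":
        return make_ec_row(**spec.params, seed=spec.seed)
    if spec.kind == "bead_layout":
        from .beads import place_beads

        return place_beads(**spec.params, seed=spec.seed)
    raise ValueError(f"unknown kind: {spec.kind}")
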