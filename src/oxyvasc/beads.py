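"""Oxygen-generating bead kinetics, placement and parameter estimation.

The release law is a decreasing Hill gate on local oxygen times an
exponential depletion clock,

    rate(c, t) = G_n * H_n**h / (c**h + H_n**h) * exp(-tau * t),

with shared peak rate ``G_n = 2.2`` and oxygen half-saturation
``H_n = 0.11`` and with ``tau = 0.5``/day for the burst-release CPO
particles versus ``tau = 0.05``/day for the sustained-release HOGs.
The oxygen gate makes release self-limiting: once local oxygen exceeds
``H_n`` (~2.3% dissolved oxygen, inside the hypoxic band) generation
shuts down steeply (Hill coefficient ``h = 6``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .params import ModelParameters


@dataclass
class ReleaseParams:
    """The (G_n, H_n, hill_h, tau) tuple in effect for one bead type."""

    G_n: float
    H_n: float
    hill_h: float
    tau: float

    @classmethod
    def for_type(cls, bead_type: str, p: ModelParameters) -> "ReleaseParams":
        return cls(G_n=p.G_n, H_n=p.H_n, hill_h=p.hill_h, tau=p.tau(bead_type))


@dataclass
class BeadSet:
    """Lattice sites occupied by beads of a single type."""

    sites: np.ndarray          # (n, 2) int array of (row, col)
    bead_type: str             # 'CPO' or 'HOG'
    params: ReleaseParams
    placement_seed: int

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ReleaseCurve:
    """A sampled oxygen-generation time course (possibly noisy)."""

    times: np.ndarray          # days, strictly increasing
    rates: np.ndarray          # nondimensional release rate
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D sequence")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.rates.shape != self.times.shape:
            raise ValueError("times and rates must have matching shapes")


def bead_release_rate(c, t, params: ReleaseParams):
    """Instantaneous release rate at local oxygen ``c`` and age ``t`` days.

    Accepts scalars or arrays (broadcast).  Bounded by ``G_n * exp(-tau t)``,
    strictly decreasing in ``t`` and non-increasing in ``c``.
    """
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(c < 0):
        raise ValueError("local oxygen must be >= 0")
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    h = params.hill_h
    hill = params.H_n**h / (c**h + params.H_n**h)
    out = params.G_n * hill * np.exp(-params.tau * t)
    return out if out.ndim else float(out)


def cumulative_release_zero_oxygen(t, params: ReleaseParams):
    """Total release up to ``t`` days with the oxygen gate fully open.

    Closed form (G_n / tau) * (1 - exp(-tau t)); the t -> infinity limit
    is G_n / tau, i.e. the sustained particles deliver tau_cpo/tau_hog =
    10x the total oxygen of the burst particles.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if params.tau == 0:
        raise ValueError("tau must be nonzero for the closed form")
    out = params.G_n / params.tau * (1.0 - np.exp(-params.tau * t))
    return out if out.ndim else float(out)


def place_beads(
    grid_nx: int,
    grid_ny: int,
    fraction: float,
    bead_type: str,
    seed: int,
    p: ModelParameters | None = None,
) -> BeadSet:
    """Place ``round(fraction * nx * ny)`` beads uniformly without replacement.

    Deterministic given (grid, fraction, seed); the seed governs placement
    only.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    p = p or ModelParameters()
    n_sites = grid_nx * grid_ny
    n_beads = int(round(fraction * n_sites))
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_sites, size=n_beads, replace=False)
    sites = np.column_stack(np.unravel_index(np.sort(flat), (grid_nx, grid_ny)))
    return BeadSet(
        sites=sites.astype(np.int64),
        bead_type=bead_type,
        params=ReleaseParams.for_type(bead_type, p) if bead_type != "none"
        else ReleaseParams(p.G_n, p.H_n, p.hill_h, 0.0),
        placement_seed=seed,
    )


def fit_release_params(
    curve: ReleaseCurve,
    fix_H: bool = True,
    oxygen: float = 0.0,
    H_n: float = 0.11,
    hill_h: float = 6.0,
):
    """Least-squares estimate of (G_n, tau) [and H_n] from a release curve.

    The curve is modelled as ``bead_release_rate`` evaluated at constant
    local oxygen (default 0, where the Hill gate is 1 and only G_n and tau
    are identifiable).  Initialization is deterministic: G starts at the
    maximum observed rate and tau at the log-slope between the first and
    last strictly positive samples.

    Returns ``(estimates, residual_norm)`` where estimates is a dict with
    keys ``G_n``, ``tau`` and (if ``fix_H`` is false) ``H_n``.
    """
    t, y = curve.times, curve.rates
    if t.size < 5:
        raise ValueError("need at least 5 samples to fit the release law")
    if np.any(y < -10 * max(curve.noise_sd, 1e-12)):
        raise ValueError("rates must be >= 0 (up to noise)")
    if not np.any(y > 0):
        raise ValueError("all-zero curve: release parameters are degenerate")
    if not fix_H and oxygen == 0.0:
        raise ValueError("H_n is unidentifiable from a zero-oxygen curve")

    g0 = float(np.max(y))
    pos = np.flatnonzero(y > 0)
    i0, i1 = pos[0], pos[-1]
    if i1 > i0 and y[i1] < y[i0]:
        tau0 = float(np.log(y[i0] / y[i1]) / (t[i1] - t[i0]))
    else:
        tau0 = 0.1
    tau0 = max(tau0, 1e-6)

    def model(theta):
        if fix_H:
            g, tau = theta
            hn = H_n
        else:
            g, tau, hn = theta
        rp = ReleaseParams(G_n=g, H_n=hn, hill_h=hill_h, tau=tau)
        return bead_release_rate(np.full_like(t, oxygen), t, rp)

    x0 = [g0, tau0] if fix_H else [g0, tau0, H_n]
    lower = [0.0, 1e-9] if fix_H else [0.0, 1e-9, 1e-9]
    sol = least_squares(
        lambda th: model(th) - y, x0=x0, bounds=(lower, np.inf),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    est = {"G_n": float(sol.x[0]), "tau": float(sol.x[1])}
    if not fix_H:
        est["H_n"] = float(sol.x[2])
    return est, float(np.linalg.norm(sol.fun))


def write_bead_set(bs: BeadSet, path: str) -> None:
    """Serialize a BeadSet as (row, col, type) tab-delimited text."""
    with open(path, "w") as fh:
        fh.write("row\tcol\ttype\n")
        for r, c in bs.sites:
            fh.write(f"{r}\t{c}\t{bs.bead_type}\n")


def read_bead_set(path: str, p: ModelParameters | None = None,
                  placement_seed: int = -1) -> BeadSet:
    """Read a BeadSet written by :func:`write_bead_set`."""
    p = p or ModelParameters()
    rows, cols, types = [], [], []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            r, c, ty = line.split()
            rows.append(int(r)); cols.append(int(c)); types.append(ty)
    if not types:
        raise ValueError("empty bead file")
    bead_type = types[0]
    if any(ty != bead_type for ty in types):
        raise ValueError("mixed bead types in one file")
    return BeadSet(
        sites=np.column_stack([rows, cols]).astype(np.int64),
        bead_type=bead_type,
        params=ReleaseParams.for_type(bead_type, p),
        placement_seed=placement_seed,
    )


def write_release_curve(curve: ReleaseCurve, path: str) -> None:
    """Serialize a ReleaseCurve as two-column (time_days, rate) text."""
    with open(path, "w") as fh:
        fh.write("time_days\trate\n")
        for t, r in zip(curve.times, curve.rates):
            fh.write(f"{t:.10g}\t{r:.10g}\n")


def read_release_curve(path: str, noise_sd: float = 0.0) -> ReleaseCurve:
    """Read a ReleaseCurve written by :func:`write_release_curve`."""
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    return ReleaseCurve(times=data[:, 0], rates=data[:, 1], noise_sd=noise_sd)
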