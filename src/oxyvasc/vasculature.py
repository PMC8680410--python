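"""Discrete endothelial agents: Dll4-Notch lateral inhibition, tip
selection, sprout growth up VEGF gradients, anastomosis and perfusion.

Each agent carries eight intracellular species: VEGFR-2 (V), active
VEGFR-2 (Va), effective active VEGFR-2 (Ve), Notch1 (N), active Notch1
(Na), effective active Notch1 (Ne), Dll4 (D4) and actin (A).  The causal
chain is VEGF -> Va -> Ve -> Dll4 -> neighbor Na/Ne -> suppressed
neighbor Ve -> suppressed neighbor actin; a cell whose actin exceeds
``theta_tip`` and beats every lattice neighbor becomes a migrating tip.

The inhibition of effective VEGFR-2 by effective Notch is cooperative,

    Ve = Va / (1 + (k_inh * Ne)**inh_exponent),

with exponent 2 by default: a linear attenuation admits no symmetry
breaking (the homogeneous state of the two-cell fixed-point map
x = M/(1 + k x) is always stable), whereas with exponent 2 the
homogeneous state destabilizes once k_inh * Ne exceeds 1, giving the
salt-and-pepper tip/stalk pattern characteristic of lateral inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .params import ModelParameters, ScenarioConfig

# species indices in the 8-vector
V, VA, VE, N1, NA, NE, D4, ACT = range(8)
SPECIES = ("V", "Va", "Ve", "N", "Na", "Ne", "D4", "A")

#: intracellular state of a resting endothelial cell: full receptor pools,
#: no signalling activity
BASELINE_STATE = np.array([1.0, 0, 0, 1.0, 0, 0, 0, 0])

ROLE_QUIESCENT, ROLE_STALK, ROLE_TIP = 0, 1, 2
ROLE_NAMES = {ROLE_QUIESCENT: "quiescent", ROLE_STALK: "stalk", ROLE_TIP: "tip"}

# neighbor offsets in deterministic N, E, S, W order (N = row - 1)
_OFFSETS = ((-1, 0), (0, 1), (1, 0), (0, -1))


@dataclass
class EndothelialAgent:
    """One endothelial cell: lattice site, role and 8-species state."""

    site: tuple[int, int]
    role: str = "quiescent"
    state: np.ndarray = field(default_factory=lambda: BASELINE_STATE.copy())
    sprout_id: int = 0

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float)
        if self.state.shape != (8,):
            raise ValueError("state must hold exactly 8 species")
        if np.any(self.state < 0):
            raise ValueError("species levels must be >= 0")


def _effective_vegfr(va, ne, p: ModelParameters):
    return va / (1.0 + (p.k_inh * ne) ** p.inh_exponent)


def metabolic_activity(c, p: ModelParameters):
    """Oxygen-dependent activity of endothelial signalling, in [0, 1].

    A Hill factor c^q / (c^q + K^q) centered on the anoxia bound:
    endothelial cells in anoxic tissue cannot sustain VEGFR-2 signalling
    (so sprouts stall at the anoxic frontier), while hypoxic and normoxic
    tissue supports near-full activity.
    """
    c = np.asarray(c, dtype=float)
    q = p.ec_oxygen_q
    out = c**q / (c**q + p.ec_oxygen_K**q)
    return out if out.ndim else float(out)


def notch_step(
    agent: EndothelialAgent,
    neighbor_agents: list[EndothelialAgent],
    local_vegf: float,
    p: ModelParameters,
    dt: float,
    local_oxygen: float | None = None,
) -> EndothelialAgent:
    """One explicit update of the intracellular system for a single agent.

    Neighbor states are read at their pre-step values (synchronous
    semantics when applied to a whole network).  If ``local_oxygen`` is
    given, VEGFR-2 activation is scaled by :func:`metabolic_activity`;
    with None the cell is treated as metabolically unconstrained.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    s = agent.state
    if np.any(s < 0):
        raise ValueError("species levels must be >= 0")
    if neighbor_agents:
        mean_d4 = float(np.mean([nb.state[D4] for nb in neighbor_agents]))
    else:
        mean_d4 = 0.0
    oxy = None if local_oxygen is None else np.array([local_oxygen])
    new = _advance_states(
        s[np.newaxis, :], np.array([mean_d4]), np.array([local_vegf]), p, dt,
        oxygen=oxy,
    )[0]
    return EndothelialAgent(
        site=agent.site, role=agent.role, state=new, sprout_id=agent.sprout_id
    )


def _advance_states(states, mean_d4, vegf, p: ModelParameters, dt: float,
                    oxygen=None):
    """Vectorized synchronous update of (n, 8) state rows."""
    v, va, ne, n1, na, d4, act = (
        states[:, V], states[:, VA], states[:, NE],
        states[:, N1], states[:, NA], states[:, D4], states[:, ACT],
    )
    ve = _effective_vegfr(va, ne, p)

    drive = p.k_act * vegf
    if oxygen is not None:
        drive = drive * metabolic_activity(oxygen, p)
    dv = p.beta_v * v * (1.0 - v) - drive * v
    dva = drive * v - p.delta_va * va
    dn1 = p.beta_n * n1 * (1.0 - n1) - p.k_notch * mean_d4 * n1
    dna = p.k_notch * mean_d4 * n1 - p.delta_na * na
    # effective Notch rises quickly with Na but releases slowly (persistent
    # transcriptional repression), which keeps fresh stalk cells inhibited
    # for upwards of a day and so spaces out branch initiation
    dne = np.where(na > ne, p.k_track, p.k_notch_release) * (na - ne)
    dd4 = p.beta_d4 * ve - p.delta_d4 * d4
    dact = p.k_actin * (ve - act)

    out = states.copy()
    out[:, V] = v + dt * dv
    out[:, VA] = va + dt * dva
    out[:, N1] = n1 + dt * dn1
    out[:, NA] = na + dt * dna
    out[:, NE] = ne + dt * dne
    out[:, D4] = d4 + dt * dd4
    out[:, ACT] = act + dt * dact
    np.clip(out, 0.0, None, out=out)
    out[:, VE] = _effective_vegfr(out[:, VA], out[:, NE], p)
    return out


class VascularNetwork:
    """All endothelial agents plus the segment graph connecting them.

    Agents are stored as parallel arrays for vectorized updates; a
    ``site_index`` grid maps lattice sites to agent ids (-1 = empty).
    Segments are undirected edges between lattice-adjacent agents; a
    segment is flagged perfused when it lies on a path between two
    distinct boundary roots (an anastomosed loop).
    """

    def __init__(self, grid_nx: int, grid_ny: int, capacity: int = 64) -> None:
        self.shape = (grid_nx, grid_ny)
        self._n = 0
        self._cap = capacity
        self._rows = np.empty(capacity, dtype=np.int64)
        self._cols = np.empty(capacity, dtype=np.int64)
        self._state = np.empty((capacity, 8), dtype=float)
        self._role = np.empty(capacity, dtype=np.int8)
        self._sprout_id = np.empty(capacity, dtype=np.int64)
        self._is_root = np.empty(capacity, dtype=bool)
        self._degree = np.empty(capacity, dtype=np.int64)
        self._uf_parent = np.empty(capacity, dtype=np.int64)
        self._next_sprout_id = 0
        self.site_index = np.full((grid_nx, grid_ny), -1, dtype=np.int64)
        self.segments: list[tuple[int, int]] = []
        self.perfused: list[bool] = []
        self.perfusion_dirty: bool = False
        self._perfused_mask: np.ndarray | None = None

    # agent storage uses amortized capacity doubling; the public attributes
    # are views onto the live prefix, so in-place mutation is cheap
    @property
    def rows(self) -> np.ndarray:
        return self._rows[: self._n]

    @property
    def cols(self) -> np.ndarray:
        return self._cols[: self._n]

    @property
    def state(self) -> np.ndarray:
        return self._state[: self._n]

    @property
    def role(self) -> np.ndarray:
        return self._role[: self._n]

    @property
    def sprout_id(self) -> np.ndarray:
        return self._sprout_id[: self._n]

    @property
    def is_root(self) -> np.ndarray:
        return self._is_root[: self._n]

    @property
    def n_agents(self) -> int:
        return self._n

    def _grow_buffers(self) -> None:
        self._cap *= 2
        for name in ("_rows", "_cols", "_role", "_sprout_id", "_is_root",
                     "_degree", "_uf_parent"):
            buf = getattr(self, name)
            new = np.empty(self._cap, dtype=buf.dtype)
            new[: self._n] = buf[: self._n]
            setattr(self, name, new)
        new_state = np.empty((self._cap, 8), dtype=float)
        new_state[: self._n] = self._state[: self._n]
        self._state = new_state

    def add_agent(
        self,
        site: tuple[int, int],
        role: int = ROLE_QUIESCENT,
        state: np.ndarray | None = None,
        sprout_id: int = 0,
        is_root: bool = False,
    ) -> int:
        r, c = site
        if self.site_index[r, c] != -1:
            raise ValueError(f"site {site} already occupied")
        if self._n == self._cap:
            self._grow_buffers()
        idx = self._n
        self._rows[idx] = r
        self._cols[idx] = c
        self._state[idx] = BASELINE_STATE if state is None else np.asarray(state, float)
        self._role[idx] = role
        self._sprout_id[idx] = sprout_id
        self._is_root[idx] = is_root
        self._degree[idx] = 0
        self._uf_parent[idx] = idx
        self._n += 1
        self._next_sprout_id = max(self._next_sprout_id, sprout_id + 1)
        self.site_index[r, c] = idx
        return idx

    # -- segment bookkeeping ----------------------------------------------

    def _uf_find(self, i: int) -> int:
        parent = self._uf_parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return int(root)

    def same_tree(self, i: int, j: int) -> bool:
        """True if agents i and j already belong to one connected vessel."""
        return self._uf_find(i) == self._uf_find(j)

    def add_segment(self, i: int, j: int) -> None:
        """Connect two agents; updates degrees and tree connectivity."""
        self.segments.append((int(i), int(j)))
        self.perfused.append(False)
        self._degree[i] += 1
        self._degree[j] += 1
        self._uf_parent[self._uf_find(i)] = self._uf_find(j)

    @property
    def degree(self) -> np.ndarray:
        return self._degree[: self._n]

    @classmethod
    def from_agents(
        cls, grid_nx: int, grid_ny: int, agents: list[EndothelialAgent]
    ) -> "VascularNetwork":
        net = cls(grid_nx, grid_ny)
        name_to_role = {v: k for k, v in ROLE_NAMES.items()}
        for a in agents:
            net.add_agent(a.site, role=name_to_role[a.role], state=a.state,
                          sprout_id=a.sprout_id)
        return net

    def agent(self, idx: int) -> EndothelialAgent:
        """Materialize one agent as an EndothelialAgent record."""
        return EndothelialAgent(
            site=(int(self.rows[idx]), int(self.cols[idx])),
            role=ROLE_NAMES[int(self.role[idx])],
            state=self.state[idx].copy(),
            sprout_id=int(self.sprout_id[idx]),
        )

    # -- neighbor machinery ----------------------------------------------

    def _neighbor_ids(self) -> np.ndarray:
        """(n, 4) agent ids of lattice neighbors in N,E,S,W order; -1 absent."""
        nr, nc = self.shape
        out = np.full((self.n_agents, 4), -1, dtype=np.int64)
        for k, (dr, dc) in enumerate(_OFFSETS):
            rr, cc = self.rows + dr, self.cols + dc
            ok = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
            out[ok, k] = self.site_index[rr[ok], cc[ok]]
        return out

    def neighbors_of(self, idx: int) -> list[int]:
        nr, nc = self.shape
        r, c = self.rows[idx], self.cols[idx]
        out = []
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and self.site_index[rr, cc] != -1:
                out.append(int(self.site_index[rr, cc]))
        return out

    def occupied_site_mask(self) -> np.ndarray:
        return self.site_index >= 0

    def perfused_site_mask(self) -> np.ndarray:
        """Boolean grid of sites belonging to perfused segments.

        Cached between perfusion updates (agents never leave a perfused
        segment once flagged, and flags only change in update_perfusion).
        """
        if self._perfused_mask is None:
            mask = np.zeros(self.shape, dtype=bool)
            ids = [i for (i, j), perf in zip(self.segments, self.perfused)
                   if perf for i in (i, j)]
            if ids:
                ids = np.asarray(ids)
                mask[self._rows[ids], self._cols[ids]] = True
            self._perfused_mask = mask
        return self._perfused_mask

    # -- graph helpers ----------------------------------------------------

    def graph(self) -> nx.Graph:
        gph = nx.Graph()
        gph.add_nodes_from(range(self.n_agents))
        gph.add_edges_from(self.segments)
        return gph

    def update_perfusion(self) -> None:
        """Flag segments lying on shortest loops between boundary roots."""
        gph = self.graph()
        roots = [int(r) for r in np.flatnonzero(self.is_root)]
        root_set = set(roots)
        perfused_edges: set[frozenset] = set()
        for a in roots:
            paths = nx.single_source_shortest_path(gph, a)
            for b in root_set.intersection(paths):
                if b <= a:
                    continue
                path = paths[b]
                perfused_edges.update(
                    frozenset(e) for e in zip(path[:-1], path[1:])
                )
        self.perfused = [frozenset(s) in perfused_edges for s in self.segments]
        self.perfusion_dirty = False
        self._perfused_mask = None


def seed_boundary_sprouts(cfg: ScenarioConfig, p: ModelParameters) -> VascularNetwork:
    """Seed quiescent agents around the domain perimeter.

    The perimeter is walked clockwise from the origin and every
    ``sprout_seed_spacing``-th site receives one agent (corners visited
    once, so sites are never duplicated); each seed is the root of its
    own sprout.  Deterministic.
    """
    nr, nc = cfg.grid_nx, cfg.grid_ny
    spacing = p.sprout_seed_spacing
    if spacing > min(nr, nc):
        raise ValueError("sprout_seed_spacing exceeds the edge length")
    path: list[tuple[int, int]] = []
    path += [(0, j) for j in range(nc)]                       # top, L->R
    path += [(i, nc - 1) for i in range(1, nr)]               # right, T->B
    path += [(nr - 1, j) for j in range(nc - 2, -1, -1)]      # bottom, R->L
    path += [(i, 0) for i in range(nr - 2, 0, -1)]            # left, B->T
    net = VascularNetwork(nr, nc)
    for sid, site in enumerate(path[::spacing]):
        net.add_agent(site, role=ROLE_QUIESCENT, sprout_id=sid, is_root=True)
    return net


def notch_step_all(
    net: VascularNetwork,
    vegf_field: np.ndarray,
    p: ModelParameters,
    dt: float,
    oxygen_field: np.ndarray | None = None,
) -> None:
    """Synchronous Notch update of every agent (matches :func:`notch_step`)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if net.n_agents == 0:
        return
    nb = net._neighbor_ids()
    valid = nb >= 0
    d4 = np.where(valid, net.state[nb.clip(min=0), D4], 0.0)
    counts = valid.sum(axis=1)
    mean_d4 = np.where(counts > 0, d4.sum(axis=1) / np.maximum(counts, 1), 0.0)
    vegf = vegf_field[net.rows, net.cols]
    oxy = None if oxygen_field is None else oxygen_field[net.rows, net.cols]
    net.state[:] = _advance_states(net.state, mean_d4, vegf, p, dt, oxygen=oxy)


def select_tips(
    net: VascularNetwork, vegf_field: np.ndarray, p: ModelParameters
) -> VascularNetwork:
    """Promote local actin maxima above ``theta_tip`` to tips.

    An agent becomes a tip iff its actin is >= theta_tip and strictly
    greater than every lattice-neighbor agent's actin (ties broken toward
    the smaller agent id), so no two adjacent agents are ever both tips.
    Previous tips that no longer win revert to stalk.  A promoted agent
    that already carries vessel segments starts a new sprout (fresh
    sprout id): branch initiation is a sprouting event, and every sprout
    has at most one tip.
    """
    if net.n_agents == 0:
        return net
    act = net.state[:, ACT]
    nb = net._neighbor_ids()
    valid = nb >= 0
    nb_safe = nb.clip(min=0)
    nb_act = net.state[nb_safe, ACT]
    ids = np.arange(net.n_agents)[:, np.newaxis]
    beats = (act[:, np.newaxis] > nb_act) | (
        (act[:, np.newaxis] == nb_act) & (ids < nb_safe)
    )
    wins = (act >= p.theta_tip) & np.all(beats | ~valid, axis=1)
    was_tip = net.role == ROLE_TIP
    for idx in np.flatnonzero(wins & ~was_tip & (net.degree > 0)):
        net.sprout_id[idx] = net._next_sprout_id
        net._next_sprout_id += 1
    net.role[wins] = ROLE_TIP
    net.role[was_tip & ~wins] = ROLE_STALK
    return net


def grow_and_anastomose(
    net: VascularNetwork,
    vegf_field: np.ndarray,
    cfg: ScenarioConfig,
    p: ModelParameters,
    update_perfusion: bool = True,
) -> VascularNetwork:
    """One growth event: every tip advances one site up the VEGF field.

    Tips are processed in increasing agent-id order.  Each tip moves to
    its unoccupied lattice-neighbor site of maximal VEGF (ties resolved in
    N, E, S, W order); a stalk daughter fills the vacated site and a
    segment joins them.  The daughter is born Notch-activated (its active
    and effective Notch are equilibrated to the tip's Dll4, its VEGFR-2
    activity and actin reset), reflecting the asymmetry of tip/stalk
    division — a verbatim copy would compete symmetrically with its own
    tip and mutual inhibition would stall the sprout.  A tip arriving
    adjacent to an agent of a different sprout fuses with it
    (anastomosis): a segment is added, the tip retires to stalk, and
    perfusion flags are refreshed.  Tips with no free neighbor stall
    without error.
    """
    nr, nc = net.shape
    fused = False
    for tip in np.flatnonzero(net.role == ROLE_TIP):
        r, c = int(net.rows[tip]), int(net.cols[tip])
        best, best_g = None, -np.inf
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and net.site_index[rr, cc] == -1:
                gval = vegf_field[rr, cc]
                if gval > best_g:
                    best, best_g = (rr, cc), gval
        if best is None:
            continue  # stalled

        # vacate the old site, move the tip, leave a stalk daughter behind
        net.site_index[r, c] = -1
        net.rows[tip], net.cols[tip] = best
        net.site_index[best] = tip
        daughter = net.state[tip].copy()
        notch_level = (p.k_notch / p.delta_na) * daughter[D4]
        daughter[VA] = daughter[VE] = daughter[ACT] = 0.0
        daughter[NA] = daughter[NE] = notch_level
        stalk = net.add_agent(
            (r, c), role=ROLE_STALK, state=daughter,
            sprout_id=int(net.sprout_id[tip]),
        )
        # the daughter takes over the tip's previous connections and root role
        if net._degree[tip]:
            net.segments = [
                (stalk if i == tip else i, stalk if j == tip else j)
                for (i, j) in net.segments
            ]
            net._degree[stalk] = net._degree[tip]
            net._degree[tip] = 0
        if net.is_root[tip]:
            net.is_root[tip] = False
            net.is_root[stalk] = True
        net.add_segment(stalk, tip)

        # anastomosis: fuse with the smallest-id neighboring agent belonging
        # to a vessel tree not yet connected to this one
        others = [
            k for k in net.neighbors_of(tip)
            if k != stalk and not net.same_tree(tip, k)
        ]
        if others:
            partner = min(others)
            net.add_segment(tip, partner)
            net.role[tip] = ROLE_STALK
            fused = True
    if fused:
        if update_perfusion:
            net.update_perfusion()
        else:
            net.perfusion_dirty = True
    return net


def write_network(net: VascularNetwork, path_prefix: str) -> None:
    """Serialize a network as two delimited-text tables.

    ``<prefix>_agents.tsv``: id, row, col, role, sprout, root and the 8
    species; ``<prefix>_segments.tsv``: agent-id pairs with perfusion flag.
    """
    with open(path_prefix + "_agents.tsv", "w") as fh:
        fh.write("id\trow\tcol\trole\tsprout\troot\t" + "\t".join(SPECIES) + "\n")
        for i in range(net.n_agents):
            vals = "\t".join(f"{x:.10g}" for x in net.state[i])
            fh.write(
                f"{i}\t{net.rows[i]}\t{net.cols[i]}\t"
                f"{ROLE_NAMES[int(net.role[i])]}\t{net.sprout_id[i]}\t"
                f"{int(net.is_root[i])}\t{vals}\n"
            )
    with open(path_prefix + "_segments.tsv", "w") as fh:
        fh.write("agent_a\tagent_b\tperfused\n")
        for (i, j), perf in zip(net.segments, net.perfused):
            fh.write(f"{i}\t{j}\t{int(perf)}\n")
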