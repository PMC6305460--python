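"""Stochastic wiring and reduced-scale simulation of recurrent populations.

Implements the wiring scheme of the example cortical-column use case:
cylindrical population geometry with normally distributed soma depths and
redraw of protruding cells, Bernoulli pairwise connectivity without
autapses, multapse counts / conduction delays / synaptic conductances drawn
from capped normal distributions (support restriction by redraw, hard
floors delta_min and g_min), layer-specific synapse placement from the
overlap of presynaptic axon length and postsynaptic dendrite length per
layer, and extrinsic Poisson drive onto dendritic/apical compartments with
area-proportional placement.

``run_network`` couples passive multicompartment cells (one Crank-Nicolson
solve per population per time step, batched over cells) through an event
queue: somatic threshold crossings (theta_AP = -10 mV) schedule
bi-exponential conductance events on the targets after the drawn delay.
Extracellular potentials (via a probe kernel matrix) and per-population
current dipole moments are accumulated at every time step, so transmembrane
currents never need to be stored.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cable import PassiveParams
from .dipole import DipoleMoment
from .extracellular import ProbeSpec, kernel_matrix
from .morphology import SegmentTree

__all__ = [
    "PopulationSpec", "ConnectionRule", "NetworkResult", "two_population_demo",
    "place_somata", "draw_connectivity", "connections_from_probability",
    "probability_from_connections", "draw_multapses", "draw_delays",
    "draw_conductances", "layer_specificity", "place_synapses",
    "extrinsic_input", "run_network", "capped_normal",
]

THETA_AP = -10.0       # mV, action-potential detection threshold
DELAY_MIN = 0.3        # ms, default minimum conduction delay
COLUMN_RADIUS = 210.0  # um, lateral population radius
LAYER6_BOTTOM = -2082.0  # um


@dataclass
class PopulationSpec:
    """One neuron population: fixture morphology, size, geometry and drive.

    Soma depths are drawn from N(z_mean, z_sd) (um, negative below the
    surface), lateral positions uniformly within ``radius``.  ``n_ext``
    external synapses per cell fire as independent Poisson processes with
    rate ``nu_ext`` (Hz); their conductances are drawn from the capped
    normal N(ext_g_mean, ext_g_sd) H(g - ext_g_min).
    """

    name: str
    tree: SegmentTree
    N: int
    z_mean: float
    z_sd: float
    radius: float = COLUMN_RADIUS
    n_ext: int = 100
    nu_ext: float = 5.0
    ext_tau_r: float = 0.2
    ext_tau_d: float = 1.7
    ext_e_syn: float = 0.0
    ext_g_mean: float = 0.3
    ext_g_sd: float = 0.11
    ext_g_min: float = 0.0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("population size must be >= 1")
        if self.radius <= 0 or self.z_sd < 0:
            raise ValueError("require radius > 0 and z_sd >= 0")


@dataclass
class ConnectionRule:
    """Pairwise connection statistics from population X onto population Y."""

    C: float                       # pairwise connection probability
    nsyn_mean: float = 3.3         # multapse count mean
    nsyn_sd: float = 1.4
    delay_mean: float = 1.5       # ms
    delay_sd: float = 0.5
    delay_min: float = DELAY_MIN  # ms, hard floor
    g_mean: float = 0.3           # nS
    g_sd: float = 0.11
    g_min: float = 0.0            # nS, hard floor
    tau_r: float = 0.2            # ms
    tau_d: float = 1.7            # ms
    e_syn: float = 0.0            # mV
    L: np.ndarray = None          # layer specificity vector (sums to 1)
    layer_bounds: np.ndarray = None  # layer boundaries, descending depths (um)

    def __post_init__(self):
        if not 0.0 <= self.C <= 1.0:
            raise ValueError("connection probability must lie in [0, 1]")
        if self.delay_min <= 0:
            raise ValueError("delay floor must be positive")
        if self.L is not None:
            self.L = np.asarray(self.L, dtype=float)
            if self.layer_bounds is None:
                raise ValueError("layer specificity requires layer_bounds")
            self.layer_bounds = np.asarray(self.layer_bounds, dtype=float)
            if len(self.layer_bounds) != len(self.L) + 1:
                raise ValueError("need len(L) + 1 layer boundaries")
            if abs(self.L.sum() - 1.0) > 1e-9:
                raise ValueError("layer specificity must sum to 1")


def capped_normal(rng, mean, sd, size, floor=0.0, max_redraws=1000):
    """Normal draws with the support restricted to [floor, inf) by redraw.

    The Heaviside cap is a support restriction, not clipping: values below
    the floor are redrawn (up to ``max_redraws`` sweeps, then an error).
    """
    out = np.asarray(rng.normal(mean, sd, size=size), dtype=float)
    if sd == 0:
        if mean < floor:
            raise ValueError("degenerate distribution entirely below the floor")
        return out
    for _ in range(max_redraws):
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("capped normal: too many redraws (infeasible floor)")


def truncated_normal_mean(mean, sd, floor=0.0):
    """Mean of N(mean, sd) restricted to [floor, inf) (closed form)."""
    if sd == 0:
        return float(mean)
    a = (floor - mean) / sd
    return float(mean + sd * stats.norm.pdf(a) / stats.norm.sf(a))


# ---------------------------------------------------------------------------
# geometry

def _z_extent(tree: SegmentTree):
    z = np.concatenate([tree.start[:, 2], tree.end[:, 2]])
    return float(z.min()), float(z.max())


def place_somata(pop: PopulationSpec, layer_bounds=(0.0, LAYER6_BOTTOM),
                 seed=0, rng=None):
    """Draw soma positions and z-rotations for a population.

    Lateral placement is uniform in area within the population radius;
    depths come from N(z_mean, z_sd) and are redrawn whenever the morphology
    would protrude above the cortical surface (z = 0) or below the bottom
    boundary.  Each cell gets a uniform rotation angle about its vertical
    axis.  Returns (positions (N, 3), angles (N,)).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    z_top = float(max(layer_bounds))
    z_bot = float(min(layer_bounds))
    zmin_rel, zmax_rel = _z_extent(pop.tree)
    pos = np.empty((pop.N, 3))
    # uniform in area within the radius
    r = pop.radius * np.sqrt(rng.uniform(size=pop.N))
    ang = rng.uniform(0.0, 2.0 * np.pi, size=pop.N)
    pos[:, 0] = r * np.cos(ang)
    pos[:, 1] = r * np.sin(ang)
    for i in range(pop.N):
        for attempt in range(10**4):
            z = rng.normal(pop.z_mean, pop.z_sd)
            if z + zmax_rel <= z_top and z + zmin_rel >= z_bot:
                pos[i, 2] = z
                break
        else:
            raise RuntimeError(
                f"could not place population {pop.name!r}: 1e4 consecutive "
                "depth redraws rejected (infeasible depth window)")
    rotations = rng.uniform(0.0, 2.0 * np.pi, size=pop.N)
    return pos, rotations


def _rot_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _placed_coords(tree, position, rotation):
    """Segment start/mid/end of a cell rotated about z and translated."""
    R = _rot_z(rotation)
    return tuple(arr @ R.T + position for arr in (tree.start, tree.mid, tree.end))


# ---------------------------------------------------------------------------
# connectivity

def draw_connectivity(C, N_X, N_Y, same_population=False, seed=0, rng=None):
    """Boolean (N_X, N_Y) Bernoulli(C) connectivity matrix, no autapses."""
    if not 0.0 <= C <= 1.0:
        raise ValueError("C must lie in [0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    conn = rng.uniform(size=(N_X, N_Y)) < C
    if same_population:
        np.fill_diagonal(conn, False)
    return conn


def connections_from_probability(C, N_X, N_Y):
    """Expected connection count K from pairwise probability C.

    K = ln(1 - C) / ln(1 - 1/(N_X N_Y)); diverges for C = 1.
    """
    if not 0.0 <= C < 1.0:
        raise ValueError("C must lie in [0, 1)")
    if C == 0.0:
        return 0.0
    return float(np.log1p(-C) / np.log1p(-1.0 / (N_X * N_Y)))


def probability_from_connections(K, N_X, N_Y):
    """Inverse of :func:`connections_from_probability`:
    C = 1 - (1 - 1/(N_X N_Y))^K."""
    return float(-np.expm1(K * np.log1p(-1.0 / (N_X * N_Y))))


def draw_multapses(nsyn_mean, nsyn_sd, n_draws, seed=0, rng=None):
    """Synapse counts per connection: capped normal, rounded to integers."""
    if nsyn_mean < 0:
        raise ValueError("multapse mean must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    vals = capped_normal(rng, nsyn_mean, nsyn_sd, n_draws, floor=0.0)
    return np.round(vals).astype(int)


def draw_delays(delay_mean, delay_sd, delay_min, n_draws, seed=0, rng=None):
    """Conduction delays (ms) from N(mean, sd) H(delta - delta_min)."""
    if delay_min <= 0:
        raise ValueError("delay floor must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    return capped_normal(rng, delay_mean, delay_sd, n_draws, floor=delay_min)


def draw_conductances(g_mean, g_sd, g_min, n_draws, seed=0, rng=None):
    """Synaptic peak conductances (nS) from N(mean, sd) H(g - g_min)."""
    if g_min < 0:
        raise ValueError("conductance floor must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    return capped_normal(rng, g_mean, g_sd, n_draws, floor=g_min)


def layer_specificity(axon_length_per_layer, dendrite_length_per_layer):
    """Normalized per-layer product of axon and dendrite cable length.

    L^L = (Delta s_X^L * Delta s_Y^L) / sum_L (...); sums to one.
    """
    a = np.asarray(axon_length_per_layer, dtype=float)
    d = np.asarray(dendrite_length_per_layer, dtype=float)
    if a.shape != d.shape:
        raise ValueError("layer vectors must have equal length")
    if np.any(a < 0) or np.any(d < 0):
        raise ValueError("cable lengths must be nonnegative")
    prod = a * d
    total = prod.sum()
    if total <= 0:
        raise ValueError("no layer has overlapping axon and dendrite length")
    return prod / total


def _placement_weights(z_mid, areas, L, layer_bounds):
    """Per-segment synapse placement weights: area times the layer mixture
    of normal densities centered at each layer's mid-depth with SD
    Delta_L / 2, weighted by the layer specificity."""
    if L is None:
        return areas.copy()
    bounds = np.asarray(layer_bounds, dtype=float)
    density = np.zeros_like(z_mid)
    for li, w in enumerate(L):
        if w == 0:
            continue
        top, bot = bounds[li], bounds[li + 1]
        mu = 0.5 * (top + bot)
        sd = abs(top - bot) / 2.0
        density += w * stats.norm.pdf(z_mid, loc=mu, scale=sd)
    return areas * density


def place_synapses(tree: SegmentTree, L, layer_bounds, n_syn, seed=0,
                   rng=None, z_offset=0.0, labels=None):
    """Draw target segment indices for n_syn synapses (with replacement).

    The per-segment probability is proportional to membrane area times the
    layer-specificity mixture density evaluated at the segment depth
    (``z_offset`` shifts the cell to its placed depth).  ``labels``
    restricts the candidate compartments (e.g. ("dend", "apic")).
    """
    if n_syn < 0:
        raise ValueError("n_syn must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    z = tree.mid[:, 2] + z_offset
    w = _placement_weights(z, tree.area, L, layer_bounds)
    if labels is not None:
        w = np.where(np.isin(tree.label, list(labels)), w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("all synapse placement weights are zero")
    if n_syn == 0:
        return np.empty(0, dtype=int)
    return rng.choice(len(w), size=n_syn, p=w / total)


def extrinsic_input(tree: SegmentTree, n_ext, nu_ext, T, seed=0, rng=None,
                    z_offset=0.0):
    """External synapse sites and Poisson spike trains for one cell.

    Placement is area-proportional over dendritic and apical compartments;
    each of the n_ext synapses fires as an independent homogeneous Poisson
    process with rate nu_ext (Hz) over [0, T) ms.  Returns (segment indices,
    list of onset-time arrays).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if not np.isin(tree.label, ["dend", "apic"]).any():
        raise ValueError("cell has no dendritic or apical compartments")
    sites = place_synapses(tree, None, None, n_ext, rng=rng,
                           z_offset=z_offset, labels=("dend", "apic"))
    trains = []
    rate_per_ms = nu_ext / 1000.0
    for _ in range(n_ext):
        count = rng.poisson(rate_per_ms * T)
        trains.append(np.sort(rng.uniform(0.0, T, size=count)))
    return sites, trains


# ---------------------------------------------------------------------------
# network simulation

@dataclass
class NetworkResult:
    """Spikes and forward-modeled signals of a network simulation."""

    time: np.ndarray                       # (n_t,) ms
    spikes: dict                           # name -> (cell ids, times ms)
    lfp: dict = None                       # name/"total" -> (n_c, n_t) mV
    dipoles: dict = None                   # name/"total" -> DipoleMoment
    positions: dict = None                 # name -> (N, 3) um
    soma_v: dict = None                    # name -> (N, n_t) mV somatic V


class _PopState:
    """Per-population solver state for the batched Crank-Nicolson update."""

    def __init__(self, pop, params, dt, positions, rotations):
        tree = pop.tree
        self.pop = pop
        self.tree = tree
        self.n = tree.n_segments
        self.N = pop.N
        self.soma = tree.soma_index()
        self.C = params.c_m * tree.area * 1e-5        # nF
        g_leak = params.g_L * tree.area * 1e-2        # uS
        Lax = tree.axial_laplacian(rho_a=params.rho_a)
        self.Lax = Lax
        self.M0 = np.diag(g_leak) + Lax
        self.base_rhs = g_leak * params.E_L
        self.Cdt = self.C / dt
        self.v = np.full((pop.N, self.n), float(params.V_init))
        self.groups = {}     # (tau_r, tau_d, e_syn) -> index
        self.A = []          # list of (N, n) rise-state arrays
        self.B = []          # decay states
        self.decay = []      # (exp(-dt/tau_r), exp(-dt/tau_d), half-step pair)
        self.e_syn = []
        self.norm = []
        self.dt = dt
        mids = np.empty((pop.N, self.n, 3))
        for j in range(pop.N):
            _s, m, _e = _placed_coords(tree, positions[j], rotations[j])
            mids[j] = m
        self.mids = mids
        self.positions = positions
        self.rotations = rotations

    def group_index(self, tau_r, tau_d, e_syn):
        key = (float(tau_r), float(tau_d), float(e_syn))
        if key not in self.groups:
            self.groups[key] = len(self.A)
            self.A.append(np.zeros((self.N, self.n)))
            self.B.append(np.zeros((self.N, self.n)))
            t_peak = key[0] * key[1] / (key[1] - key[0]) * np.log(key[1] / key[0])
            norm = 1.0 / (np.exp(-t_peak / key[1]) - np.exp(-t_peak / key[0]))
            self.norm.append(norm)
            self.decay.append((np.exp(-self.dt / key[0]), np.exp(-self.dt / key[1]),
                               np.exp(-0.5 * self.dt / key[0]),
                               np.exp(-0.5 * self.dt / key[1])))
            self.e_syn.append(key[2])
        return self.groups[key]

    def conductances_half(self):
        """Total synaptic conductance (uS) and g*e product at the half step."""
        g = np.zeros((self.N, self.n))
        ge = np.zeros((self.N, self.n))
        for gi in range(len(self.A)):
            _dr, _dd, hr, hd = self.decay[gi]
            gk = (self.B[gi] * hd - self.A[gi] * hr) * self.norm[gi] * 1e-3
            g += gk
            ge += gk * self.e_syn[gi]
        return g, ge

    def step(self):
        """One Crank-Nicolson step; returns I_m (N, n) at the new time."""
        g, ge = self.conductances_half()
        A_mat = 0.5 * self.M0[None, :, :].repeat(self.N, axis=0)
        idx = np.arange(self.n)
        A_mat[:, idx, idx] += self.Cdt[None, :] + 0.5 * g
        rhs = (self.Cdt[None, :] * self.v
               - 0.5 * np.einsum("kl,nl->nk", self.M0, self.v)
               - 0.5 * g * self.v + self.base_rhs[None, :] + ge)
        self.v = np.linalg.solve(A_mat, rhs[:, :, None])[:, :, 0]
        # decay synapse states across the full step
        for gi in range(len(self.A)):
            dr, dd, _hr, _hd = self.decay[gi]
            self.A[gi] *= dr
            self.B[gi] *= dd
        return -np.einsum("kl,nl->nk", self.Lax, self.v)

    def imem(self):
        return -np.einsum("kl,nl->nk", self.Lax, self.v)


def run_network(populations, rules, params=None, probe: ProbeSpec = None,
                T=200.0, dt=0.0625, seed=0,
                layer_bounds=(0.0, LAYER6_BOTTOM), t_refractory=2.0,
                record_soma_v=False) -> NetworkResult:
    """Wire and simulate recurrently connected multicompartment populations.

    ``populations`` is a list of PopulationSpec; ``rules`` maps
    (post_name, pre_name) to a ConnectionRule.  Somatic crossings of
    theta_AP = -10 mV in a presynaptic cell schedule conductance events on
    its targets after the drawn per-synapse delay (which must exceed dt to
    be resolvable).  Per-population extracellular potentials (when a probe
    is given) and current dipole moments are accumulated every time step;
    their per-population decomposition sums exactly to the totals.
    """
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    params = params or PassiveParams()
    pops = {p.name: p for p in populations}
    if len(pops) != len(populations):
        raise ValueError("population names must be unique")
    ss = np.random.SeedSequence(seed)
    rng_place, rng_wire, rng_ext = [np.random.default_rng(s)
                                    for s in ss.spawn(3)]

    n_steps = int(round(T / dt))
    time = np.arange(n_steps + 1) * dt

    # --- placement and solver state
    states = {}
    for pop in populations:
        pos, rot = place_somata(pop, layer_bounds, rng=rng_place)
        pp = params[pop.name] if isinstance(params, dict) else params
        states[pop.name] = _PopState(pop, pp, dt, pos, rot)

    # --- probe kernels
    M_kernels = {}
    if probe is not None:
        for pop in populations:
            st = states[pop.name]
            rows = []
            for j in range(pop.N):
                s, m, e = _placed_coords(pop.tree, st.positions[j],
                                         st.rotations[j])
                shifted = SegmentTree(
                    start=s, mid=m, end=e, length=pop.tree.length,
                    diam=pop.tree.diam, area=pop.tree.area,
                    label=pop.tree.label, section_id=pop.tree.section_id,
                    parent=pop.tree.parent,
                    r_half_start=pop.tree.r_half_start,
                    r_half_end=pop.tree.r_half_end,
                    rho_a=pop.tree.rho_a, nodes=pop.tree.nodes,
                    sections=pop.tree.sections)
                rows.append(kernel_matrix(shifted, probe, seed=seed).M)
            M_kernels[pop.name] = np.concatenate(rows, axis=1)

    # --- recurrent wiring: outgoing synapse lists per presynaptic cell
    out_syn = {p.name: [[] for _ in range(p.N)] for p in populations}
    for (y_name, x_name), rule in rules.items():
        if y_name not in pops or x_name not in pops:
            raise ValueError(f"rule references unknown population {(y_name, x_name)}")
        X, Y = pops[x_name], pops[y_name]
        stY = states[y_name]
        conn = draw_connectivity(rule.C, X.N, Y.N,
                                 same_population=(x_name == y_name),
                                 rng=rng_wire)
        ii, jj = np.nonzero(conn)
        nsyn = draw_multapses(rule.nsyn_mean, rule.nsyn_sd, len(ii), rng=rng_wire)
        for (i, j, ns) in zip(ii, jj, nsyn):
            if ns == 0:
                continue
            delays = draw_delays(rule.delay_mean, rule.delay_sd,
                                 rule.delay_min, ns, rng=rng_wire)
            if np.any(delays < dt):
                raise ValueError(
                    "drawn delay below dt: events cannot be resolved")
            weights = draw_conductances(rule.g_mean, rule.g_sd, rule.g_min,
                                        ns, rng=rng_wire)
            segs = place_synapses(Y.tree, rule.L, rule.layer_bounds, int(ns),
                                  rng=rng_wire,
                                  z_offset=stY.positions[j, 2])
            gi = stY.group_index(rule.tau_r, rule.tau_d, rule.e_syn)
            for seg, d, w in zip(segs, delays, weights):
                out_syn[x_name][i].append((y_name, gi, int(j), int(seg),
                                           float(w), float(d)))

    # --- extrinsic Poisson input, pre-bucketed into time steps
    events = defaultdict(list)  # step index -> list of (pop, gi, cell, seg, amp)
    for pop in populations:
        st = states[pop.name]
        gi = st.group_index(pop.ext_tau_r, pop.ext_tau_d, pop.ext_e_syn)
        for j in range(pop.N):
            sites, trains = extrinsic_input(pop.tree, pop.n_ext, pop.nu_ext,
                                            T, rng=rng_ext,
                                            z_offset=st.positions[j, 2])
            if pop.n_ext == 0:
                continue
            weights = draw_conductances(pop.ext_g_mean, pop.ext_g_sd,
                                        pop.ext_g_min, pop.n_ext, rng=rng_ext)
            for seg, train, w in zip(sites, trains, weights):
                for t_on in train:
                    events[int(round(t_on / dt))].append(
                        (pop.name, gi, j, int(seg), float(w)))

    # --- allocate outputs
    lfp = None
    if probe is not None:
        lfp = {p.name: np.zeros((len(probe.positions), n_steps + 1))
               for p in populations}
    dip = {p.name: np.zeros((3, n_steps + 1)) for p in populations}
    spikes = {p.name: ([], []) for p in populations}
    soma_v = {p.name: np.zeros((p.N, n_steps + 1)) for p in populations} \
        if record_soma_v else None
    last_spike = {p.name: np.full(p.N, -np.inf) for p in populations}
    prev_soma = {p.name: states[p.name].v[:, states[p.name].soma].copy()
                 for p in populations}

    def record(k):
        for pop in populations:
            st = states[pop.name]
            im = st.imem()
            dip[pop.name][:, k] = np.einsum("nsk,ns->k", st.mids, im) * 1e-6
            if lfp is not None:
                lfp[pop.name][:, k] = M_kernels[pop.name] @ im.reshape(-1)
            if soma_v is not None:
                soma_v[pop.name][:, k] = st.v[:, st.soma]

    record(0)
    for k in range(n_steps):
        t_now = time[k]
        # deliver events scheduled for this step boundary
        for (pname, gi, j, seg, amp) in events.pop(k, ()):
            st = states[pname]
            st.A[gi][j, seg] += amp
            st.B[gi][j, seg] += amp
        for pop in populations:
            states[pop.name].step()
        # spike detection and event scheduling at the new time
        t_new = time[k + 1]
        for pop in populations:
            st = states[pop.name]
            vs = st.v[:, st.soma]
            crossed = np.flatnonzero(
                (vs >= THETA_AP) & (prev_soma[pop.name] < THETA_AP)
                & (t_new - last_spike[pop.name] >= t_refractory))
            prev_soma[pop.name] = vs.copy()
            for i in crossed:
                last_spike[pop.name][i] = t_new
                spikes[pop.name][0].append(int(i))
                spikes[pop.name][1].append(float(t_new))
                for (y_name, gi, j, seg, w, d) in out_syn[pop.name][i]:
                    events[int(round((t_new + d) / dt))].append(
                        (y_name, gi, j, seg, w))
        record(k + 1)

    # totals by linear superposition
    dip_out = {name: DipoleMoment(p) for name, p in dip.items()}
    dip_out["total"] = DipoleMoment(sum(p for p in dip.values()))
    lfp_out = None
    if lfp is not None:
        lfp_out = dict(lfp)
        lfp_out["total"] = sum(lfp.values())
    spk = {name: (np.asarray(ids, dtype=int), np.asarray(ts))
           for name, (ids, ts) in spikes.items()}
    return NetworkResult(
        time=time, spikes=spk, lfp=lfp_out, dipoles=dip_out,
        positions={p.name: states[p.name].positions for p in populations},
        soma_v=soma_v)


def two_population_demo(scale=0.1, T=200.0, dt=0.0625, seed=0, probe=None,
                        record_soma_v=False):
    """Reference excitatory/inhibitory two-population network, scaled down.

    The reference sizes are 2400 excitatory and 480 inhibitory cells;
    ``scale`` shrinks both (default 1/10).  Ball-and-stick cells receive
    strong extrinsic Poisson drive (passive membranes need substantial
    conductance to reach the -10 mV detection threshold), excitatory
    connections use fast AMPA-like kernels (tau 0.2/1.7 ms, reversal 0 mV)
    and inhibitory ones GABA_A-like kernels (0.2/8.3 ms, -80 mV); multapse,
    delay and conductance statistics follow the capped-normal scheme.
    """
    from .morphology import make_ball_and_stick

    tree = make_ball_and_stick(20.0, 400.0, 2.0, nseg=8)
    n_e = max(2, int(round(2400 * scale)))
    n_i = max(2, int(round(480 * scale)))
    pop_e = PopulationSpec("E", tree, N=n_e, z_mean=-1170.0, z_sd=50.0,
                           n_ext=150, nu_ext=120.0,
                           ext_g_mean=1.0, ext_g_sd=0.3)
    pop_i = PopulationSpec("I", tree, N=n_i, z_mean=-1170.0, z_sd=50.0,
                           n_ext=150, nu_ext=120.0,
                           ext_g_mean=1.0, ext_g_sd=0.3)
    rules = {
        ("E", "E"): ConnectionRule(C=0.05, nsyn_mean=3.3, nsyn_sd=1.4,
                                   delay_mean=1.5, delay_sd=0.5,
                                   g_mean=0.6, g_sd=0.2, e_syn=0.0),
        ("I", "E"): ConnectionRule(C=0.2, nsyn_mean=6.0, nsyn_sd=2.0,
                                   delay_mean=1.4, delay_sd=0.4,
                                   g_mean=1.0, g_sd=0.2, e_syn=0.0),
        ("E", "I"): ConnectionRule(C=0.2, nsyn_mean=12.0, nsyn_sd=4.0,
                                   delay_mean=1.0, delay_sd=0.3,
                                   g_mean=1.0, g_sd=0.2, e_syn=-80.0,
                                   tau_r=0.2, tau_d=8.3),
        ("I", "I"): ConnectionRule(C=0.1, nsyn_mean=6.0, nsyn_sd=2.0,
                                   delay_mean=1.0, delay_sd=0.3,
                                   g_mean=0.8, g_sd=0.2, e_syn=-80.0,
                                   tau_r=0.2, tau_d=8.3),
    }
    result = run_network([pop_e, pop_i], rules, probe=probe, T=T, dt=dt,
                         seed=seed, record_soma_v=record_soma_v)
    return result, (pop_e, pop_i), rules
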