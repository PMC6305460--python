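"""Passive multicompartment cable simulation.

Solves the branched compartmental cable system

    C_n dV_n/dt = -g_L,n (V_n - E_L) - [L V]_n - sum_k g_k(t) (V_n - e_k) + I_stim,n

with Crank-Nicolson time stepping (synaptic conductances evaluated at the
half step), where L is the axial conductance Laplacian of the segment tree.
The per-segment transmembrane current is defined as the net axial current
into each segment's node, I_m = -(L V); because L is a Laplacian this sum
vanishes over the whole cell at every time step by construction, which is
the discrete statement that current monopoles do not exist.

Units: mV, ms, nA, uS, nF; membrane parameters in uF/cm^2 and S/cm^2,
geometry in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import SegmentTree

__all__ = [
    "PassiveParams",
    "SynapseSpec",
    "StepCurrent",
    "SimulationResult",
    "two_exp_conductance",
    "detect_spikes",
    "simulate",
]

DEFAULT_DT = 0.0625  # ms -> 16 kHz sampling
DEFAULT_V_INIT = -77.0  # mV


@dataclass
class PassiveParams:
    """Passive membrane parameters.

    c_m: specific capacitance (uF/cm^2); g_L: leak conductance (S/cm^2);
    E_L: leak reversal (mV); rho_a: axial resistivity (ohm*cm); V_init:
    initial potential (mV).  Defaults give the classic 10 ms membrane time
    constant (c_m/g_L) and the initialization voltage -77 mV.
    """

    c_m: float = 1.0
    g_L: float = 1e-4
    E_L: float = -77.0
    rho_a: float = 150.0
    V_init: float = DEFAULT_V_INIT

    def __post_init__(self):
        vals = (self.c_m, self.g_L, self.E_L, self.rho_a, self.V_init)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite passive parameter")
        if self.c_m <= 0 or self.g_L < 0 or self.rho_a <= 0:
            raise ValueError("require c_m > 0, g_L >= 0, rho_a > 0")


@dataclass
class SynapseSpec:
    """Bi-exponential conductance synapse on one segment.

    The conductance transient g(t) = g_max*N*(exp(-t/tau_d) - exp(-t/tau_r))
    is normalized so its peak equals g_max (nS); one transient is triggered
    per onset time (ms) and transients sum linearly.
    """

    segment: int
    onsets: tuple = ()
    tau_r: float = 0.2
    tau_d: float = 1.7
    g_max: float = 1.0
    e_syn: float = 0.0

    def __post_init__(self):
        if not 0 < self.tau_r < self.tau_d:
            raise ValueError("require 0 < tau_r < tau_d")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        self.onsets = tuple(float(t) for t in np.atleast_1d(np.asarray(self.onsets, float)))


@dataclass
class StepCurrent:
    """Current clamp: `amplitude` nA into `segment` for t in [start, stop)."""

    segment: int
    amplitude: float
    start: float = 0.0
    stop: float = np.inf


@dataclass
class SimulationResult:
    """Membrane potentials (mV) and transmembrane currents (nA) over time."""

    time: np.ndarray   # (n_t,) ms
    v_m: np.ndarray    # (n_seg, n_t) mV
    i_m: np.ndarray    # (n_seg, n_t) nA, net outward transmembrane current
    tree: SegmentTree = None
    params: PassiveParams = None
    synapses: list = field(default_factory=list)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def two_exp_conductance(t, tau_r, tau_d, g_max=1.0):
    """Bi-exponential conductance kernel, peak-normalized to g_max.

    g(t) = g_max*N*(exp(-t/tau_d) - exp(-t/tau_r)) for t >= 0, zero before;
    the peak occurs at t_peak = tau_r*tau_d/(tau_d - tau_r)*ln(tau_d/tau_r).
    """
    if not tau_r < tau_d:
        raise ValueError("require tau_r < tau_d")
    if tau_r <= 0:
        raise ValueError("time constants must be positive")
    t = np.asarray(t, dtype=float)
    t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    norm = 1.0 / (np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r))
    out = np.where(t >= 0,
                   g_max * norm * (np.exp(-np.maximum(t, 0) / tau_d)
                                   - np.exp(-np.maximum(t, 0) / tau_r)),
                   0.0)
    return out


def detect_spikes(v, threshold=-10.0, t_refractory=2.0, dt=DEFAULT_DT, t0=0.0):
    """Times (ms) of upward threshold crossings separated by >= t_refractory.

    ``v`` is a uniformly sampled voltage trace; the default threshold is the
    action-potential detection level -10 mV.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return np.empty(0)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    times = t0 + up * dt
    out = []
    last = -np.inf
    for t in times:
        if t - last >= t_refractory:
            out.append(t)
            last = t
    return np.asarray(out)


def _stimulus_currents(stimuli, n_seg, t_half):
    """Injected current (nA) per segment at the half-step times."""
    i = np.zeros((n_seg, len(t_half)))
    for st in stimuli:
        mask = (t_half >= st.start) & (t_half < st.stop)
        i[st.segment, mask] += st.amplitude
    return i


def simulate(tree: SegmentTree, params: PassiveParams, synapses=(), stimuli=(),
             T=100.0, dt=DEFAULT_DT) -> SimulationResult:
    """Integrate the passive cable system and return V_m and I_m.

    Crank-Nicolson with the synaptic conductances evaluated implicitly at
    the half step; second-order accurate in dt and unconditionally stable.
    Raises if the solution leaves the physiological range (|V| > 1e3 mV),
    naming dt.
    """
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    n = tree.n_segments
    for syn in synapses:
        if not 0 <= syn.segment < n:
            raise ValueError(f"synapse targets segment {syn.segment} of {n}")
    for st in stimuli:
        if not 0 <= st.segment < n:
            raise ValueError(f"stimulus targets segment {st.segment} of {n}")

    n_t = int(round(T / dt)) + 1
    time = np.arange(n_t) * dt
    t_half = time[:-1] + dt / 2.0

    C = params.c_m * tree.area * 1e-5          # nF
    g_leak = params.g_L * tree.area * 1e-2     # uS
    L = tree.axial_laplacian(rho_a=params.rho_a)  # uS

    # synaptic conductance time courses at half steps, grouped per reversal
    g_half = np.zeros((n, len(t_half)))        # uS
    ge_half = np.zeros((n, len(t_half)))       # uS*mV (g * e_syn)
    for syn in synapses:
        g = np.zeros(len(t_half))
        for onset in syn.onsets:
            g += two_exp_conductance(t_half - onset, syn.tau_r, syn.tau_d,
                                     syn.g_max)
        g *= 1e-3  # nS -> uS
        g_half[syn.segment] += g
        ge_half[syn.segment] += g * syn.e_syn

    i_stim = _stimulus_currents(stimuli, n, t_half)

    v = np.full(n, float(params.V_init))
    V = np.empty((n, n_t))
    V[:, 0] = v
    M0 = np.diag(g_leak) + L                  # constant part of the operator
    Cdt = C / dt
    base_rhs = g_leak * params.E_L
    for k in range(n_t - 1):
        gs = g_half[:, k]
        M = M0 + np.diag(gs)
        A = np.diag(Cdt) + 0.5 * M
        b = (Cdt * v - 0.5 * (M @ v)
             + base_rhs + ge_half[:, k] + i_stim[:, k])
        v = np.linalg.solve(A, b)
        V[:, k + 1] = v
        if np.max(np.abs(v)) > 1e3:
            raise RuntimeError(
                f"cable solver unstable or diverging at t={time[k+1]:g} ms "
                f"(dt={dt:g} ms): |V| exceeded 1e3 mV")

    I_m = -(L @ V)
    return SimulationResult(time=time, v_m=V, i_m=I_m, tree=tree,
                            params=params, synapses=list(synapses))
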