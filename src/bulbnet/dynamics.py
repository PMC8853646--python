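"""Izhikevich cell dynamics, dendrodendritic synapses, OSN drive, Euler engine.

Each cell follows the two-variable Izhikevich model

    C dv/dt = k (v - v_r)(v - v_t) - u + I
      du/dt = a (b (v - v_r) - u),        v >= v_c  =>  v <- c, u <- u + d

integrated by forward Euler (default dt = 0.1 ms).  Mitral cells are tuned
for class II (resonator-like, discontinuous f-I onset) behaviour; granule
cells are integrators with b < 0, which admits a closed-form relation
between (b, k) and the cell's input resistance R and rheobase.

Synapses are reciprocal: an MC spike drives AMPA/NMDA gating on the GC
side of each of its synapses (and, through the kappa rule, a small GABA
increment on every MC sharing a GC with the spiker, standing in for
network-driven GC activity); a GC spike drives GABA gating on the MC side.
GABA current is attenuated by exp(-L/lambda) for a synapse a dendritic
distance L from the MC soma.  OSN input is a set of 100 Poisson synapses
per MC with sinusoidally modulated rate (sniffing at 6 Hz).

Units: um, ms, mV, pA, nS, pF, GOhm (so GOhm*pA = mV, nS*mV = pA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .netgen import Network

__all__ = [
    "IzhikevichParams",
    "MC_PARAMS",
    "GC_PARAMS",
    "ReceptorParams",
    "DD_RECEPTORS",
    "OSN_RECEPTORS",
    "izhikevich_step",
    "gc_excitability_from_bk",
    "bk_from_excitability",
    "sample_cell_params",
    "receptor_current",
    "advance_gating",
    "simulate_single_cell",
    "fi_curve",
    "OSNDrive",
    "make_osn_drive",
    "osn_rate",
    "Protocol",
    "SimulationResult",
    "run_simulation",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of one Izhikevich cell (units in field comments)."""

    C: float  # pF
    k: float  # nS/mV
    a: float  # 1/ms
    b: float  # nS
    c: float  # mV (reset)
    d: float  # pA (recovery jump)
    v_r: float  # mV
    v_t: float  # mV
    v_c: float  # mV (spike cutoff)


#: Mean mitral-cell parameters (class II excitability).
MC_PARAMS = IzhikevichParams(
    C=191.0, k=2.5, a=0.02, b=12.0, c=-70.0, d=13.0, v_r=-58.0, v_t=-49.0, v_c=30.0
)
#: Mean granule-cell parameters (integrator, b < 0).
GC_PARAMS = IzhikevichParams(
    C=48.0, k=0.067, a=0.01, b=-0.133, c=-75.0, d=2.0, v_r=-71.0, v_t=-39.0, v_c=25.0
)


@dataclass(frozen=True)
class ReceptorParams:
    """Conductances (nS), time constants (ms) and gating rates of one synapse class."""

    g_ampa: float
    g_nmda: float
    g_gaba: float = 0.0
    tau_ampa: float = 5.5
    tau_nmda_rise: float = 10.0
    tau_nmda_decay: float = 80.0
    tau_gaba: float = 18.0
    alpha: float = 0.1  # 1/ms, NMDA opening rate
    W: float = 0.5  # gating increment weight
    kappa: float = 0.006  # second-order GABA increment factor
    lambda_len: float = 675.0  # um, GABA dendritic attenuation constant
    E_e: float = 0.0  # mV
    E_i: float = -70.0  # mV
    mg: float = 1.0  # mM


#: Dendrodendritic MC-GC synapse parameters.
DD_RECEPTORS = ReceptorParams(g_ampa=0.73, g_nmda=0.84, g_gaba=0.13)
#: Olfactory-sensory-neuron input synapse parameters.
OSN_RECEPTORS = ReceptorParams(
    g_ampa=6.7,
    g_nmda=12.0,
    tau_ampa=14.3,
    tau_nmda_rise=13.0,
    tau_nmda_decay=70.0,
    alpha=0.03,
)


def izhikevich_step(
    v: float, u: float, p: IzhikevichParams, I: float, dt: float
) -> tuple[float, float, bool]:
    """One forward-Euler step; returns (v, u, spiked)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dv = (p.k * (v - p.v_r) * (v - p.v_t) - u + I) / p.C
    du = p.a * (p.b * (v - p.v_r) - u)
    v = v + dt * dv
    u = u + dt * du
    if not (math.isfinite(v) and math.isfinite(u)):
        raise FloatingPointError("non-finite cell state; integration failed")
    if v >= p.v_c:
        return p.c, u + p.d, True
    return v, u, False


def gc_excitability_from_bk(
    b: float, k: float, v_r: float, v_t: float
) -> tuple[float, float]:
    """Invert the (R, rheobase) -> (b, k) relations for integrator GCs.

    With D = b/k - (v_r - v_t):  rheobase = k D^2 / 4 and R = 1/(k D).
    Requires D > 0 (holds for b < 0 and v_r < v_t); returns (R in GOhm,
    rheobase in pA).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    D = b / k - (v_r - v_t)
    if D <= 0:
        raise ValueError("no excitability solution: b/k - (v_r - v_t) <= 0")
    rheobase = k * D * D / 4.0
    R = D / (4.0 * rheobase)
    return R, rheobase


def bk_from_excitability(
    R: float, rheobase: float, v_r: float, v_t: float
) -> tuple[float, float]:
    """Forward map (R, rheobase) -> (b, k)."""
    b = (v_r - v_t + 4.0 * R * rheobase) / (4.0 * R * R * rheobase)
    k = 1.0 / (4.0 * R * R * rheobase)
    return b, k


def sample_cell_params(
    kind: str,
    rng: np.random.Generator,
    rheobase_window: tuple[float, float] = (10.0, 70.0),
    resistance_window: tuple[float, float] = (0.25, 1.5),
    max_tries: int = 10_000,
) -> IzhikevichParams:
    """Draw heterogeneous cell parameters around the population means.

    Every parameter ~ Normal(mean, |mean|/10), except GC (b, k) which are
    jointly drawn at sd = 2|mean|/3 and resampled until b < 0 and the
    implied rheobase and input resistance fall in the physiological windows.
    """
    if kind == "MC":
        mean = MC_PARAMS
        vals = {
            f: rng.normal(getattr(mean, f), abs(getattr(mean, f)) / 10.0)
            for f in ("C", "k", "a", "b", "c", "d", "v_r", "v_t", "v_c")
        }
        return IzhikevichParams(**vals)
    if kind != "GC":
        raise ValueError("kind must be 'MC' or 'GC'")
    mean = GC_PARAMS
    # an extreme (v_r, v_t) draw can make the (b, k) windows unreachable;
    # in that case the whole parameter set is redrawn
    for _ in range(100):
        vals = {
            f: rng.normal(getattr(mean, f), abs(getattr(mean, f)) / 10.0)
            for f in ("C", "a", "c", "d", "v_r", "v_t", "v_c")
        }
        for _ in range(max_tries):
            b = rng.normal(mean.b, abs(mean.b) * 2.0 / 3.0)
            k = rng.normal(mean.k, abs(mean.k) * 2.0 / 3.0)
            if b >= 0 or k <= 0:
                continue
            try:
                R, rho = gc_excitability_from_bk(b, k, vals["v_r"], vals["v_t"])
            except ValueError:
                continue
            if rheobase_window[0] <= rho <= rheobase_window[1] and (
                resistance_window[0] <= R <= resistance_window[1]
            ):
                return IzhikevichParams(b=b, k=k, **vals)
    raise RuntimeError("GC (b, k) resampling cap exceeded; check windows")


def receptor_current(
    cls: str,
    s,
    V,
    params: ReceptorParams = DD_RECEPTORS,
    dendritic_distance: float = 0.0,
):
    """Receptor current (pA, positive = outward) for gating fraction s at voltage V."""
    s = np.asarray(s, dtype=float)
    V = np.asarray(V, dtype=float)
    if cls == "AMPA":
        out = s * params.g_ampa * (V - params.E_e)
    elif cls == "NMDA":
        block = 1.0 + params.mg * np.exp(-0.062 * V) / 3.57
        out = s * params.g_nmda * (V - params.E_e) / block
    elif cls == "GABA":
        att = math.exp(-dendritic_distance / params.lambda_len)
        out = s * params.g_gaba * (V - params.E_i) * att
    else:
        raise ValueError(f"unknown receptor class {cls!r}")
    return out if out.shape else float(out)


def advance_gating(
    s_ampa, s_gaba, s_nmda, n, dt: float, params: ReceptorParams = DD_RECEPTORS
):
    """Forward-Euler decay of the gating variables; returns updated copies."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s_ampa = s_ampa + dt * (-s_ampa / params.tau_ampa)
    s_gaba = s_gaba + dt * (-s_gaba / params.tau_gaba)
    s_nmda = s_nmda + dt * (
        -s_nmda / params.tau_nmda_decay + params.alpha * n * (1.0 - s_nmda)
    )
    n = n + dt * (-n / params.tau_nmda_rise)
    return s_ampa, s_gaba, s_nmda, n


def simulate_single_cell(
    p: IzhikevichParams,
    I: float,
    duration: float = 1000.0,
    dt: float = 0.1,
    padding: float = 100.0,
    record_trace: bool = False,
):
    """Isolated cell under DC current; returns spike count in the recorded window.

    ``padding`` ms run (and discarded) before the recorded ``duration``.
    With record_trace, also returns the voltage trace of the full run.
    """
    v, u = p.v_r, 0.0
    n_pad = int(round(padding / dt))
    n_rec = int(round(duration / dt))
    spikes = 0
    trace = np.empty(n_pad + n_rec) if record_trace else None
    for i in range(n_pad + n_rec):
        v, u, spiked = izhikevich_step(v, u, p, I, dt)
        if spiked and i >= n_pad:
            spikes += 1
        if record_trace:
            trace[i] = v
    return (spikes, trace) if record_trace else spikes


def fi_curve(
    p: IzhikevichParams, currents, duration: float = 1000.0, dt: float = 0.1
) -> np.ndarray:
    """Firing frequency (Hz) for each DC current level (1 s per level)."""
    rates = [
        simulate_single_cell(p, float(I), duration, dt) * 1000.0 / duration
        for I in currents
    ]
    return np.asarray(rates)


# ---------------------------------------------------------------------------
# OSN (olfactory sensory neuron) drive


@dataclass
class OSNDrive:
    """Per-MC sinusoidal Poisson-rate parameters for the OSN synapses."""

    r_max: np.ndarray  # Hz, per MC
    phase: np.ndarray  # rad, per MC
    f: float = 6.0  # Hz, sniff frequency
    n_synapses: int = 100
    odor_glomeruli: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def osn_rate(drive: OSNDrive, t_ms: float) -> np.ndarray:
    """Instantaneous Poisson rate r(t) per MC in Hz.

    r(t) = r_max/2 + (r_max/4) (sin(2 pi f t - phi) + 1), so r ranges over
    [r_max/2, r_max] with time-average 3 r_max / 4.
    """
    t_s = t_ms / 1000.0
    return drive.r_max / 2.0 + (drive.r_max / 4.0) * (
        np.sin(2.0 * math.pi * drive.f * t_s - drive.phase) + 1.0
    )


def make_osn_drive(
    net: Network,
    rng: np.random.Generator,
    odor_fraction: float = 0.2,
    odor_glomeruli=None,
    odor_rate_range: tuple[float, float] = (2.0, 3.0),
    background_rate_range: tuple[float, float] = (0.0, 0.25),
    f: float = 6.0,
) -> OSNDrive:
    """Assign per-glomerulus then per-MC rate and phase parameters.

    A fraction of glomeruli (or an explicit id set) receives odor rates
    x_g ~ U(2, 3) Hz; the rest get background x_g ~ U(0, 0.25) Hz.  Each
    sister MC draws r_max ~ N(x_g, x_g/10) and phase ~ N(p_g, pi/4).
    """
    n_glom = len(net.space.glomeruli)
    if odor_glomeruli is None:
        n_odor = int(round(odor_fraction * n_glom))
        odor_glomeruli = rng.choice(n_glom, size=n_odor, replace=False)
    odor_set = set(int(g) for g in np.asarray(odor_glomeruli).ravel())
    x_g = np.empty(n_glom)
    p_g = rng.uniform(0.0, 2.0 * math.pi, size=n_glom)
    for g in range(n_glom):
        lo, hi = odor_rate_range if g in odor_set else background_rate_range
        x_g[g] = rng.uniform(lo, hi)
    r_max = np.empty(net.n_mc)
    phase = np.empty(net.n_mc)
    for i, mc in enumerate(net.mitral_cells):
        g = mc.glomerulus
        r_max[i] = max(rng.normal(x_g[g], x_g[g] / 10.0), 0.0)
        phase[i] = rng.normal(p_g[g], math.pi / 4.0)
    return OSNDrive(
        r_max=r_max,
        phase=phase,
        f=f,
        odor_glomeruli=np.asarray(sorted(odor_set), dtype=int),
    )


# ---------------------------------------------------------------------------
# Network simulation


@dataclass
class Protocol:
    """Inputs and switches for one simulation run.

    ``mc_current``/``gc_current`` are constant per-cell arrays (pA) or
    callables t_ms -> array.  ``gaba_scale`` = 0 disables the GC network;
    ``gc_active_mask`` silences a subset of GCs entirely (tonic inhibition).
    """

    duration: float = 1000.0  # recorded window, ms
    padding: float = 100.0  # unrecorded settling time, ms
    mc_current: object = None
    gc_current: object = None
    osn: OSNDrive | None = None
    gaba_scale: float = 1.0
    gc_active_mask: np.ndarray | None = None
    kappa_enabled: bool = True
    # the kappa rule targets every MC sharing a GC with the spiker; the
    # spiker trivially shares its own GCs, so its synapses are included by
    # default - set False to exclude self-inhibition
    kappa_include_self: bool = True
    record_lfp: bool = False
    electrode: tuple[float, float, float] | None = None
    lfp_include_osn: bool = True
    receptors: ReceptorParams = DD_RECEPTORS
    osn_receptors: ReceptorParams = OSN_RECEPTORS


@dataclass
class SimulationResult:
    """Spike events and (optionally) the LFP trace of one run."""

    dt: float
    duration: float
    padding: float
    mc_spikes: list  # (cell_id, t_ms) with t relative to recording onset
    gc_spikes: list
    lfp: np.ndarray | None = None  # uV per recorded step

    def mc_spike_array(self) -> np.ndarray:
        return np.asarray(self.mc_spikes, dtype=float).reshape(-1, 2)

    def gc_spike_array(self) -> np.ndarray:
        return np.asarray(self.gc_spikes, dtype=float).reshape(-1, 2)


def _current_at(source, t: float, n: int) -> np.ndarray:
    if source is None:
        return np.zeros(n)
    if callable(source):
        return np.asarray(source(t), dtype=float)
    return np.asarray(source, dtype=float)


#: uV produced by 1 pA at 1 um for sigma = 1/300 1/(Ohm cm):
#: phi = I/(4 pi sigma r), converted to the project units.
_LFP_UV_PER_PA_UM = 1e-12 / (4.0 * math.pi * (1.0 / 300.0) * 1e-4) * 1e6


def run_simulation(
    net: Network,
    protocol: Protocol,
    rng: np.random.Generator,
    dt: float = 0.1,
    mc_params: list[IzhikevichParams] | None = None,
    gc_params: list[IzhikevichParams] | None = None,
) -> SimulationResult:
    """Forward-Euler network simulation.

    Per step: gather synaptic + injected + OSN currents, advance all gating,
    step all cells, then process spikes (post-update threshold; reset before
    the next step; spike time stamped at the step end).  Heterogeneous cell
    parameters may be passed in; otherwise they are drawn from ``rng``.
    """
    n_mc, n_gc = net.n_mc, net.n_gc
    rp = protocol.receptors
    orp = protocol.osn_receptors
    if mc_params is None:
        mc_params = [sample_cell_params("MC", rng) for _ in range(n_mc)]
    if gc_params is None:
        gc_params = [sample_cell_params("GC", rng) for _ in range(n_gc)]

    def pack(params):
        return {
            f: np.array([getattr(p, f) for p in params])
            for f in ("C", "k", "a", "b", "c", "d", "v_r", "v_t", "v_c")
        }

    P_mc, P_gc = pack(mc_params), pack(gc_params)
    v_mc = P_mc["v_r"].copy()
    u_mc = np.zeros(n_mc)
    v_gc = P_gc["v_r"].copy()
    u_gc = np.zeros(n_gc)

    # synapse arrays
    syn_mc = np.array([s.mc_id for s in net.synapses], dtype=int)
    syn_gc = np.array([s.gc_id for s in net.synapses], dtype=int)
    n_syn = len(net.synapses)
    att = np.exp(
        -np.array([s.dendritic_distance for s in net.synapses]) / rp.lambda_len
    )
    s_ampa = np.zeros(n_syn)
    s_nmda = np.zeros(n_syn)
    n_gate = np.zeros(n_syn)
    s_gaba = np.zeros(n_syn)

    active_gc = (
        np.ones(n_gc, dtype=bool)
        if protocol.gc_active_mask is None
        else np.asarray(protocol.gc_active_mask, dtype=bool)
    )
    syn_active = active_gc[syn_gc] if n_syn else np.zeros(0, dtype=bool)

    adj = net.adjacency().astype(np.int32)  # for the kappa rule

    # OSN synapses
    osn = protocol.osn
    if osn is not None:
        n_os = osn.n_synapses
        os_ampa = np.zeros((n_mc, n_os))
        os_nmda = np.zeros((n_mc, n_os))
        os_n = np.zeros((n_mc, n_os))

    # LFP weights
    record_lfp = protocol.record_lfp
    if record_lfp:
        if protocol.electrode is None:
            lay = net.space.layers
            electrode = (0.0, 0.0, lay.epl_floor + 0.5 * lay.epl_thickness)
        else:
            electrode = protocol.electrode
        ex, ey, ez = electrode
        if n_syn:
            locs = np.array([s.location for s in net.synapses])
            dists = np.sqrt(
                (locs[:, 0] - ex) ** 2 + (locs[:, 1] - ey) ** 2 + (locs[:, 2] - ez) ** 2
            )
            w_syn = _LFP_UV_PER_PA_UM / np.maximum(dists, 1.0)
        else:
            w_syn = np.zeros(0)
        mc_xy = np.array([mc.xy for mc in net.mitral_cells]).reshape(-1, 2)
        mc_z = np.array([mc.z for mc in net.mitral_cells])
        d_mc = np.sqrt(
            (mc_xy[:, 0] - ex) ** 2 + (mc_xy[:, 1] - ey) ** 2 + (mc_z - ez) ** 2
        )
        w_mc = _LFP_UV_PER_PA_UM / np.maximum(d_mc, 1.0)

    n_pad = int(round(protocol.padding / dt))
    n_rec = int(round(protocol.duration / dt))
    lfp = np.zeros(n_rec) if record_lfp else None
    mc_spikes: list[tuple[int, float]] = []
    gc_spikes: list[tuple[int, float]] = []

    W = rp.W
    kW = rp.kappa * W

    for step in range(n_pad + n_rec):
        t = (step + 1) * dt  # spike/report time at step end
        t_rec = t - protocol.padding

        # --- currents
        I_mc = _current_at(protocol.mc_current, t, n_mc).copy()
        I_gc = _current_at(protocol.gc_current, t, n_gc).copy()

        if n_syn:
            V_g = v_gc[syn_gc]
            V_m = v_mc[syn_mc]
            i_ampa = s_ampa * rp.g_ampa * (V_g - rp.E_e)
            block = 1.0 + rp.mg * np.exp(-0.062 * V_g) / 3.57
            i_nmda = s_nmda * rp.g_nmda * (V_g - rp.E_e) / block
            i_gaba = (
                protocol.gaba_scale * s_gaba * rp.g_gaba * (V_m - rp.E_i) * att
            )
            i_ampa = np.where(syn_active, i_ampa, 0.0)
            i_nmda = np.where(syn_active, i_nmda, 0.0)
            i_gaba = np.where(syn_active, i_gaba, 0.0)
            I_gc -= np.bincount(syn_gc, weights=i_ampa + i_nmda, minlength=n_gc)
            I_mc -= np.bincount(syn_mc, weights=i_gaba, minlength=n_mc)

        if osn is not None:
            Vm_col = v_mc[:, None]
            oi_ampa = os_ampa * orp.g_ampa * (Vm_col - orp.E_e)
            oblock = 1.0 + orp.mg * np.exp(-0.062 * Vm_col) / 3.57
            oi_nmda = os_nmda * orp.g_nmda * (Vm_col - orp.E_e) / oblock
            I_osn_mc = (oi_ampa + oi_nmda).sum(axis=1)
            I_mc -= I_osn_mc

        # --- LFP sample (currents of this step)
        if record_lfp and step >= n_pad:
            phi = 0.0
            if n_syn:
                phi += float(np.dot(w_syn, i_ampa + i_nmda + i_gaba))
            if osn is not None and protocol.lfp_include_osn:
                phi += float(np.dot(w_mc, I_osn_mc))
            lfp[step - n_pad] = phi

        # --- advance gating (decay / NMDA kinetics)
        if n_syn:
            s_ampa += dt * (-s_ampa / rp.tau_ampa)
            s_gaba += dt * (-s_gaba / rp.tau_gaba)
            s_nmda += dt * (
                -s_nmda / rp.tau_nmda_decay + rp.alpha * n_gate * (1.0 - s_nmda)
            )
            n_gate += dt * (-n_gate / rp.tau_nmda_rise)
        if osn is not None:
            os_ampa += dt * (-os_ampa / orp.tau_ampa)
            os_nmda += dt * (
                -os_nmda / orp.tau_nmda_decay + orp.alpha * os_n * (1.0 - os_nmda)
            )
            os_n += dt * (-os_n / orp.tau_nmda_rise)
            # Poisson OSN events (rate in Hz, dt in ms)
            rates = osn_rate(osn, t)
            p_ev = np.clip(rates * dt * 1e-3, 0.0, 1.0)
            events = rng.random((n_mc, osn.n_synapses)) < p_ev[:, None]
            if events.any():
                os_ampa = np.where(
                    events, os_ampa + orp.W * (1.0 - os_ampa), os_ampa
                )
                os_n = np.where(events, os_n + orp.W * (1.0 - os_n), os_n)

        # --- step cells (both derivatives evaluated at the pre-step state)
        dv_mc = (
            P_mc["k"] * (v_mc - P_mc["v_r"]) * (v_mc - P_mc["v_t"]) - u_mc + I_mc
        ) / P_mc["C"]
        du_mc = P_mc["a"] * (P_mc["b"] * (v_mc - P_mc["v_r"]) - u_mc)
        v_mc += dt * dv_mc
        u_mc += dt * du_mc
        dv_gc = (
            P_gc["k"] * (v_gc - P_gc["v_r"]) * (v_gc - P_gc["v_t"]) - u_gc + I_gc
        ) / P_gc["C"]
        du_gc = P_gc["a"] * (P_gc["b"] * (v_gc - P_gc["v_r"]) - u_gc)
        v_gc += dt * dv_gc
        u_gc += dt * du_gc
        if not (np.all(np.isfinite(v_mc)) and np.all(np.isfinite(v_gc))):
            raise FloatingPointError(f"non-finite membrane state at t={t} ms")

        spk_mc = v_mc >= P_mc["v_c"]
        crossed_gc = v_gc >= P_gc["v_c"]
        spk_gc = crossed_gc & active_gc  # silenced GCs never emit spikes
        v_mc = np.where(spk_mc, P_mc["c"], v_mc)
        u_mc = np.where(spk_mc, u_mc + P_mc["d"], u_mc)
        v_gc = np.where(crossed_gc, P_gc["c"], v_gc)
        u_gc = np.where(crossed_gc, u_gc + P_gc["d"], u_gc)

        # --- spike-triggered gating updates
        if spk_mc.any() and n_syn:
            hit = spk_mc[syn_mc]
            s_ampa = np.where(hit, s_ampa + W * (1.0 - s_ampa), s_ampa)
            n_gate = np.where(hit, n_gate + W * (1.0 - n_gate), n_gate)
            if protocol.kappa_enabled:
                # each synapse of GC g receives one kappa*W increment per
                # spiking MC connected to g
                cnt_gc = np.asarray(
                    spk_mc.astype(np.int32) @ adj
                ).ravel()
                cnt_syn = cnt_gc[syn_gc]
                if not protocol.kappa_include_self:
                    cnt_syn = cnt_syn - hit.astype(np.int32)
                mask = cnt_syn > 0
                if mask.any():
                    s_gaba = np.where(
                        mask,
                        1.0 - (1.0 - s_gaba) * (1.0 - kW) ** cnt_syn,
                        s_gaba,
                    )
        if spk_gc.any() and n_syn:
            hit = spk_gc[syn_gc]
            s_gaba = np.where(hit, s_gaba + W * (1.0 - s_gaba), s_gaba)

        if step >= n_pad:
            for i in np.nonzero(spk_mc)[0]:
                mc_spikes.append((int(i), t_rec))
            for i in np.nonzero(spk_gc)[0]:
                gc_spikes.append((int(i), t_rec))

    return SimulationResult(
        dt=dt,
        duration=protocol.duration,
        padding=protocol.padding,
        mc_spikes=mc_spikes,
        gc_spikes=gc_spikes,
        lfp=lfp,
    )
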