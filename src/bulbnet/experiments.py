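"""The five network protocols: lateral inhibition, odor decorrelation,
cortical feedback to GCs and to MCs, and granule-cell neurogenesis.

Each protocol is a plain function over a generated :class:`~bulbnet.netgen.Network`
taking an explicit ``numpy.random.Generator``, so runs are reproducible
bit-for-bit given (network, seed, config).  Durations, pair counts and
window grids are parameters; their defaults follow the standard protocol
definitions, and the miniature values used in the test-suite simply shrink
them.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .analysis import (
    correlation_timecourse,
    fit_stretched_exp,
    summary_correlation,
    windowed_rates,
)
from .dynamics import (
    Protocol,
    run_simulation,
    sample_cell_params,
)
from .netgen import Network, Synapse, wire_granule_cell
from .placement import PlacementConfig, place_granule_cell

__all__ = [
    "OdorPanel",
    "make_odor_panel",
    "odor_current_fn",
    "subnetwork",
    "exp_lateral_inhibition",
    "exp_decorrelation",
    "exp_gc_feedback",
    "exp_mc_feedback",
    "NeurogenesisConfig",
    "exp_neurogenesis",
]

SNIFF_HZ = 6.0
SNIFF_MS = 1000.0 / SNIFF_HZ


# ---------------------------------------------------------------------------
# Odor panels (sniff-modulated sinusoidal input currents)


@dataclass
class OdorPanel:
    """A set of odors over the glomerular map with per-MC input currents.

    Odor-receiving glomeruli keep one strength/phase draw shared across all
    odors that target them (so overlapping glomeruli receive identical
    input); background draws are fresh per odor.  ``mc_I0``/``mc_phase``
    have shape (n_odors, n_mc).
    """

    odor_glomeruli: list[np.ndarray]
    mc_I0: np.ndarray
    mc_phase: np.ndarray
    f: float = SNIFF_HZ

    @property
    def n_odors(self) -> int:
        return len(self.odor_glomeruli)

    def overlap(self, i: int, j: int) -> int:
        return len(
            set(self.odor_glomeruli[i].tolist())
            & set(self.odor_glomeruli[j].tolist())
        )


def make_odor_panel(
    net: Network,
    rng: np.random.Generator,
    odor_glomeruli: list[np.ndarray],
    odor_strength_range: tuple[float, float] = (400.0, 600.0),
    background_strength_range: tuple[float, float] = (0.0, 150.0),
    f: float = SNIFF_HZ,
) -> OdorPanel:
    """Draw glomerulus strengths/phases and per-MC currents for each odor."""
    n_glom = len(net.space.glomeruli)
    gloms = [mc.glomerulus for mc in net.mitral_cells]
    # one shared odor-condition draw per glomerulus
    odor_I = rng.uniform(*odor_strength_range, size=n_glom)
    odor_phase = rng.uniform(0.0, 2.0 * math.pi, size=n_glom)
    # shared per-MC deviations for the odor condition, so overlapping
    # glomeruli drive identical currents in every odor that targets them
    mc_I0_odor = np.array(
        [max(rng.normal(odor_I[g], odor_I[g] / 5.0), 0.0) for g in gloms]
    )
    mc_phase_odor = np.array(
        [rng.normal(odor_phase[g], math.pi / 4.0) for g in gloms]
    )
    I0 = np.zeros((len(odor_glomeruli), net.n_mc))
    phase = np.zeros_like(I0)
    for oi, glset in enumerate(odor_glomeruli):
        target = np.zeros(n_glom, dtype=bool)
        target[np.asarray(glset, dtype=int)] = True
        bg_I = rng.uniform(*background_strength_range, size=n_glom)
        bg_phase = rng.uniform(0.0, 2.0 * math.pi, size=n_glom)
        for mi, g in enumerate(gloms):
            if target[g]:
                I0[oi, mi] = mc_I0_odor[mi]
                phase[oi, mi] = mc_phase_odor[mi]
            else:
                I0[oi, mi] = max(rng.normal(bg_I[g], bg_I[g] / 5.0 + 1e-12), 0.0)
                phase[oi, mi] = rng.normal(bg_phase[g], math.pi / 4.0)
    return OdorPanel(
        odor_glomeruli=[np.asarray(g, dtype=int) for g in odor_glomeruli],
        mc_I0=I0,
        mc_phase=phase,
        f=f,
    )


def sliding_odor_glomeruli(
    n_glom: int, n_odors: int = 6, per_odor: int = 30, stride: int = 5
) -> list[np.ndarray]:
    """Odor i targets glomeruli [i*stride, i*stride + per_odor) (mod n_glom)."""
    return [
        (np.arange(per_odor) + i * stride) % n_glom for i in range(n_odors)
    ]


def odor_current_fn(panel: OdorPanel, odor: int):
    """Per-MC current callable t_ms -> pA: I0/2 + I0/4 (sin(2 pi f t - phi) + 1)."""
    I0 = panel.mc_I0[odor]
    phi = panel.mc_phase[odor]
    f = panel.f

    def fn(t_ms: float) -> np.ndarray:
        ph = 2.0 * math.pi * f * (t_ms / 1000.0) - phi
        return I0 / 2.0 + I0 / 4.0 * (np.sin(ph) + 1.0)

    return fn


# ---------------------------------------------------------------------------
# Subnetwork extraction (exact for the dynamics of the retained MCs)


def subnetwork(net: Network, mc_ids: list[int]) -> tuple[Network, np.ndarray]:
    """Network restricted to ``mc_ids`` plus every GC connected to them.

    The inhibitory input to the retained MCs only depends on these GCs (and
    on spikes of the retained MCs themselves), so simulating the subnetwork
    reproduces their dynamics exactly when all other MCs are silent.
    Returns (subnet, original gc ids in subnet order).
    """
    keep_mc = {int(m): i for i, m in enumerate(mc_ids)}
    gc_ids = sorted(
        {s.gc_id for s in net.synapses if s.mc_id in keep_mc}
    )
    keep_gc = {g: i for i, g in enumerate(gc_ids)}
    mcs = []
    for old, new in keep_mc.items():
        mc = copy.copy(net.mitral_cells[old])
        mc.id = new
        mcs.append(mc)
    gcs = []
    for old in gc_ids:
        gc = copy.copy(net.granule_cells[old])
        gc.id = keep_gc[old]
        gcs.append(gc)
    syns = [
        Synapse(
            mc_id=keep_mc[s.mc_id],
            gc_id=keep_gc[s.gc_id],
            location=s.location,
            dendritic_distance=s.dendritic_distance,
        )
        for s in net.synapses
        if s.mc_id in keep_mc and s.gc_id in keep_gc
    ]
    sub = Network(
        space=net.space, mitral_cells=mcs, granule_cells=gcs, synapses=syns
    )
    return sub, np.asarray(gc_ids, dtype=int)


# ---------------------------------------------------------------------------
# Lateral inhibition


def select_mc_pairs(
    net: Network,
    rng: np.random.Generator,
    n_pairs: int,
    degree_tol: float = 75.0,
    dz_tol: float = 5.0,
    max_tries: int = 200_000,
) -> list[tuple[int, int]]:
    """MC pairs with near-average GC degree and nearly equal disk heights."""
    deg = net.mc_degrees()
    mean_deg = deg.mean()
    eligible = np.nonzero(np.abs(deg - mean_deg) <= degree_tol)[0]
    if len(eligible) < 2:
        raise ValueError(
            f"too few MCs within {degree_tol} of the mean degree ({mean_deg:.1f})"
        )
    z = np.array([mc.z for mc in net.mitral_cells])
    pairs: list[tuple[int, int]] = []
    seen = set()
    for _ in range(max_tries):
        if len(pairs) >= n_pairs:
            break
        a, b = rng.choice(eligible, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in seen or abs(z[a] - z[b]) > dz_tol:
            continue
        seen.add(key)
        pairs.append((int(a), int(b)))
    if not pairs:
        raise ValueError("no qualifying MC pairs found (z tolerance too strict?)")
    return pairs


def exp_lateral_inhibition(
    net: Network,
    rng: np.random.Generator,
    n_pairs: int = 100,
    current_a: float = 700.0,
    current_b: float = 750.0,
    duration: float = 1000.0,
    padding: float = 100.0,
    dt: float = 0.1,
    degree_tol: float = 75.0,
    dz_tol: float = 5.0,
    bin_width: float = 100.0,
    n_bins: int = 12,
    fit: bool = True,
) -> dict:
    """Paired-stimulation lateral-inhibition protocol.

    For each qualifying pair (A, B): condition (a) drives A alone with
    ``current_a`` pA DC; condition (b) adds ``current_b`` pA to B.  The
    drop in A's firing rate (a) - (b) is binned against pair distance and,
    optionally, fit with a stretched exponential, as is the shared-GC count.
    """
    pairs = select_mc_pairs(net, rng, n_pairs, degree_tol, dz_tol)
    adj = net.adjacency()
    rows = []
    for a, b in pairs:
        sub, _ = subnetwork(net, [a, b])
        seed = int(rng.integers(2**31 - 1))
        mc_params = [
            sample_cell_params("MC", np.random.default_rng(seed + 1)),
            sample_cell_params("MC", np.random.default_rng(seed + 2)),
        ]
        gc_rng = np.random.default_rng(seed + 3)
        gc_params = [sample_cell_params("GC", gc_rng) for _ in range(sub.n_gc)]
        res_a = run_simulation(
            sub,
            Protocol(
                duration=duration,
                padding=padding,
                mc_current=np.array([current_a, 0.0]),
            ),
            np.random.default_rng(seed + 4),
            dt=dt,
            mc_params=mc_params,
            gc_params=gc_params,
        )
        res_b = run_simulation(
            sub,
            Protocol(
                duration=duration,
                padding=padding,
                mc_current=np.array([current_a, current_b]),
            ),
            np.random.default_rng(seed + 4),
            dt=dt,
            mc_params=mc_params,
            gc_params=gc_params,
        )
        rate = lambda res: sum(1 for i, _ in res.mc_spikes if i == 0) * (
            1000.0 / duration
        )
        shared = adj.getrow(a).multiply(adj.getrow(b)).nnz
        dist = net.space.xy_distance(
            net.mitral_cells[a].xy, net.mitral_cells[b].xy
        )
        rows.append(
            {
                "mc_a": a,
                "mc_b": b,
                "distance": dist,
                "shared_gcs": shared,
                "rate_alone": rate(res_a),
                "rate_paired": rate(res_b),
                "delta_rate": rate(res_a) - rate(res_b),
            }
        )
    out: dict = {"pairs": rows}
    dists = np.array([r["distance"] for r in rows])
    deltas = np.array([r["delta_rate"] for r in rows])
    shared = np.array([r["shared_gcs"] for r in rows], dtype=float)
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    centers = edges[:-1] + bin_width / 2.0
    mean_delta = np.full(n_bins, np.nan)
    mean_shared = np.full(n_bins, np.nan)
    for i in range(n_bins):
        m = (dists >= edges[i]) & (dists < edges[i + 1])
        if m.any():
            mean_delta[i] = deltas[m].mean()
            mean_shared[i] = shared[m].mean()
    out.update(
        bin_centers=centers, mean_delta_rate=mean_delta, mean_shared_gcs=mean_shared
    )
    if fit:
        try:
            out["fit_shared"] = fit_stretched_exp(centers, mean_shared)
            out["fit_delta"] = fit_stretched_exp(centers, mean_delta)
        except (ValueError, RuntimeError) as err:
            out["fit_error"] = str(err)
    return out


# ---------------------------------------------------------------------------
# Odor decorrelation


def exp_decorrelation(
    net: Network,
    rng: np.random.Generator,
    panel: OdorPanel | None = None,
    windows_ms: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    n_sniffs: int = 6,
    dt: float = 0.1,
    padding: float = 0.0,
) -> dict:
    """Correlation of MC responses to odor pairs, with and without GCs.

    The GC-disabled condition zeroes the GABA conductance; everything else
    (network, cell parameters, input currents) is held identical.  The
    decorrelation attributed to the GC network is corr(no GC) - corr(GC),
    summarised per odor pair as the window-mean after the first sniff.
    """
    if panel is None:
        glsets = sliding_odor_glomeruli(len(net.space.glomeruli))
        panel = make_odor_panel(net, rng, glsets)
    duration = n_sniffs * SNIFF_MS
    seed = int(rng.integers(2**31 - 1))
    mc_params = [
        sample_cell_params("MC", np.random.default_rng(seed + i))
        for i in range(net.n_mc)
    ]
    gc_rng = np.random.default_rng(seed - 1)
    gc_params = [sample_cell_params("GC", gc_rng) for _ in range(net.n_gc)]
    spikes = {}
    for gaba, label in ((1.0, "gc"), (0.0, "nogc")):
        for oi in range(panel.n_odors):
            proto = Protocol(
                duration=duration,
                padding=padding,
                mc_current=odor_current_fn(panel, oi),
                gaba_scale=gaba,
            )
            res = run_simulation(
                net,
                proto,
                np.random.default_rng(seed + 1000 + oi),
                dt=dt,
                mc_params=mc_params,
                gc_params=gc_params,
            )
            spikes[(label, oi)] = res.mc_spikes
    results = {w: {"gc": [], "nogc": [], "pairs": []} for w in windows_ms}
    for w in windows_ms:
        rates = {
            key: windowed_rates(sp, net.n_mc, duration, w)
            for key, sp in spikes.items()
        }
        for i in range(panel.n_odors):
            for j in range(i + 1, panel.n_odors):
                for label in ("gc", "nogc"):
                    c = correlation_timecourse(
                        rates[(label, i)], rates[(label, j)]
                    )
                    s = summary_correlation(c, w, 0.5, duration)
                    results[w][label].append(s)
                results[w]["pairs"].append((i, j))
    decorr = {
        w: float(
            np.nanmean(
                np.asarray(results[w]["nogc"]) - np.asarray(results[w]["gc"])
            )
        )
        for w in windows_ms
    }
    return {"windows_ms": windows_ms, "by_window": results, "decorrelation": decorr}


# ---------------------------------------------------------------------------
# Cortical feedback to GCs


def exp_gc_feedback(
    net: Network,
    alt_net: Network,
    rng: np.random.Generator,
    levels: tuple[float, ...] = (0.001, 0.01, 0.05, 0.10, 0.15, 0.20),
    feedback_pa: float = 50.0,
    n_odor_glomeruli: int = 35,
    n_sniffs: int = 2,
    window: float = 10.0,
    dt: float = 0.1,
) -> dict:
    """Same-network vs cross-network correlation of feedback-driven MC rate changes.

    ``alt_net`` must share the MC arrangement of ``net`` but carry an
    independently generated GC population.  For each feedback level
    (fraction of all GCs, 50 pA DC each) three trials run: two disjoint GC
    sets in ``net`` and one set in ``alt_net``; per 10 ms window the Pearson
    correlation between odor-receiving-MC rate-change vectors is averaged
    over the second sniff onward.
    """
    n_glom = len(net.space.glomeruli)
    odor_gloms = rng.choice(n_glom, size=min(n_odor_glomeruli, n_glom), replace=False)
    panel = make_odor_panel(net, rng, [odor_gloms])
    duration = n_sniffs * SNIFF_MS
    odor_set = set(int(g) for g in odor_gloms)
    odor_mcs = np.array(
        [i for i, mc in enumerate(net.mitral_cells) if mc.glomerulus in odor_set]
    )
    seed = int(rng.integers(2**31 - 1))

    def run(network, gc_set, run_seed):
        gc_current = np.zeros(network.n_gc)
        if gc_set is not None and len(gc_set):
            gc_current[gc_set] = feedback_pa
        proto = Protocol(
            duration=duration,
            padding=0.0,
            mc_current=odor_current_fn(panel, 0),
            gc_current=gc_current,
        )
        res = run_simulation(
            network, proto, np.random.default_rng(run_seed), dt=dt
        )
        return windowed_rates(res.mc_spikes, network.n_mc, duration, window)[odor_mcs]

    out = {"levels": levels, "same_network": [], "cross_network": []}
    for li, level in enumerate(levels):
        n_target = int(round(level * net.n_gc))
        if 2 * n_target > net.n_gc:
            raise ValueError(
                f"level {level} needs {2*n_target} disjoint GCs, only {net.n_gc}"
            )
        if n_target == 0:
            out["same_network"].append(float("nan"))
            out["cross_network"].append(float("nan"))
            continue
        perm = rng.permutation(net.n_gc)
        set1, set2 = perm[:n_target], perm[n_target : 2 * n_target]
        set3 = rng.permutation(alt_net.n_gc)[:n_target]
        base = run(net, None, seed + 10 * li)
        d1 = run(net, set1, seed + 10 * li) - base
        d2 = run(net, set2, seed + 10 * li) - base
        base3 = run(alt_net, None, seed + 10 * li + 1)
        d3 = run(alt_net, set3, seed + 10 * li + 1) - base3
        c_same = correlation_timecourse(d1, d2)
        c_cross = correlation_timecourse(d1, d3)
        out["same_network"].append(
            summary_correlation(c_same, window, 0.5, duration)
        )
        out["cross_network"].append(
            summary_correlation(c_cross, window, 0.5, duration)
        )
    return out


# ---------------------------------------------------------------------------
# Cortical feedback to MCs


def exp_mc_feedback(
    net: Network,
    rng: np.random.Generator,
    fraction: float = 0.2,
    n_trials: int = 5,
    feedback_mean: float = 200.0,
    feedback_sd: float = 20.0,
    n_odor_glomeruli: int = 35,
    n_sniffs: int = 2,
    dt: float = 0.1,
) -> list[dict]:
    """Direct excitatory feedback to a random 20% of MCs during odor input.

    Returns one record per targeted MC per trial: its feedback-driven rate
    change, GC degree and odor-receiving status.
    """
    deg = net.mc_degrees()
    duration = n_sniffs * SNIFF_MS
    rows = []
    n_glom = len(net.space.glomeruli)
    for trial in range(n_trials):
        odor_gloms = rng.choice(
            n_glom, size=min(n_odor_glomeruli, n_glom), replace=False
        )
        panel = make_odor_panel(net, rng, [odor_gloms])
        odor_set = set(int(g) for g in odor_gloms)
        targeted = rng.choice(
            net.n_mc, size=max(int(round(fraction * net.n_mc)), 1), replace=False
        )
        fb = np.zeros(net.n_mc)
        fb[targeted] = np.maximum(
            rng.normal(feedback_mean, feedback_sd, size=len(targeted)), 0.0
        )
        seed = int(rng.integers(2**31 - 1))
        mc_params = [
            sample_cell_params("MC", np.random.default_rng(seed + i))
            for i in range(net.n_mc)
        ]
        gc_rng = np.random.default_rng(seed - 1)
        gc_params = [sample_cell_params("GC", gc_rng) for _ in range(net.n_gc)]
        odor_fn = odor_current_fn(panel, 0)

        def run(extra):
            proto = Protocol(
                duration=duration,
                padding=0.0,
                mc_current=(lambda t: odor_fn(t) + extra),
            )
            res = run_simulation(
                net,
                proto,
                np.random.default_rng(seed + 7),
                dt=dt,
                mc_params=mc_params,
                gc_params=gc_params,
            )
            counts = np.zeros(net.n_mc)
            for i, _ in res.mc_spikes:
                counts[i] += 1
            return counts * 1000.0 / duration

        base = run(np.zeros(net.n_mc))
        with_fb = run(fb)
        for i in targeted:
            rows.append(
                {
                    "trial": trial,
                    "mc_id": int(i),
                    "gc_degree": int(deg[i]),
                    "delta_rate": float(with_fb[i] - base[i]),
                    "odor_receiving": net.mitral_cells[i].glomerulus in odor_set,
                    "feedback_pa": float(fb[i]),
                }
            )
    return rows


# ---------------------------------------------------------------------------
# Neurogenesis


@dataclass
class NeurogenesisConfig:
    """Mode and schedule of one neurogenesis experiment."""

    mode: str = "control"  # control | baseline | addition | guided
    rounds: int = 10
    replacement_fraction: float = 0.25
    add_count: int | None = None  # per round; default (15*n_mc - n_gc0)/rounds
    guidance_radius_factor: float = 0.1
    target_ratio: float = 15.0
    windows_ms: float = 5.0
    n_sniffs: int = 2
    min_initial_correlation: float = 0.1
    max_overlap_tries: int = 50


def _remove_gcs(net: Network, remove_ids: set[int]) -> Network:
    """Drop GCs (and their synapses, rolling back MC occupancy); renumber."""
    keep = [g for g in range(net.n_gc) if g not in remove_ids]
    remap = {old: new for new, old in enumerate(keep)}
    by_id = {mc.id: mc for mc in net.mitral_cells}
    syns = []
    for s in net.synapses:
        if s.gc_id in remove_ids:
            by_id[s.mc_id].n_preexisting -= 1
        else:
            syns.append(
                Synapse(
                    mc_id=s.mc_id,
                    gc_id=remap[s.gc_id],
                    location=s.location,
                    dendritic_distance=s.dendritic_distance,
                )
            )
    gcs = []
    for old in keep:
        gc = copy.copy(net.granule_cells[old])
        gc.id = remap[old]
        gcs.append(gc)
    return Network(
        space=net.space,
        mitral_cells=net.mitral_cells,
        granule_cells=gcs,
        synapses=syns,
    )


def _add_gcs(
    net: Network,
    rng: np.random.Generator,
    count: int,
    placement: PlacementConfig | None = None,
    mc_weights: np.ndarray | None = None,
    guidance_radius_factor: float = 0.1,
    max_overlap_tries: int = 50,
) -> Network:
    """Wire ``count`` new connected GCs, optionally guided toward active MCs."""
    for _ in range(count):
        while True:
            center = None
            target_mc = None
            if mc_weights is not None:
                target_mc = net.mitral_cells[
                    int(rng.choice(net.n_mc, p=mc_weights))
                ]
                r = target_mc.morphology.r_max * guidance_radius_factor
                rr = r * math.sqrt(rng.uniform())
                th = rng.uniform(0.0, 2.0 * math.pi)
                center = (
                    target_mc.xy[0] + rr * math.cos(th),
                    target_mc.xy[1] + rr * math.sin(th),
                )
            gc = place_granule_cell(
                net.space,
                rng,
                config=placement,
                gc_id=net.n_gc,
                center_xy=center,
            )
            if target_mc is not None:
                # resample the cone until the target MC's disk height falls
                # inside it (guarantees geometric overlap given the xy rule);
                # bounded, then fall back to the plain draw
                z_m = target_mc.morphology.z_m
                tries = 0
                while (
                    not (gc.morphology.z0 < z_m <= gc.morphology.z_max)
                    and tries < max_overlap_tries
                ):
                    gc = place_granule_cell(
                        net.space,
                        rng,
                        config=placement,
                        gc_id=net.n_gc,
                        center_xy=center,
                    )
                    tries += 1
            syns = wire_granule_cell(gc, net.mitral_cells, net.space, rng)
            if syns:
                net.granule_cells.append(gc)
                net.synapses.extend(syns)
                break
    return net


def exp_neurogenesis(
    net: Network,
    rng: np.random.Generator,
    panel: OdorPanel,
    config: NeurogenesisConfig,
    dt: float = 0.1,
) -> dict:
    """Rounds of simulation + GC turnover/addition; odor-pair correlation tracking.

    Per round every odor is simulated (2 sniffs), odor-pair correlations are
    summarised over the second sniff (5 ms windows), and the mode's update
    is applied: control replaces a random 25% of GCs, baseline replaces the
    least-active 25%, addition adds new random GCs and guided addition
    places them near MCs sampled by firing rate.  Only pairs whose initial
    correlation exceeds ``min_initial_correlation`` are scored.
    """
    cfg = config
    net = copy.deepcopy(net)
    duration = cfg.n_sniffs * SNIFF_MS
    n_mc = net.n_mc
    initial_deg = net.mc_degrees().copy()
    if cfg.add_count is None:
        add_count = int(
            round((cfg.target_ratio * n_mc - net.n_gc) / cfg.rounds)
        )
    else:
        add_count = cfg.add_count
    seed = int(rng.integers(2**31 - 1))
    mc_params = [
        sample_cell_params("MC", np.random.default_rng(seed + i))
        for i in range(n_mc)
    ]
    pair_corrs: list[dict] = []
    pairs = [
        (i, j)
        for i in range(panel.n_odors)
        for j in range(panel.n_odors)
        if i < j
    ]

    def simulate_round(network):
        gc_rng = np.random.default_rng(seed - 1)
        gc_params = [
            sample_cell_params("GC", gc_rng) for _ in range(network.n_gc)
        ]
        mc_rates, gc_counts = [], np.zeros(network.n_gc)
        mc_spike_sets = []
        for oi in range(panel.n_odors):
            proto = Protocol(
                duration=duration,
                padding=0.0,
                mc_current=odor_current_fn(panel, oi),
            )
            res = run_simulation(
                network,
                proto,
                np.random.default_rng(seed + 100 + oi),
                dt=dt,
                mc_params=mc_params,
                gc_params=gc_params,
            )
            mc_spike_sets.append(res.mc_spikes)
            for g, _ in res.gc_spikes:
                gc_counts[g] += 1
            counts = np.zeros(n_mc)
            for i, _ in res.mc_spikes:
                counts[i] += 1
            mc_rates.append(counts)
        rates = [
            windowed_rates(sp, n_mc, duration, cfg.windows_ms)
            for sp in mc_spike_sets
        ]
        corrs = {}
        for i, j in pairs:
            c = correlation_timecourse(rates[i], rates[j])
            corrs[(i, j)] = summary_correlation(
                c, cfg.windows_ms, 0.5, duration
            )
        return corrs, gc_counts, np.sum(mc_rates, axis=0)

    corr0, gc_act, mc_act = simulate_round(net)
    scored = [p for p in pairs if corr0[p] > cfg.min_initial_correlation]
    history = [corr0]
    for rnd in range(cfg.rounds):
        if cfg.mode in ("control", "baseline"):
            n_repl = int(round(cfg.replacement_fraction * net.n_gc))
            if cfg.mode == "control":
                remove = set(
                    int(i)
                    for i in rng.choice(net.n_gc, size=n_repl, replace=False)
                )
            else:
                # least active, ties broken uniformly at random
                noise = rng.uniform(0.0, 1e-6, size=net.n_gc)
                order = np.argsort(gc_act + noise)
                remove = set(int(i) for i in order[:n_repl])
            net = _remove_gcs(net, remove)
            net = _add_gcs(net, rng, n_repl)
        elif cfg.mode == "addition":
            net = _add_gcs(net, rng, add_count)
        elif cfg.mode == "guided":
            total = mc_act.sum()
            weights = (
                mc_act / total
                if total > 0
                else np.full(n_mc, 1.0 / n_mc)
            )
            net = _add_gcs(
                net,
                rng,
                add_count,
                mc_weights=weights,
                guidance_radius_factor=cfg.guidance_radius_factor,
                max_overlap_tries=cfg.max_overlap_tries,
            )
        else:
            raise ValueError(f"unknown neurogenesis mode {cfg.mode!r}")
        corrs, gc_act, mc_act = simulate_round(net)
        history.append(corrs)
    rel_changes = []
    for p in scored:
        c0, c1 = corr0[p], history[-1][p]
        rel_changes.append((c1 - c0) / abs(c0))
    rel_changes = np.asarray(rel_changes)
    final_deg = net.mc_degrees()
    return {
        "mode": cfg.mode,
        "scored_pairs": scored,
        "history": history,
        "relative_change": rel_changes,
        "mean_relative_reduction": float(-np.mean(rel_changes))
        if rel_changes.size
        else float("nan"),
        "fraction_decorrelated": float(np.mean(rel_changes < 0))
        if rel_changes.size
        else float("nan"),
        "initial_mc_degree": initial_deg,
        "final_mc_degree": final_deg,
        "degree_change": final_deg - initial_deg,
        "n_gc_final": net.n_gc,
    }
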