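"""Sequential probabilistic wiring of granule cells onto the mitral-cell scaffold.

GCs are created one at a time and offered to every MC whose disk can reach
the cone cross-section at the disk height, visiting the MCs in a freshly
shuffled order.  Each pair connects with probability 1 - exp(-lambda),
where lambda is the expected synapse count discounted by the MC's current
sheath occupancy.  A GC keeps at most ``S_available`` connections (a random
surplus subset is dropped and the affected MCs' occupancy rolled back), and
GCs that end up fully disconnected are discarded without counting toward
the target of ``ratio`` GCs per MC.

A distance-independent control mode replaces the geometric probability
with a single constant for every pair, calibrated to a target mean degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

from .morphology import GranuleMorphology, gc_cone_radius
from .overlap import (
    InteractionConstants,
    connection_probability,
    expected_synapses,
    overlap_length_circles,
)
from .placement import (
    GranuleCell,
    MitralCell,
    OBSpace,
    PlacementConfig,
    place_granule_cell,
)

__all__ = [
    "Synapse",
    "Network",
    "generate_network",
    "wire_granule_cell",
    "sample_synapse_location",
    "network_statistics",
    "shared_gc_fraction",
    "shared_gc_by_distance",
]


@dataclass
class Synapse:
    """A single reciprocal MC-GC contact."""

    mc_id: int
    gc_id: int
    location: tuple[float, float, float]
    dendritic_distance: float  # radial distance from the MC soma, um


@dataclass
class Network:
    """The wired bulb: cells, synapse table and sparse adjacency."""

    space: OBSpace
    mitral_cells: list[MitralCell]
    granule_cells: list[GranuleCell]
    synapses: list[Synapse] = field(default_factory=list)

    @property
    def n_mc(self) -> int:
        return len(self.mitral_cells)

    @property
    def n_gc(self) -> int:
        return len(self.granule_cells)

    def adjacency(self) -> sparse.csr_matrix:
        """Binary MC x GC adjacency built from the synapse table."""
        rows = [s.mc_id for s in self.synapses]
        cols = [s.gc_id for s in self.synapses]
        data = np.ones(len(rows), dtype=np.int8)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_mc, self.n_gc)
        )

    def mc_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_mc, dtype=int)
        for s in self.synapses:
            deg[s.mc_id] += 1
        return deg

    def gc_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_gc, dtype=int)
        for s in self.synapses:
            deg[s.gc_id] += 1
        return deg


def _pair_geometry(mc: MitralCell, gc_morph: GranuleMorphology, space: OBSpace):
    """(s, r_g) of the disk/cone cross-section, or None if no vertical overlap."""
    z = mc.morphology.z_m
    if not (gc_morph.z0 < z <= gc_morph.z_max):
        return None
    r_g = gc_cone_radius(z, gc_morph)
    center = gc_morph.center_xy_at(z)
    s = space.xy_distance(mc.xy, center)
    if s >= r_g + mc.morphology.r_max:
        return None
    return s, r_g


def sample_synapse_location(
    mc: MitralCell,
    gc: GranuleCell,
    space: OBSpace,
    rng: np.random.Generator,
    uniform_over_lens: bool = False,
    max_tries: int = 10_000,
) -> tuple[tuple[float, float, float], float]:
    """Sample a synapse point in the disk-cone overlap at the MC disk height.

    By default the radial coordinate follows the dendritic density
    (rejection sampling of the rho_m-weighted disk restricted to the lens);
    ``uniform_over_lens`` instead draws area-uniform points in the lens.
    Returns ((x, y, z), radial distance from the MC soma).
    """
    m = mc.morphology
    geom = _pair_geometry(mc, gc.morphology, space)
    if geom is None:
        raise ValueError("MC and GC do not overlap; no synapse location exists")
    s, r_g = geom
    cx, cy = gc.morphology.center_xy_at(m.z_m)
    # orientation of the GC-circle centre seen from the MC soma (the lens is
    # symmetric about this axis; degenerate at s = 0)
    base_angle = math.atan2(cy - mc.xy[1], cx - mc.xy[0]) if s > 0 else 0.0
    tanm = math.tan(m.m)
    r_m = m.r_max

    if uniform_over_lens:
        F = lambda r: 0.5 * r * r  # area weight instead of dendritic weight
        Finv = lambda y: math.sqrt(2.0 * y)
    else:
        F = lambda r: m.alpha * (math.atan(m.k * r - tanm) + m.m)
        Finv = lambda y: (math.tan(y / m.alpha - m.m) + tanm) / m.k

    def bounds(th: float):
        root2 = r_g * r_g - (s * math.sin(th)) ** 2
        if root2 <= 0.0:
            return None
        root = math.sqrt(root2)
        lo = max(s * math.cos(th) - root, 0.0)
        hi = min(s * math.cos(th) + root, r_m)
        if hi <= lo:
            return None
        return lo, hi

    th_max = math.pi if s <= r_g else math.asin(min(r_g / s, 1.0))
    grid = np.linspace(0.0, th_max, 129)
    weights = []
    for th in grid:
        b = bounds(float(th))
        weights.append(0.0 if b is None else F(b[1]) - F(b[0]))
    w_max = 1.5 * max(max(weights), 1e-300)

    for _ in range(max_tries):
        th = rng.uniform(-th_max, th_max)
        b = bounds(th)
        if b is None:
            continue
        w = F(b[1]) - F(b[0])
        if rng.uniform(0.0, w_max) >= w:
            continue
        r = Finv(F(b[0]) + rng.uniform() * w)
        r = min(max(r, b[0]), b[1])
        ang = base_angle + th
        x = mc.xy[0] + r * math.cos(ang)
        y = mc.xy[1] + r * math.sin(ang)
        return (x, y, m.z_m), r
    raise RuntimeError("failed to sample a synapse location in the overlap lens")


def _sample_disk_location(
    mc: MitralCell, rng: np.random.Generator
) -> tuple[tuple[float, float, float], float]:
    """Density-weighted point anywhere on the MC disk (distance-independent mode)."""
    m = mc.morphology
    tanm = math.tan(m.m)
    f_rm = m.alpha * (math.atan(m.k * m.r_max - tanm) + m.m)
    r = (math.tan(rng.uniform() * f_rm / m.alpha - m.m) + tanm) / m.k
    r = min(max(r, 0.0), m.r_max)
    th = rng.uniform(0.0, 2.0 * math.pi)
    return (mc.xy[0] + r * math.cos(th), mc.xy[1] + r * math.sin(th), m.z_m), r


def wire_granule_cell(
    gc: GranuleCell,
    mcs: list[MitralCell],
    space: OBSpace,
    rng: np.random.Generator,
    consts: InteractionConstants = InteractionConstants(),
    mode: str = "geometric",
    p_constant: float | None = None,
    uniform_over_lens: bool = False,
) -> list[Synapse]:
    """Offer one GC to every overlapping MC (shuffled order); return its synapses.

    Mutates the accepted MCs' ``n_preexisting`` occupancy counters, rolling
    back any surplus connections beyond the GC's spine budget.
    """
    morph = gc.morphology
    budget = int(math.floor(morph.S_available))
    if budget <= 0:
        return []
    order = rng.permutation(len(mcs))
    accepted: list[Synapse] = []
    for idx in order:
        mc = mcs[idx]
        if mode == "geometric":
            geom = _pair_geometry(mc, morph, space)
            if geom is None:
                continue
            s, r_g = geom
            L = overlap_length_circles(s, mc.morphology.r_max, r_g, mc.morphology)
            lam = expected_synapses(
                L,
                mc.morphology.z_m,
                morph,
                mc.n_preexisting,
                mc.morphology.total_length,
                consts,
            )
            p = connection_probability(lam)
        elif mode == "distance_independent":
            # S2 control: constant pair probability, no geometric gating
            if p_constant is None:
                raise ValueError("distance_independent mode needs p_constant")
            p = p_constant
        else:
            raise ValueError(f"unknown wiring mode {mode!r}")
        if rng.uniform() < p:
            if mode == "geometric":
                loc, dist = sample_synapse_location(
                    mc, gc, space, rng, uniform_over_lens=uniform_over_lens
                )
            else:
                loc, dist = _sample_disk_location(mc, rng)
            accepted.append(
                Synapse(
                    mc_id=mc.id, gc_id=gc.id, location=loc, dendritic_distance=dist
                )
            )
            mc.n_preexisting += 1
    if len(accepted) > budget:
        by_id = {mc.id: mc for mc in mcs}
        keep = set(int(i) for i in rng.choice(len(accepted), size=budget, replace=False))
        kept = []
        for i, syn in enumerate(accepted):
            if i in keep:
                kept.append(syn)
            else:
                by_id[syn.mc_id].n_preexisting -= 1
        accepted = kept
    return accepted


def generate_network(
    space: OBSpace,
    mcs: list[MitralCell],
    rng: np.random.Generator,
    gc_per_mc_ratio: float = 15.0,
    mode: str = "geometric",
    p_constant: float | None = None,
    config: PlacementConfig | None = None,
    consts: InteractionConstants = InteractionConstants(),
    uniform_over_lens: bool = False,
    progress: bool = False,
) -> Network:
    """Wire GCs one at a time until ``ratio * n_MC`` connected GCs exist.

    Disconnected GCs are discarded without counting.  In
    ``distance_independent`` mode every MC-GC pair connects with the single
    probability ``p_constant`` (calibrate it to a geometric run's mean
    degree for the control comparison).
    """
    if gc_per_mc_ratio <= 0:
        raise ValueError("gc_per_mc_ratio must be positive")
    target = int(round(gc_per_mc_ratio * len(mcs)))
    net = Network(space=space, mitral_cells=mcs, granule_cells=[])
    iterator = range(target)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="wiring GCs")
    for _ in iterator:
        while True:
            gc = place_granule_cell(
                space, rng, config=config, gc_id=len(net.granule_cells)
            )
            syns = wire_granule_cell(
                gc,
                mcs,
                space,
                rng,
                consts=consts,
                mode=mode,
                p_constant=p_constant,
                uniform_over_lens=uniform_over_lens,
            )
            if syns:
                net.granule_cells.append(gc)
                net.synapses.extend(syns)
                break
    return net


def calibrate_constant_probability(reference: Network) -> float:
    """Constant pair probability matching a geometric network's synapse count."""
    n_pairs = reference.n_mc * reference.n_gc
    return len(reference.synapses) / n_pairs


def shared_gc_fraction(
    net: Network,
    mc_a: int,
    mc_b: int,
    adjacency: sparse.csr_matrix | None = None,
    jaccard: bool = False,
) -> float:
    """Fraction of GCs shared by two MCs.

    Default denominator is |GCs of a| (ordered-pair convention, so each
    unordered pair contributes two samples); ``jaccard`` uses the symmetric
    |shared| / |union| instead.
    """
    adj = adjacency if adjacency is not None else net.adjacency()
    a = adj.getrow(mc_a)
    b = adj.getrow(mc_b)
    shared = a.multiply(b).nnz
    denom = (a.nnz + b.nnz - shared) if jaccard else a.nnz
    if denom == 0:
        return 0.0
    return shared / denom


def shared_gc_by_distance(
    net: Network,
    pairs: list[tuple[int, int]] | None = None,
    bin_width: float = 100.0,
    n_bins: int = 12,
    rng: np.random.Generator | None = None,
    max_pairs: int = 2000,
):
    """Mean shared-GC count per inter-soma-distance bin over sampled MC pairs.

    Returns (bin_centers, mean_shared, counts).
    """
    adj = net.adjacency().astype(np.int32)
    if pairs is None:
        rng = rng or np.random.default_rng()
        idx = rng.choice(net.n_mc, size=(max_pairs, 2))
        pairs = [(int(i), int(j)) for i, j in idx if i != j]
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i, j in pairs:
        d = net.space.xy_distance(net.mitral_cells[i].xy, net.mitral_cells[j].xy)
        b = int(d // bin_width)
        if b >= n_bins:
            continue
        shared = adj.getrow(i).multiply(adj.getrow(j)).nnz
        sums[b] += shared
        counts[b] += 1
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    centers = edges[:-1] + bin_width / 2.0
    return centers, means, counts


def network_statistics(net: Network, sample_pairs: int = 2000, rng=None) -> dict:
    """Degree summaries, exponential/skew-normal fits, sister-GC overlap."""
    rng = rng or np.random.default_rng(0)
    mc_deg = net.mc_degrees()
    gc_deg = net.gc_degrees()
    types = np.array([mc.mc_type for mc in net.mitral_cells])
    out: dict = {
        "n_mc": net.n_mc,
        "n_gc": net.n_gc,
        "n_synapses": len(net.synapses),
        "mc_degree_mean": float(mc_deg.mean()) if net.n_mc else 0.0,
        "mc_degree_mean_type1": float(mc_deg[types == 1].mean())
        if (types == 1).any()
        else float("nan"),
        "mc_degree_mean_type2": float(mc_deg[types == 2].mean())
        if (types == 2).any()
        else float("nan"),
        "gc_degree_mean": float(gc_deg.mean()) if net.n_gc else 0.0,
    }
    # skew-normal fit of the GC degree distribution
    if net.n_gc >= 10 and gc_deg.std() > 0:
        shape, loc, scale = stats.skewnorm.fit(gc_deg.astype(float))
        out["gc_degree_skewnorm"] = {"shape": shape, "shift": loc, "scale": scale}
    # sister vs non-sister shared-GC fraction (ordered pairs)
    gloms = np.array([mc.glomerulus for mc in net.mitral_cells])
    adj = net.adjacency()
    sister_vals, nonsister_vals = [], []
    by_glom: dict[int, list[int]] = {}
    for i, g in enumerate(gloms):
        by_glom.setdefault(int(g), []).append(i)
    for members in by_glom.values():
        for a in members:
            for b in members:
                if a != b:
                    sister_vals.append(shared_gc_fraction(net, a, b, adj))
    n_needed = max(len(sister_vals), 200)
    tries = 0
    while len(nonsister_vals) < n_needed and tries < 50 * n_needed:
        a, b = rng.choice(net.n_mc, size=2, replace=False)
        tries += 1
        if gloms[a] != gloms[b]:
            nonsister_vals.append(shared_gc_fraction(net, int(a), int(b), adj))
    out["sister_shared_fraction_mean"] = (
        float(np.mean(sister_vals)) if sister_vals else float("nan")
    )
    out["nonsister_shared_fraction_mean"] = (
        float(np.mean(nonsister_vals)) if nonsister_vals else float("nan")
    )
    return out
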