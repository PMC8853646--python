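"""Spatial layout of the model bulb: glomeruli, mitral cells, granule cells.

The bulb is a thin cylinder of configurable radius, its height split into
IPL, MCL and EPL slabs.  Glomerular projections scatter uniformly in the
disk at a fixed area density; each anchors a cluster of 15-25 sister MCs
whose somata fall off with distance following a truncated logistic law.
GC cones are sampled with the distributions listed in ``PlacementConfig``.
All sampling uses a single ``numpy.random.Generator``; truncated laws are
realized by inverse-CDF restriction for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .morphology import (
    GranuleMorphology,
    LayerStack,
    MitralMorphology,
    available_spines,
    derive_mc_profile,
)

__all__ = [
    "OBSpace",
    "PlacementConfig",
    "MitralCell",
    "GranuleCell",
    "build_space",
    "place_mitral_cells",
    "place_granule_cell",
    "spine_count_bounds",
]


@dataclass
class OBSpace:
    """Layered cylindrical bulb space with glomerulus projections."""

    radius: float
    layers: LayerStack = field(default_factory=LayerStack)
    glomerulus_density: float = 157.0  # count per mm^2
    boundary_mode: str = "bounded"  # "bounded" | "periodic"
    glomeruli: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def xy_distance(self, a, b) -> float:
        """Distance in the xy-plane, wrapping across the disk if periodic."""
        dx = a[0] - b[0]
        dy = a[1] - b[1]
        d = math.hypot(dx, dy)
        if self.boundary_mode == "periodic":
            # wrap on a square period of the disk diameter in each axis
            period = 2.0 * self.radius
            dx = dx - period * round(dx / period)
            dy = dy - period * round(dy / period)
            d = math.hypot(dx, dy)
        return d


@dataclass
class MitralCell:
    """A placed mitral cell: soma position plus disk morphology and wiring state."""

    id: int
    glomerulus: int
    xy: tuple[float, float]
    morphology: MitralMorphology
    n_preexisting: int = 0  # synapses already on the dendrite (occupancy)

    @property
    def z(self) -> float:
        return self.morphology.z_m

    @property
    def mc_type(self) -> int:
        return self.morphology.mc_type


@dataclass
class GranuleCell:
    """A placed granule cell (cone morphology plus spine budget)."""

    id: int
    morphology: GranuleMorphology


@dataclass(frozen=True)
class PlacementConfig:
    """Sampling distributions for cell placement (lengths in um)."""

    mcs_per_glomerulus: tuple[int, int] = (15, 25)  # inclusive uniform ints
    mc_radius_range: tuple[float, float] = (75.0, 800.0)
    mc_type_I_prob: float = 2.0 / 3.0
    # soma offset from the glomerular projection: truncated logistic
    mc_offset_mu: float = 78.4
    mc_offset_s: float = 23.1
    mc_offset_max: float = 300.0
    # MC density shape variables
    mc_gamma_range: tuple[float, float] = (0.2, 0.3)
    mc_xi_range: tuple[float, float] = (1.0 / 3.0, 4.0 / 5.0)
    mc_w_range: tuple[float, float] = (0.00255, 0.00510)
    # GC cone sampling
    gc_rmax_mean: float = 83.0
    gc_rmax_sd: float = 28.0
    gc_rmax_bounds: tuple[float, float] = (30.0, 160.0)
    gc_obliquity_max: float = 50.0
    # spine-count bounds a*atan(b*V): (lower), (upper)
    spine_lo: tuple[float, float] = (39.31, 1.043e-5)
    spine_hi: tuple[float, float] = (357.7, 2.653e-6)


def build_space(
    radius: float,
    rng: np.random.Generator,
    config: PlacementConfig | None = None,
    layers: LayerStack | None = None,
    glomerulus_density: float = 157.0,
    boundary_mode: str = "bounded",
) -> OBSpace:
    """Build the bulb space and scatter glomerulus projections in the disk."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    layers = layers or LayerStack()
    area_mm2 = math.pi * (radius / 1000.0) ** 2
    n_glom = int(round(glomerulus_density * area_mm2))
    # uniform in the disk via sqrt-radius sampling
    rr = radius * np.sqrt(rng.uniform(size=n_glom))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n_glom)
    glomeruli = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    return OBSpace(
        radius=radius,
        layers=layers,
        glomerulus_density=glomerulus_density,
        boundary_mode=boundary_mode,
        glomeruli=glomeruli,
    )


def _truncated_logistic(
    rng: np.random.Generator, mu: float, s: float, lo: float, hi: float, size=None
):
    """Inverse-CDF sampling of a logistic law restricted to [lo, hi]."""
    dist = stats.logistic(loc=mu, scale=s)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=size)
    return dist.ppf(u)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    dist = stats.norm(loc=mean, scale=sd)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi))
    return float(dist.ppf(u))


def place_mitral_cells(
    space: OBSpace,
    rng: np.random.Generator,
    config: PlacementConfig | None = None,
) -> list[MitralCell]:
    """Assign 15-25 MCs to each glomerulus and place their disks in the EPL.

    Soma offsets follow the truncated logistic law; type I cells (prob 2/3)
    sit in the lower half of the EPL, type II cells in the 2/5-4/5 band.
    """
    cfg = config or PlacementConfig()
    layers = space.layers
    floor = layers.epl_floor
    cells: list[MitralCell] = []
    cid = 0
    lo, hi = cfg.mcs_per_glomerulus
    for gi, (gx, gy) in enumerate(space.glomeruli):
        n_mc = int(rng.integers(lo, hi + 1))
        for _ in range(n_mc):
            r_off = float(
                _truncated_logistic(
                    rng, cfg.mc_offset_mu, cfg.mc_offset_s, 0.0, cfg.mc_offset_max
                )
            )
            th = rng.uniform(0.0, 2.0 * math.pi)
            xy = (gx + r_off * math.cos(th), gy + r_off * math.sin(th))
            r_max = rng.uniform(*cfg.mc_radius_range)
            gamma = rng.uniform(*cfg.mc_gamma_range)
            xi = rng.uniform(*cfg.mc_xi_range)
            w = rng.uniform(*cfg.mc_w_range)
            alpha, k, m = derive_mc_profile(gamma, xi, w, r_max)
            if rng.uniform() < cfg.mc_type_I_prob:
                mc_type = 1
                z = floor + rng.uniform(0.0, 0.5 * layers.epl_thickness)
            else:
                mc_type = 2
                z = floor + rng.uniform(
                    0.4 * layers.epl_thickness, 0.8 * layers.epl_thickness
                )
            morph = MitralMorphology(
                r_max=r_max,
                gamma_peak=gamma,
                xi_center=xi,
                w=w,
                alpha=alpha,
                k=k,
                m=m,
                z_m=z,
                mc_type=mc_type,
            )
            cells.append(MitralCell(id=cid, glomerulus=gi, xy=xy, morphology=morph))
            cid += 1
    return cells


def spine_count_bounds(
    volume: float, cfg: PlacementConfig | None = None
) -> tuple[float, float]:
    """Lower/upper spine-count bounds a*atan(b*V) for a cone of volume V (um^3)."""
    cfg = cfg or PlacementConfig()
    lo = cfg.spine_lo[0] * math.atan(cfg.spine_lo[1] * volume)
    hi = cfg.spine_hi[0] * math.atan(cfg.spine_hi[1] * volume)
    return lo, hi


def place_granule_cell(
    space: OBSpace,
    rng: np.random.Generator,
    config: PlacementConfig | None = None,
    gc_id: int = 0,
    center_xy: tuple[float, float] | None = None,
) -> GranuleCell:
    """Sample one granule cell cone and its spine budget.

    ``center_xy`` overrides the uniform vertex position (used by guided
    neurogenesis); otherwise the vertex falls uniformly in the disk.
    """
    cfg = config or PlacementConfig()
    layers = space.layers
    floor = layers.epl_floor
    if center_xy is None:
        rr = space.radius * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        vx, vy = rr * math.cos(th), rr * math.sin(th)
    else:
        vx, vy = center_xy
    while True:
        r_max = _truncated_normal(
            rng, cfg.gc_rmax_mean, cfg.gc_rmax_sd, *cfg.gc_rmax_bounds
        )
        z0 = rng.uniform(0.0, floor)
        z_max = floor + rng.uniform(
            0.5 * layers.epl_thickness, layers.epl_thickness
        )
        if z_max > z0:
            break
    obl = rng.uniform(0.0, cfg.gc_obliquity_max)
    oth = rng.uniform(0.0, 2.0 * math.pi)
    face = (vx + obl * math.cos(oth), vy + obl * math.sin(oth))
    volume = math.pi * r_max**2 * (z_max - z0) / 3.0
    lo, hi = spine_count_bounds(volume, cfg)
    S = rng.uniform(lo, hi)
    morph = GranuleMorphology(
        vertex_xy=(vx, vy),
        face_center_xy=face,
        r_max=r_max,
        z0=z0,
        z_max=z_max,
        S=S,
    )
    morph.S_available = available_spines(morph, layers)
    return GranuleCell(id=gc_id, morphology=morph)
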