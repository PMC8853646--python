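"""Closed-form dendritic density models for mitral and granule cells.

Mitral-cell (MC) lateral dendrites are summarized as a radially symmetric
length density ``rho_m(r)`` on a flat disk of radius ``r_max``:

    rho_m(r) = (alpha*k / 2*pi*r) / (1 + (k*r - tan(m))**2)

whose cumulative form (total dendritic length within radius ``r``) is

    f(r) = alpha * atan(k*r - tan(m)) + m*alpha.

Granule-cell (GC) spines are distributed on an inverted oblique cone with a
parabolic vertical spine density ``N_s(z)``, giving a volumetric density

    rho_g(z) = 6*S*(z_max - z) / (pi*r_max**2 * (z_max - z_0) * (z - z_0)).

Units are micrometres throughout (project convention: um, ms, mV, pA, nS,
pF, GOhm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LayerStack",
    "MitralMorphology",
    "GranuleMorphology",
    "derive_mc_profile",
    "mc_dendrite_density",
    "mc_cumulative_length",
    "gc_spine_density",
    "gc_vertical_spine_density",
    "gc_cone_radius",
    "available_spines",
]

#: Height clamp (um) applied when evaluating rho_g near the cone vertex,
#: where the density diverges as z -> z0+.
Z_EPSILON = 1.0


@dataclass(frozen=True)
class LayerStack:
    """Thicknesses (um) of the stacked bulb layers, bottom to top: IPL, MCL, EPL."""

    epl_thickness: float = 131.0
    mcl_thickness: float = 36.0
    ipl_thickness: float = 27.0

    @property
    def total(self) -> float:
        return self.epl_thickness + self.mcl_thickness + self.ipl_thickness

    @property
    def epl_floor(self) -> float:
        """Height (um) of the bottom of the EPL above the model floor."""
        return self.ipl_thickness + self.mcl_thickness


@dataclass
class MitralMorphology:
    """Disk morphology of one MC lateral-dendrite field.

    ``gamma_peak`` is the fraction of ``r_max`` at which df/dr peaks;
    ``xi_center`` is the relative magnitude of df/dr at r=0 versus its peak;
    ``w`` (um^-1) scales the total dendritic length: f(r_max) = w*pi*r_max**2.
    ``alpha`` (um), ``k`` (um^-1), ``m`` (rad) are the derived density
    constants.  ``z_m`` is the disk height; ``mc_type`` is 1 or 2.
    """

    r_max: float
    gamma_peak: float
    xi_center: float
    w: float
    alpha: float
    k: float
    m: float
    z_m: float = 0.0
    mc_type: int = 1

    @property
    def total_length(self) -> float:
        """Total dendritic length f(r_max) in um."""
        return self.w * math.pi * self.r_max**2


@dataclass
class GranuleMorphology:
    """Inverted oblique cone carrying a GC's spines.

    The vertex sits at ``(vertex_xy, z0)``; the circular top face of radius
    ``r_max`` is centred at ``(face_center_xy, z_max)``.  ``S`` is the total
    spine count, ``S_available`` the subset inside the EPL.
    """

    vertex_xy: tuple[float, float]
    face_center_xy: tuple[float, float]
    r_max: float
    z0: float
    z_max: float
    S: float
    S_available: float = 0.0

    def center_xy_at(self, z: float) -> tuple[float, float]:
        """Axis position of the (oblique) cone at height z."""
        t = (z - self.z0) / (self.z_max - self.z0)
        vx, vy = self.vertex_xy
        fx, fy = self.face_center_xy
        return (vx + t * (fx - vx), vy + t * (fy - vy))


def derive_mc_profile(
    gamma_peak: float, xi_center: float, w: float, r_max: float
) -> tuple[float, float, float]:
    """Derive the density constants (alpha, k, m) from the shape variables.

    m = atan(sqrt(1/xi - 1)); k = tan(m)/(gamma*r_max);
    alpha = w*pi*r_max**2 / (atan(k*r_max - tan(m)) + m).
    """
    if not (0.0 < gamma_peak < 1.0):
        raise ValueError(f"gamma_peak must be in (0,1), got {gamma_peak}")
    if not (0.0 < xi_center <= 1.0):
        raise ValueError(f"xi_center must be in (0,1], got {xi_center}")
    if r_max <= 0 or w <= 0:
        raise ValueError("r_max and w must be positive")
    m = math.atan(math.sqrt(1.0 / xi_center - 1.0))
    k = math.tan(m) / (gamma_peak * r_max)
    total = w * math.pi * r_max**2
    alpha = total / (math.atan(k * r_max - math.tan(m)) + m)
    return alpha, k, m


def mc_dendrite_density(r, profile: MitralMorphology):
    """Lateral-dendrite length density rho_m(r) in um/um^2 for 0 < r <= r_max."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(r > profile.r_max):
        raise ValueError("r must satisfy 0 < r <= r_max")
    tanm = math.tan(profile.m)
    out = (profile.alpha * profile.k / (2.0 * math.pi * r)) / (
        1.0 + (profile.k * r - tanm) ** 2
    )
    return out if out.shape else float(out)


def mc_cumulative_length(r, profile: MitralMorphology):
    """Cumulative dendritic length f(r) = alpha*atan(k*r - tan m) + m*alpha (um)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > profile.r_max * (1 + 1e-12)):
        raise ValueError("r must satisfy 0 <= r <= r_max")
    tanm = math.tan(profile.m)
    out = profile.alpha * np.arctan(profile.k * r - tanm) + profile.m * profile.alpha
    return out if out.shape else float(out)


def gc_cone_radius(z, gc: GranuleMorphology):
    """Cone cross-section radius r(z) = r_max*(z - z0)/(z_max - z0)."""
    z = np.asarray(z, dtype=float)
    out = gc.r_max * (z - gc.z0) / (gc.z_max - gc.z0)
    return out if out.shape else float(out)


def gc_vertical_spine_density(z, gc: GranuleMorphology, S: float | None = None):
    """Parabolic linear spine density N_s(z) (spines/um), integrating to S."""
    z = np.asarray(z, dtype=float)
    S = gc.S if S is None else S
    a = 6.0 * S / (gc.z_max - gc.z0) ** 3
    out = -a * (z - gc.z0) * (z - gc.z_max)
    return out if out.shape else float(out)


def gc_spine_density(z: float, gc: GranuleMorphology, effective_S: float) -> float:
    """Volumetric spine density rho_g(z) (spines/um^3), clamped near the vertex.

    The density diverges as z -> z0+; evaluation height is clamped to
    z0 + Z_EPSILON to keep synapse expectations finite.
    """
    if z <= gc.z0:
        raise ValueError("z must lie above the cone vertex z0")
    z = max(z, gc.z0 + Z_EPSILON)
    z = min(z, gc.z_max)
    num = 6.0 * effective_S * (gc.z_max - z)
    den = math.pi * gc.r_max**2 * (gc.z_max - gc.z0) * (z - gc.z0)
    return num / den


def available_spines(gc: GranuleMorphology, layers: LayerStack) -> float:
    """Spines inside the EPL: integral of N_s(z) from the EPL floor to z_max.

    Closed form of the cubic antiderivative of -a*(z-z0)*(z-z_max).  Returns
    S when the whole cone sits in the EPL and 0 when it sits below it.
    """
    floor = layers.epl_floor
    if gc.z_max <= floor:
        return 0.0
    lo = max(gc.z0, floor)
    a = 6.0 * gc.S / (gc.z_max - gc.z0) ** 3

    def antideriv(z: float) -> float:
        # integral of -(z-z0)(z-zmax) dz
        return -(z**3 / 3.0 - (gc.z0 + gc.z_max) * z**2 / 2.0 + gc.z0 * gc.z_max * z)

    val = a * (antideriv(gc.z_max) - antideriv(lo))
    # guard tiny negative round-off
    return float(min(max(val, 0.0), gc.S))
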