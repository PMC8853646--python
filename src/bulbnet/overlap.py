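"""Disk-cone overlap integrals, expected synapse counts and connection probability.

The dendritic length ``L`` shared by an MC disk (radius ``r_m``, centred at
the origin) and the GC cone cross-section at the disk height (a circle of
radius ``r_g`` whose centre lies a distance ``s`` away) is the integral of
the MC density over the lens of intersection.  Because the density is
radially symmetric about the MC soma, the inner radial integral has the
closed form f(r)/(2*pi) (cumulative dendritic length), leaving a one
dimensional quadrature in the polar angle.  The integration regions split
into nine regimes depending on the relative sizes of ``r_m``, ``r_g`` and
the separation ``s``.

The expected number of synapses for the pair treats the dendrite as a
cylinder wrapped in an interaction sheath of cross-section ``q`` (um^2);
spines already occupying the sheath discount the available volume.  A
Poisson model converts the expectation into a connection probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .morphology import (
    GranuleMorphology,
    MitralMorphology,
    gc_cone_radius,
    gc_spine_density,
    mc_cumulative_length,
)

__all__ = [
    "InteractionConstants",
    "OverlapCase",
    "classify_overlap",
    "overlap_length",
    "overlap_length_circles",
    "expected_synapses",
    "connection_probability",
]

#: absolute quadrature tolerance on L, in um
L_ABS_TOL = 1e-3

#: Gauss-Legendre nodes used for the theta quadrature.  The integrands are
#: smooth except for square-root behaviour at lens corners; 96 nodes keep
#: the error well under L_ABS_TOL for the radii used in the model.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)


def _gl(f, a: float, b: float) -> float:
    """Integrate a vectorized scalar function over [a, b] by Gauss-Legendre."""
    if b <= a:
        return 0.0
    mid = 0.5 * (a + b)
    half = 0.5 * (b - a)
    x = mid + half * _GL_NODES
    return half * float(np.dot(_GL_WEIGHTS, f(x)))


def _gl_sqrt_end(f, a: float, b: float) -> float:
    """Integrate f over [a, b] when f has sqrt(b - theta) behaviour at b.

    The substitution theta = b - (b-a) t^2 turns the square-root endpoint
    into an analytic integrand, restoring spectral accuracy.
    """
    if b <= a:
        return 0.0
    t = 0.5 * (_GL_NODES + 1.0)  # nodes on (0, 1)
    w = 0.5 * _GL_WEIGHTS
    span = b - a
    theta = b - span * t * t
    return float(np.dot(w, f(theta) * 2.0 * span * t))


@dataclass(frozen=True)
class InteractionConstants:
    """Geometric constants of the spine-dendrite interaction sheath."""

    d_shell: float = 1.02  # effective spine diameter, um
    r_dendrite: float = 0.63  # lateral-dendrite cylinder radius, um
    v_spine: float = 0.58  # average spine volume, um^3

    @property
    def q(self) -> float:
        """Sheath cross-section area (um^2): (d_shell+r_dend)^2 - r_dend^2."""
        return (self.d_shell + self.r_dendrite) ** 2 - self.r_dendrite**2


class OverlapCase(Enum):
    """The nine integration regimes for the disk-circle lens."""

    DISJOINT = "disjoint"
    EDGE = "edge"  # sqrt(rg^2+rm^2) <= s < rg+rm (all size cases)
    CHORD = "chord"  # max(|rm-rg|, rg) <= s < sqrt(rg^2+rm^2)
    BAND = "band"  # rm > 2rg, rg <= s < rm-rg: annular band strip
    GC_INSIDE = "gc_inside"  # rm > 2rg (or rm-rg>rg), s < min(rg, rm-rg)
    CENTER_COVERED = "center_covered"  # |rm-rg| <= s < rg: GC circle covers MC center
    MC_INSIDE = "mc_inside"  # rg > rm, s < rg-rm: whole disk inside circle


def classify_overlap(s: float, r_m: float, r_g: float) -> OverlapCase:
    """Determine the integration regime for separation s and radii r_m, r_g."""
    if r_m < 0 or r_g < 0 or s < 0:
        raise ValueError("radii and separation must be nonnegative")
    if r_g == 0.0 or s >= r_g + r_m:
        return OverlapCase.DISJOINT
    hyp = math.hypot(r_g, r_m)
    if s >= hyp:
        return OverlapCase.EDGE
    if r_g > r_m:
        if s >= r_g:
            return OverlapCase.CHORD
        if s >= r_g - r_m:
            return OverlapCase.CENTER_COVERED
        return OverlapCase.MC_INSIDE
    # r_m >= r_g
    if s >= max(r_m - r_g, r_g):
        return OverlapCase.CHORD
    if s >= r_g:  # implies r_m - r_g > s >= r_g, i.e. r_m > 2 r_g
        return OverlapCase.BAND
    if s >= r_m - r_g:  # GC circle covers the MC centre
        return OverlapCase.CENTER_COVERED
    return OverlapCase.GC_INSIDE


def _angles(s: float, r_m: float, r_g: float) -> tuple[float, float]:
    """Polar angles mu (lens corner seen from MC centre) and gamma (tangent)."""
    cmu = (r_m**2 + s**2 - r_g**2) / (2.0 * r_m * s)
    mu = math.acos(min(1.0, max(-1.0, cmu)))
    gamma = math.asin(min(1.0, r_g / s)) if s > 0 else math.pi
    return mu, gamma


def overlap_length_circles(
    s: float, r_m: float, r_g: float, profile: MitralMorphology
) -> float:
    """Dendritic length (um) inside the lens of the MC disk and a circle.

    ``s`` is the centre separation, ``r_g`` the circle radius at the disk
    height.  Dispatches on the nine case regimes; each case integrates the
    closed-form cumulative length over the polar angle.
    """
    case = classify_overlap(s, r_m, r_g)
    if case is OverlapCase.DISJOINT:
        return 0.0

    tanm = math.tan(profile.m)
    alpha, k, m = profile.alpha, profile.k, profile.m

    def f(r):
        """Cumulative dendritic length, vectorized and clipped to [0, r_m]."""
        r = np.clip(r, 0.0, r_m)
        return alpha * (np.arctan(k * r - tanm) + m)

    f_rm = float(alpha * (math.atan(k * r_m - tanm) + m))
    two_pi = 2.0 * math.pi

    if case is OverlapCase.MC_INSIDE:
        return f_rm

    def root(th):
        return np.sqrt(np.maximum(r_g**2 - (s * np.sin(th)) ** 2, 0.0))

    def g_lo(th):
        return s * np.cos(th) - root(th)

    def g_hi(th):
        return s * np.cos(th) + root(th)

    if case is OverlapCase.GC_INSIDE:
        # full GC circle inside the disk: integrate f(g'(theta)) over all
        # theta; split at pi/2 where the root term is smallest (near-kink
        # when s approaches r_g)
        val = _gl(lambda th: f(g_hi(th)), 0.0, math.pi / 2.0) + _gl(
            lambda th: f(g_hi(th)), math.pi / 2.0, math.pi
        )
        return 2.0 * val / two_pi

    mu, gamma = _angles(s, r_m, r_g)

    if case is OverlapCase.EDGE:
        # theta in [0, mu], radial from g(theta) to rm
        val = _gl(lambda th: f_rm - f(g_lo(th)), 0.0, mu)
        return 2.0 * val / two_pi

    if case is OverlapCase.CHORD:
        # [0,mu]: g..rm ; [mu,gamma]: g..g' (sqrt corner at gamma)
        v1 = _gl(lambda th: f_rm - f(g_lo(th)), 0.0, mu)
        v2 = _gl_sqrt_end(lambda th: f(g_hi(th)) - f(g_lo(th)), mu, gamma)
        return 2.0 * (v1 + v2) / two_pi

    if case is OverlapCase.BAND:
        # strip between the two circle branches, sqrt corner at gamma
        val = _gl_sqrt_end(lambda th: f(g_hi(th)) - f(g_lo(th)), 0.0, gamma)
        return 2.0 * val / two_pi

    if case is OverlapCase.CENTER_COVERED:
        # [mu,pi]: 0..g' ; [0,mu]: 0..rm; split at pi/2 (near-kink for s ~ r_g)
        if mu < math.pi / 2.0:
            v1 = _gl(lambda th: f(g_hi(th)), mu, math.pi / 2.0) + _gl(
                lambda th: f(g_hi(th)), math.pi / 2.0, math.pi
            )
        else:
            v1 = _gl(lambda th: f(g_hi(th)), mu, math.pi)
        v2 = mu * f_rm
        return 2.0 * (v1 + v2) / two_pi

    raise AssertionError(f"unhandled case {case}")


def overlap_length(
    mc: MitralMorphology,
    mc_xy: tuple[float, float],
    gc: GranuleMorphology,
) -> float:
    """Overlap dendritic length between a placed MC disk and a GC cone.

    The cone cross-section at the disk height z_m gives the circle radius
    r_g and (oblique) centre; returns 0 when z_m lies outside (z0, z_max].
    """
    z = mc.z_m
    if not (gc.z0 < z <= gc.z_max):
        return 0.0
    r_g = gc_cone_radius(z, gc)
    cx, cy = gc.center_xy_at(z)
    s = math.hypot(cx - mc_xy[0], cy - mc_xy[1])
    return overlap_length_circles(s, mc.r_max, r_g, mc)


def expected_synapses(
    L: float,
    z_m: float,
    gc: GranuleMorphology,
    n_preexisting: int,
    mc_total_length: float,
    consts: InteractionConstants = InteractionConstants(),
) -> float:
    """Expected synapse count lambda for an MC-GC pair.

    V = q*pi*L discounted by the fraction of the MC's total interaction
    sheath already occupied by ``n_preexisting`` spines; multiplied by the
    volumetric spine density at the disk height (using S_available).
    """
    if L < 0:
        raise ValueError("L must be nonnegative")
    if L == 0.0:
        return 0.0
    if mc_total_length <= 0:
        raise ValueError("degenerate MC with zero total dendritic length")
    q = consts.q
    v = q * math.pi * L
    v_tot = q * math.pi * mc_total_length
    occupancy = 1.0 - n_preexisting * consts.v_spine / v_tot
    v_eff = v * max(occupancy, 0.0)
    rho = gc_spine_density(z_m, gc, effective_S=gc.S_available)
    return rho * v_eff


def connection_probability(lambda_syn) -> float:
    """P(at least one synapse) = 1 - exp(-lambda) under the Poisson model."""
    lam = np.asarray(lambda_syn, dtype=float)
    if np.any(lam < 0):
        raise ValueError("expected synapse count must be nonnegative")
    out = -np.expm1(-lam)
    return out if out.shape else float(out)
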