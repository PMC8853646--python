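import math

import numpy as np
import pytest

from bulbnet.morphology import GranuleMorphology, MitralMorphology, derive_mc_profile
from bulbnet.netgen import generate_network
from bulbnet.placement import build_space, place_mitral_cells


def make_profile(gamma=0.25, xi=0.5, w=0.003, r_max=400.0, z_m=100.0, mc_type=1):
    alpha, k, m = derive_mc_profile(gamma, xi, w, r_max)
    return MitralMorphology(
        r_max=r_max, gamma_peak=gamma, xi_center=xi, w=w,
        alpha=alpha, k=k, m=m, z_m=z_m, mc_type=mc_type,
    )


@pytest.fixture(scope="session")
def example_profile():
    """The worked reference disk: gamma=0.25, xi=0.5, w=0.003, r_max=400."""
    return make_profile()


@pytest.fixture(scope="session")
def example_gc():
    """Reference cone: S=10000 spines, r_max=80, vertex z=40, face z=180."""
    return GranuleMorphology(
        vertex_xy=(0.0, 0.0), face_center_xy=(0.0, 0.0),
        r_max=80.0, z0=40.0, z_max=180.0, S=10_000.0, S_available=10_000.0,
    )


@pytest.fixture(scope="session")
def tiny_net():
    """Geometric network in a 120-um bulb at a 3:1 GC:MC ratio (seeded)."""
    rng = np.random.default_rng(42)
    space = build_space(120.0, rng)
    mcs = place_mitral_cells(space, rng)
    return generate_network(space, mcs, rng, gc_per_mc_ratio=3)


def profile_oracle_length(s, r_m, r_g, profile, n=400_000, seed=0):
    """Monte-Carlo estimate of the lens dendritic length, with standard error.

    Samples disk points with radial density rho_m(r)*2*pi*r via the inverse
    cumulative length, then scores the fraction landing inside the GC circle.
    """
    rng = np.random.default_rng(seed)
    tanm = math.tan(profile.m)
    f_rm = profile.alpha * (math.atan(profile.k * r_m - tanm) + profile.m)
    u = rng.uniform(size=n)
    r = (np.tan(u * f_rm / profile.alpha - profile.m) + tanm) / profile.k
    th = rng.uniform(0, 2 * math.pi, size=n)
    inside = (r * np.cos(th) - s) ** 2 + (r * np.sin(th)) ** 2 <= r_g * r_g
    p = inside.mean()
    se = f_rm * math.sqrt(p * (1 - p) / n)
    return f_rm * p, se
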