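"""Connection probability for one mitral-cell / granule-cell pair.

Builds a reference MC disk and GC cone, computes the dendritic length in
their overlap lens, the expected synapse count and the resulting
connection probability at a range of separations.
"""

import numpy as np

from bulbnet.morphology import GranuleMorphology, MitralMorphology, derive_mc_profile
from bulbnet.overlap import (
    connection_probability,
    expected_synapses,
    overlap_length_circles,
)

# MC disk: slope peak at 25% of the radius, centre slope half the peak,
# 0.003 um of dendrite per um^2 of field area, 400 um radius
alpha, k, m = derive_mc_profile(0.25, 0.5, 0.003, 400.0)
mc = MitralMorphology(
    r_max=400.0, gamma_peak=0.25, xi_center=0.5, w=0.003,
    alpha=alpha, k=k, m=m, z_m=150.0,
)
print(f"derived constants: alpha={alpha:.1f} um, k={k:.4f} 1/um, m={m:.4f} rad")
print(f"total dendritic length f(r_max) = {mc.total_length:.1f} um")

# GC cone: 10,000 spines between z = 40 and 180 um, 80 um face radius
gc = GranuleMorphology(
    vertex_xy=(0.0, 0.0), face_center_xy=(0.0, 0.0),
    r_max=80.0, z0=40.0, z_max=180.0, S=10_000.0, S_available=9_279.0,
)
r_g = gc.r_max * (mc.z_m - gc.z0) / (gc.z_max - gc.z0)
print(f"cone cross-section radius at the disk height: {r_g:.1f} um")

print(f"\n{'s (um)':>8} {'L (um)':>10} {'lambda':>8} {'P(connect)':>10}")
for s in np.arange(0.0, 500.0, 60.0):
    L = overlap_length_circles(s, mc.r_max, r_g, mc)
    lam = expected_synapses(L, mc.z_m, gc, n_preexisting=0,
                            mc_total_length=mc.total_length)
    p = connection_probability(lam)
    print(f"{s:8.0f} {L:10.2f} {lam:8.4f} {p:10.4f}")

print(
    "\nL is the MC dendrite length inside the overlap; lambda the expected\n"
    "synapse count in the interaction sheath around it; P = 1 - exp(-lambda)\n"
    "falls off with separation, vanishing once the fields no longer touch."
)
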