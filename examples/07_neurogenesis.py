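"""Granule-cell neurogenesis without cell death.

Compares four turnover modes over rounds of simulation + rewiring:
random replacement (control), least-active replacement (baseline),
plain addition, and activity-guided addition.  Reports the mean relative
reduction in odor-pair correlation and the GC population trajectory.
"""

import numpy as np

from bulbnet.experiments import NeurogenesisConfig, exp_neurogenesis, make_odor_panel
from bulbnet.netgen import generate_network
from bulbnet.placement import build_space, place_mitral_cells

rng = np.random.default_rng(3)
space = build_space(100.0, rng)
mcs = place_mitral_cells(space, rng)
net = generate_network(space, mcs, rng, gc_per_mc_ratio=3)
print(f"base network: {net.n_mc} MCs, {net.n_gc} GCs")

n_glom = len(space.glomeruli)
odsets = [np.array([i % n_glom, (i + 1) % n_glom]) for i in range(0, 8, 2)]
panel = make_odor_panel(net, np.random.default_rng(3), odsets)
print(f"odor panel: {panel.n_odors} odors x {len(odsets[0])} glomeruli")

print(f"\n{'mode':>10} {'rel. reduction':>15} {'frac. decorr.':>14} {'final GCs':>10}")
for mode in ("control", "baseline", "addition", "guided"):
    cfg = NeurogenesisConfig(mode=mode, rounds=3, target_ratio=5.0)
    out = exp_neurogenesis(net, np.random.default_rng(11), panel, cfg)
    print(f"{mode:>10} {out['mean_relative_reduction']:15.3f} "
          f"{out['fraction_decorrelated']:14.2f} {out['n_gc_final']:10d}")

print(
    "\n'rel. reduction' is the drop in odor-pair correlation relative to the\n"
    "initial value, averaged over pairs with initial correlation > 0.1.\n"
    "Adding GCs (with or without activity guidance) decorrelates without any\n"
    "cell death; random replacement changes little.  The printed full-scale\n"
    "configurations (916 MCs replacement / 864 MCs + 4,320 GCs addition, 10\n"
    "rounds, 10 trials) run the same code for several hours per mode."
)
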