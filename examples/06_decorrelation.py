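"""Odor-pattern decorrelation by the granule-cell network.

Presents overlapping odors as sniff-modulated sinusoidal currents, with
the GC network enabled and disabled (GABA conductance zeroed), and prints
how much the GCs reduce the Pearson correlation of windowed MC firing
rates at each window length.
"""

import numpy as np

from bulbnet.experiments import exp_decorrelation, make_odor_panel, sliding_odor_glomeruli
from bulbnet.netgen import generate_network
from bulbnet.placement import build_space, place_mitral_cells

rng = np.random.default_rng(3)
space = build_space(100.0, rng)
mcs = place_mitral_cells(space, rng)
net = generate_network(space, mcs, rng, gc_per_mc_ratio=3)
print(f"network: {net.n_mc} MCs, {net.n_gc} GCs")

n_glom = len(space.glomeruli)
glsets = sliding_odor_glomeruli(n_glom, n_odors=3, per_odor=3, stride=1)
panel = make_odor_panel(net, rng, glsets)
print(f"{panel.n_odors} odors over {n_glom} glomeruli; "
      f"overlap(0,1) = {panel.overlap(0, 1)} glomeruli")

out = exp_decorrelation(net, np.random.default_rng(4), panel=panel,
                        windows_ms=(5.0, 10.0, 20.0, 50.0, 100.0), n_sniffs=3)
print(f"\n{'window':>8} {'corr GC':>9} {'corr noGC':>10} {'decorrelation':>14}")
for w in out["windows_ms"]:
    by = out["by_window"][w]
    print(f"{w:6.0f}ms {np.nanmean(by['gc']):9.3f} "
          f"{np.nanmean(by['nogc']):10.3f} {out['decorrelation'][w]:14.3f}")
print(
    "\n'decorrelation' is corr(no GC) - corr(GC), averaged over odor pairs\n"
    "after the first sniff.  GCs reshape spike timing, so their effect\n"
    "concentrates at short windows (strongest below ~20 ms); long-window\n"
    "correlations instead track how many glomeruli the odors share."
)
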