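"""Odor-driven simulation with LFP recording and spectral analysis.

Builds a reduced bulb at the full 15:1 GC:MC ratio, drives a fifth of the
glomeruli with sniff-modulated Poisson OSN input, records the summed
point-source LFP at the EPL centre and prints the band structure of its
Welch spectrum (theta at the sniff frequency, beta from the reciprocal
MC-GC loop).
"""

import numpy as np

from bulbnet.analysis import lfp_spectrum
from bulbnet.dynamics import Protocol, make_osn_drive, run_simulation
from bulbnet.netgen import generate_network
from bulbnet.placement import build_space, place_mitral_cells

rng = np.random.default_rng(7)
space = build_space(120.0, rng)
mcs = place_mitral_cells(space, rng)
net = generate_network(space, mcs, rng, gc_per_mc_ratio=15, progress=True)
print(f"network: {net.n_mc} MCs, {net.n_gc} GCs, {len(net.synapses)} synapses")

osn = make_osn_drive(net, rng, odor_fraction=0.2)
proto = Protocol(duration=900.0, padding=100.0, osn=osn, record_lfp=True)
res = run_simulation(net, proto, rng)
print(f"{len(res.mc_spikes)} MC spikes, {len(res.gc_spikes)} GC spikes in 900 ms")

freqs, power = lfp_spectrum(res.lfp)
low = (freqs >= 2) & (freqs <= 12)
mid = (freqs >= 10) & (freqs <= 100)
print(f"theta-range peak: {freqs[low][np.argmax(power[low])]:.1f} Hz "
      "(sniff-locked respiration rhythm)")
print(f"oscillatory peak 10-100 Hz: {freqs[mid][np.argmax(power[mid])]:.1f} Hz")
for lo, hi, name in [(2, 12, "theta"), (15, 40, "beta"), (40, 100, "gamma")]:
    sel = (freqs >= lo) & (freqs < hi)
    print(f"  mean {name} power [{lo}-{hi} Hz]: {power[sel].mean():.3g}")
print(
    "\nAt the anatomical GC:MC ratio the reciprocal dendrodendritic loop\n"
    "concentrates oscillatory power in the beta range on top of the theta\n"
    "sniff rhythm.  Masking most GCs as inactive (gc_active_mask) models\n"
    "tonic inhibition; in the full-size bulb that shifts the peak into the\n"
    "gamma band."
)
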