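# bulbnet

An anatomically grounded, large-scale spiking model of the mammalian
olfactory bulb.  The package is for computational neuroscientists who want
bulb networks whose mitral-cell/granule-cell connectivity follows from
measured dendritic geometry — not from random or ad-hoc distance rules —
and who need the resulting dynamics (lateral inhibition, odor
decorrelation, LFP rhythms, cortical feedback, neurogenesis) to be
reproducible and fast enough to run at scale on one machine.

## The model

**Connectivity from geometry.**  A mitral cell's lateral dendrites are a
radially symmetric length density on a disk,

ρ_m(r) = (αk / 2πr) / (1 + (kr − tan m)²),   f(r) = α·tan⁻¹(kr − tan m) + mα,

parameterised by where the dendritic mass peaks and how much sits at the
centre.  A granule cell's spines live on an inverted oblique cone with a
parabolic vertical density N_s(z); dividing by the cone cross-section
gives the volumetric density ρ_g(z).  For a cell pair, the dendritic
length L in the disk–cone overlap is the integral of ρ_m over the
intersection lens (nine case-wise regimes, reduced to one-dimensional
quadrature via the closed form f).  Wrapping the dendrite in an
interaction sheath of cross-section q ≈ 2.32 μm² gives the expected
synapse count

λ = ρ_g(z_m) · qπL · (1 − N_ps·V_spine / V_tot),

where the last factor discounts sheath volume already occupied by earlier
synapses, and the connection probability is P = 1 − e^(−λ).  Granule
cells are wired one at a time under their spine budgets until the bulb
reaches 15 deep GCs per MC; a radius-600 μm bulb yields ≈178 glomeruli,
≈3,550 MCs and ≈53,250 GCs.

**Dynamics.**  Cells are Izhikevich units (class II mitral cells,
integrator granule cells with b < 0, which gives closed forms for
rheobase and input resistance); synapses are reciprocal AMPA/NMDA → GC
and distance-attenuated GABA → MC with first-order gating, a
second-order κ rule for network-driven inhibition, and sniff-modulated
Poisson OSN drive.  Integration is forward Euler at 0.1 ms.  The LFP is
the inverse-distance-weighted sum of synaptic currents, analysed with
Butterworth filtering and Welch spectra.

## A worked example

```python
import numpy as np
from bulbnet import build_space, place_mitral_cells, generate_network, network_statistics

rng = np.random.default_rng(42)
space = build_space(120.0, rng)            # 120-um bulb, 157 glomeruli/mm^2
mcs = place_mitral_cells(space, rng)       # 15-25 MCs per glomerulus
net = generate_network(space, mcs, rng, gc_per_mc_ratio=3)
print(net.n_mc, net.n_gc, len(net.synapses))
stats = network_statistics(net, rng=np.random.default_rng(0))
print(round(stats["mc_degree_mean_type1"], 1), round(stats["mc_degree_mean_type2"], 1))
print(round(stats["sister_shared_fraction_mean"], 3))
```

prints

```
149 447 7540    # cells and synapses wired from the geometry
61.1 30.4       # type I MCs (deep disks) out-connect type II MCs
0.155           # sister MCs share few GCs despite a common glomerulus
```

The `examples/` directory has one short script per
capability: connection probability (`01`), network building (`02`),
single-cell physiology (`03`), odor-driven LFP spectra (`04`), lateral
inhibition (`05`), decorrelation (`06`) and neurogenesis (`07`).  Each
builds a reduced bulb, runs the method and prints what the numbers mean.

A thin CLI wraps the same library:

```bash
bulbnet generate --scale tiny --seed 1 --out network.h5
bulbnet simulate network.h5 --duration 900 --out run/
bulbnet lfp run/lfp.tsv --out spectrum.tsv
bulbnet stats network.h5
bulbnet experiment lateral-inhibition network.h5 --out li/
```

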