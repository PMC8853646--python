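# Methods

## Model overview

`bulbnet` builds a spiking network model of the mammalian olfactory bulb in
which connectivity is derived from cell-scale anatomy rather than assumed.
The bulb is a thin three-layer cylinder (internal plexiform layer, mitral
cell layer, external plexiform layer, default thicknesses 27/36/131 μm).
Mitral cells (MCs) carry their lateral dendrites as a radially symmetric
length density on a flat disk; granule cells (GCs) carry their spines on an
inverted oblique cone.  The expected number of dendrodendritic synapses for
an MC–GC pair follows from integrating the MC density over the disk–cone
intersection and multiplying by the local volumetric spine density; a
Poisson model turns the expectation into a connection probability.  Cells
are simulated as Izhikevich units coupled through reciprocal
AMPA/NMDA (MC→GC) and GABA_A (GC→MC) synapses, integrated by forward Euler.

Units project-wide: μm, ms, mV, pA, nS, pF, GΩ (so GΩ·pA = mV and
nS·mV = pA without conversion factors).

## Dendritic density models

The cumulative dendritic length of an MC within radius *r* is
f(r) = α·atan(kr − tan m) + mα, giving the area density
ρ_m(r) = (αk/2πr)/(1 + (kr − tan m)²) on 0 < r ≤ r_max.  Rather than
exposing (α, k, m) directly, profiles are parameterised by interpretable
shape variables: `gamma_peak` (fraction of r_max where df/dr peaks,
sampled U(0.2, 0.3)), `xi_center` (relative df/dr at the centre,
U(1/3, 4/5)) and `w` (total length per field area, U(0.00255, 0.00510)
μm⁻¹, so f(r_max) = wπr_max²).  The closed-form inversion to (α, k, m) is
exact and tested against the normalization ∫ρ_m dA = wπr_max².

GC spines follow a parabolic vertical density N_s(z) integrating to the
cell's total spine count S, divided by the cone cross-section to give the
volumetric density ρ_g(z).  ρ_g diverges at the cone vertex; evaluation is
clamped to z₀ + 1 μm.  This affects only pairs whose disk passes within a
micron of a vertex and keeps synapse expectations finite.  Only spines
above the EPL floor can reach MC dendrites, so each GC's wiring budget is
S_available = ∫_EPL N_s dz (closed-form cubic), and a GC whose cone tops
out below the EPL floor can make no synapses.

## Overlap integrals

The dendritic length L inside the lens where the disk meets the cone
cross-section splits into nine regimes by the separation s and radii
(r_m, r_g): edge contact, chord, annular band, circle-inside-disk,
centre-covered, disk-inside-circle, and their boundaries.  Because ρ_m is
radially symmetric, the inner radial integral is f(r)/2π in closed form;
only a one-dimensional quadrature in the polar angle remains.  That
quadrature uses 96-node Gauss–Legendre (the integrands are smooth except
for square-root corners at lens tips), keeping |ΔL| well below the 10⁻³ μm
working tolerance at ~70 μs per pair.  Every regime is validated against a
Monte-Carlo rejection oracle (inverse-CDF radial sampling of the dendritic
mass, scored against the circle) to within three standard errors, and
continuity is checked across all regime boundaries.

## Expected synapses and wiring

A dendrite of total length f(r_m) is wrapped in an interaction sheath of
cross-section q = (d_shell + r_dend)² − r_dend² ≈ 2.32 μm²
(d_shell = 1.02 μm spine diameter, r_dend = 0.63 μm dendrite radius).  The
pair expectation is λ = ρ_g(z_m) · qπL · (1 − N_ps·V_spine/V_tot): spines
already occupying the sheath (N_ps, volume V_spine = 0.58 μm³ each)
discount the free volume.  P(connect) = 1 − e^(−λ), capped at one synapse
per pair.

GCs are generated one at a time and offered to every vertically and
radially overlapping MC in a freshly shuffled order; accepted connections
immediately increment the MC's occupancy.  If a GC accepts more
connections than its spine budget, a uniformly random subset of budget
size is kept and the affected MCs' occupancy is rolled back, so occupancy
always equals realized degree.  Fully disconnected GCs are discarded
without counting toward the target of `ratio` GCs per MC (default 15).
Synapse positions are drawn from the overlap lens with radial density
proportional to ρ_m (synapses sit on dendrite); an area-uniform
alternative is available by configuration.  The recorded radial distance
drives the GABA attenuation term during simulation.

A distance-independent control mode replaces the geometric probability
with one constant for every MC–GC pair (calibrated to a reference
network's mean degree) and places synapses on the full disk; it reproduces
near-Gaussian degree distributions and distance-flat shared-GC counts,
against which the geometric network's skewed degrees and distance-falling
overlap are contrasted.

## Cell placement

Glomerular projections scatter uniformly in the disk at 157/mm² (1800
glomeruli over a 1.5 mm³ EPL of thickness 131 μm).  Each glomerulus
anchors U{15..25} sister MCs whose somata are offset by a truncated
logistic law (μ = 78.4, s = 23.1, support [0, 300] μm) in a uniform
direction.  Disk radii are U(75, 800) μm.  Two thirds of MCs are type I
(disks in the lower half of the EPL); the rest are type II (disks in the
2/5–4/5 band), which makes type II cells overlap deep-GC cones less and
accounts for their lower degree.  GC cones have vertices uniform in the
MCL+IPL, faces in the top half of the EPL with U(0, 50) μm obliquity, face
radii from Normal(83, 28) truncated to [30, 160] μm, and spine counts
uniform between the two cone-volume-dependent bounds a·atan(bV)
(lower: a = 39.31, b = 1.043e−5; upper: a = 357.7, b = 2.653e−6).
Truncated laws use inverse-CDF restriction rather than rejection, for
reproducibility and speed.  All sampling flows through one seeded
`numpy.random.Generator` in documented order (glomeruli → per-glomerulus
MCs → GCs in creation order).

The bulb is flat; disks may extend past the lateral boundary and are not
clipped (edge cells simply reach fewer GCs).  A periodic boundary option
wraps xy distances.

## Dynamics

Izhikevich parameters (means): MC C=191 pF, k=2.5, a=0.02, b=12, c=−70,
d=13, v_r=−58, v_t=−49, v_c=30; GC C=48, k=0.067, a=0.01, b=−0.133,
c=−75, d=2, v_r=−71, v_t=−39, v_c=25.  Per-cell heterogeneity: every
parameter ~ Normal(mean, |mean|/10) except GC (b, k), drawn jointly at
sd = 2|mean|/3 and resampled until b < 0 and the implied rheobase
ρ = kD²/4 and input resistance R = 1/(kD) (D = b/k − (v_r − v_t)) fall in
[10, 70] pA and [0.25, 1.5] GΩ.  If an extreme (v_r, v_t) draw makes that
window unreachable (≈1 cell in 2000), the whole parameter set is redrawn
rather than failing the build.  The MC parameters produce class II
excitability (discontinuous f–I onset) and ≈70 Hz at 700 pA; the GC is an
integrator whose simulated rheobase matches the closed-form value within
one 1-pA grid step.

Synapses: AMPA I = s·g·(V − E_e); NMDA adds the magnesium-block factor
1/(1 + [Mg]e^(−0.062V)/3.57) at [Mg] = 1 mM; GABA
I = s·g·(V − E_i)·e^(−L/λ) with λ = 675 μm and L the synapse's dendritic
distance.  Gating: first-order decay for AMPA (τ 5.5 ms) and GABA (18 ms);
NMDA uses a rise gate n (τ_rise 10 ms) feeding ds/dt = −s/τ_decay +
αn(1 − s) (τ_decay 80 ms, α = 0.1/ms).  An MC spike applies
s ← s + W(1 − s) (W = 0.5) to the AMPA and n gates of all its synapses,
and — the κ rule — a small increment κW (κ = 0.006) to the GABA gates of
every synapse of every GC it touches, standing in for network-driven GC
activity.  By default the spiker's own synapses are included in the κ
update (the rule is defined through shared GCs, and the spiker trivially
shares its GCs with itself); one switch excludes the spiker's own
synapses and another disables κ entirely.  A GC spike
applies the full W increment to the GABA gates of its synapses.
Simultaneous increments compound multiplicatively
(s ← 1 − (1 − s)(1 − κW)^count), identical to sequential application.

OSN input is 100 independent Poisson synapses per MC with Table-style fast
parameters (g_AMPA 6.7 nS, g_NMDA 12 nS, τ_AMPA 14.3 ms, NMDA 13/70 ms,
α 0.03/ms), rate r(t) = r_max/2 + (r_max/4)(sin(2πft − φ) + 1) at the
6 Hz sniff frequency, so r ∈ [r_max/2, r_max] with mean 3r_max/4.
Odor-receiving glomeruli draw their rate scale from U(2, 3) Hz, background
from U(0, 0.25) Hz; sister MCs share their glomerulus's scale and phase up
to Normal(·, x_g/10) and Normal(·, π/4) jitter.  Poisson thinning uses
r·dt, valid at these rates.

Integration is forward Euler at dt = 0.1 ms: gather currents, sample the
LFP, advance gating, step all cells, then test v ≥ v_c (post-update),
reset, and apply spike-triggered gating updates; spike times are stamped
at the step end.  Halving dt leaves protocol outcomes essentially
unchanged (checked in the suite).  Silenced GCs (tonic-inhibition masks)
never emit spikes and their synaptic currents are zeroed.

## LFP and analysis

The LFP is the point-source sum φ = Σ_s I_s/(4πσ|r_e − r_s|) over synaptic
currents, σ = 1/300 (Ω·cm)⁻¹, with a 1 μm minimum-distance clamp; the
electrode defaults to the xy-centre at half EPL height.  OSN-synapse
currents (located at the MC soma) are included by default alongside
dendrodendritic currents; a switch restricts the sum to MC–GC synapses,
since either reading of "every synapse" is defensible.  Spectra come from
a 6th-order 200 Hz low-pass Butterworth (zero-phase), linear detrend,
200 ms transient discard, and Welch estimation with 400 ms windows at 50%
overlap.

Firing-rate matrices count spikes in sliding windows (50% overlap);
odor-pair similarity is the per-window Pearson correlation across cells,
summarised as the mean over windows after the first sniff.  Windows where
either rate vector has zero variance are excluded from the summary
(Pearson is undefined there) rather than scored zero.  Distance profiles
(shared GCs, lateral-inhibition strength) are fit with a·exp(−bxⁿ) by
nonlinear least squares.

## Protocols

*Lateral inhibition* — pairs with GC degree within 75 of the population
mean and |Δz| ≤ 5 μm; cell A gets 700 pA DC for 1 s (100 ms unrecorded
settling), then A + B (750 pA); Δrate = rate_alone − rate_paired, binned
over 100 μm distance bins.  Each pair is simulated on the exact
two-MC subnetwork (the pair plus every GC connected to either), which
reproduces the pair's dynamics exactly while all other MCs are silent.

*Decorrelation* — six odors of 30 glomeruli with 5–25 shared; overlapping
glomeruli receive identical strength (U(400, 600) pA scale) and phase;
6 sniffs; the GC-disabled condition zeroes g_GABA with everything else
held fixed; decorrelation = corr(noGC) − corr(GC) per window length over
the default grid {2, 5, 10, 20, 50, 100} ms.

*Feedback to GCs* — one 35-glomerulus odor, 2 sniffs, second analysed;
50 pA DC to 0.1–20% of GCs; three trials (two disjoint sets in the same
network, one set in a regenerated GC arrangement around identical MCs);
mean windowed Pearson correlation between odor-receiving-MC rate-change
vectors, same- vs cross-network.

*Feedback to MCs* — Normal(200, 20) pA DC to a random 20% of MCs during
odor input; Δrate against GC degree, split by odor-receiving status.

*Neurogenesis* — per round: simulate every odor of a 10×8-glomerulus
panel (2 sniffs), summarise pair correlations (5 ms windows, second
sniff), then apply the mode: control replaces a random 25% of GCs;
baseline replaces the least-active 25% (ties broken uniformly at random);
addition adds (15·n_MC − n_GC0)/rounds randomly placed GCs per round;
guided addition samples a target MC with probability proportional to its
summed firing and places each new GC within r_max/10 of its centre,
resampling the cone (bounded tries) until it spans the target's disk
height, then falls back to an unguided draw.  New GCs wire through the
standard generator; removal rolls back MC occupancy.  Scored pairs are
those with initial correlation > 0.1.

## Problem sizes

The full-size configuration (radius 600 μm → ≈178 glomeruli, ≈3,550 MCs,
53,250 GCs) is a preset; building it means ≈10⁸ pair evaluations and is a
multi-hour single-CPU job, as are the 10-trial full-scale protocol runs.
The test-suite and examples therefore use reduced bulbs — radius 100–150 μm
(≈100–225 MCs) at ratios 3–15 — and sub-second to one-second simulations,
sizes chosen so the whole suite runs in minutes while still exercising
every code path at realistic cell densities.  Network-level assertions at
this scale target properties that do not depend on absolute size:
degree-distribution shape and type ordering, sister-vs-nonsister overlap
ordering, distance dependence vs the distance-independent control,
theta/beta LFP structure, inhibition sign and falloff, and neurogenesis
accounting.  Printed full-scale quantities (mean degree 1225.8, sister
fraction 0.13, gamma-band peaks, the four neurogenesis percentages) are
expected only from the full-size presets.

## Known limitations

- Tufted cells and superficial GCs are not modeled; their absence likely
  depresses type II MC connectivity relative to a complete bulb.
- The bulb is flat (no curvature) and does not grow during neurogenesis.
- Synaptic strengths are static: no plasticity, and GABA release is
  strictly spike-triggered apart from the κ shortcut.
- The reduced-scale rhythm tests reproduce theta and beta; the
  gamma-frequency regime under sparse GC activity emerges only at much
  larger network sizes than the suite builds.
- MC disks are planes: the disk's vertical extent is ignored when
  intersecting cones, consistent with treating ρ_g as constant across the
  disk thickness.
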