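import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulbnet.morphology import GranuleMorphology, LayerStack
from bulbnet.netgen import Network, Synapse
from bulbnet.placement import GranuleCell, MitralCell, OBSpace
from bulbnet.dynamics import (
    DD_RECEPTORS,
    GC_PARAMS,
    MC_PARAMS,
    OSNDrive,
    Protocol,
    advance_gating,
    fi_curve,
    gc_excitability_from_bk,
    bk_from_excitability,
    izhikevich_step,
    osn_rate,
    receptor_current,
    run_simulation,
    sample_cell_params,
    simulate_single_cell,
)

from .conftest import make_profile


class TestIzhikevichStep:
    def test_rest_is_fixed_point(self):
        v, u, spiked = izhikevich_step(MC_PARAMS.v_r, 0.0, MC_PARAMS, 0.0, 0.1)
        assert v == MC_PARAMS.v_r and u == 0.0 and not spiked

    def test_reset_rule(self):
        v, u, spiked = izhikevich_step(MC_PARAMS.v_c + 1.0, 5.0, MC_PARAMS, 0.0, 0.1)
        assert spiked
        assert v == MC_PARAMS.c  # -70
        assert u > 5.0 + MC_PARAMS.d - 1.0  # jumped by d (plus the Euler increment)

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            izhikevich_step(-60.0, 0.0, MC_PARAMS, 0.0, 0.0)

    def test_mc_rate_at_700pa(self):
        """Table-mean MC at 700 pA DC fires at ~70 Hz (forward Euler, 0.1 ms)."""
        spikes = simulate_single_cell(MC_PARAMS, 700.0)
        assert spikes == pytest.approx(70, abs=7)

    def test_class_two_onset(self):
        """The MC f-I curve jumps discontinuously from 0 to a nonzero floor."""
        rates = fi_curve(MC_PARAMS, np.arange(0, 301, 25))
        nonzero = rates[rates > 0]
        assert len(nonzero) > 0
        assert nonzero[0] >= 8.0  # no continuous ramp from zero


class TestGCExcitability:
    def test_reference_inversion(self):
        R, rho = gc_excitability_from_bk(-0.133, 0.067, -71.0, -39.0)
        assert rho == pytest.approx(15.1, abs=0.05)
        assert R == pytest.approx(0.497, abs=0.002)
        assert 10.0 <= rho <= 70.0 and 0.25 <= R <= 1.5

    def test_round_trip(self):
        R, rho = gc_excitability_from_bk(-0.133, 0.067, -71.0, -39.0)
        b, k = bk_from_excitability(R, rho, -71.0, -39.0)
        assert b == pytest.approx(-0.133, rel=1e-10)
        assert k == pytest.approx(0.067, rel=1e-10)

    def test_no_solution_signal(self):
        # b/k more negative than v_t - v_r leaves no positive rheobase
        with pytest.raises(ValueError):
            gc_excitability_from_bk(-3.0, 0.067, -71.0, -39.0)

    def test_simulated_rheobase_matches_analytic(self):
        """Spiking onset of the mean GC lies within one 1-pA grid step of 15.1."""
        _, rho = gc_excitability_from_bk(GC_PARAMS.b, GC_PARAMS.k, GC_PARAMS.v_r, GC_PARAMS.v_t)
        grid = np.arange(10.0, 25.0, 1.0)
        spikes = np.array(
            [simulate_single_cell(GC_PARAMS, I, duration=1000.0, padding=500.0) for I in grid]
        )
        onset = grid[np.argmax(spikes > 0)]
        assert abs(onset - rho) <= 1.0

    def test_sampled_gcs_satisfy_windows(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            p = sample_cell_params("GC", rng)
            assert p.b < 0
            R, rho = gc_excitability_from_bk(p.b, p.k, p.v_r, p.v_t)
            assert 10.0 <= rho <= 70.0
            assert 0.25 <= R <= 1.5

    def test_sampled_mcs_near_means(self):
        rng = np.random.default_rng(7)
        cs = [sample_cell_params("MC", rng).C for _ in range(400)]
        assert np.mean(cs) == pytest.approx(191.0, abs=3 * 19.1 / math.sqrt(400))


class TestReceptorCurrents:
    def test_zero_gating_zero_current(self):
        for cls in ("AMPA", "NMDA", "GABA"):
            assert receptor_current(cls, 0.0, -58.0) == 0.0

    def test_magnesium_block_values(self):
        # block factor 1/(1 + Mg e^{-0.062V}/3.57)
        i0 = receptor_current("NMDA", 1.0, 0.0)
        assert i0 == 0.0  # V = E_e
        block_0 = 1.0 / (1.0 + 1.0 / 3.57)
        assert block_0 == pytest.approx(0.781, abs=1e-3)
        i = receptor_current("NMDA", 1.0, -58.0)
        expected = DD_RECEPTORS.g_nmda * (-58.0) * (
            1.0 / (1.0 + math.exp(0.062 * 58.0) / 3.57)
        )
        assert i == pytest.approx(expected, rel=1e-12)
        assert 1.0 / (1.0 + math.exp(0.062 * 58.0) / 3.57) == pytest.approx(0.089, abs=2e-3)

    def test_gaba_dendritic_attenuation(self):
        near = receptor_current("GABA", 1.0, -58.0, dendritic_distance=0.0)
        far = receptor_current("GABA", 1.0, -58.0, dendritic_distance=675.0)
        assert far / near == pytest.approx(math.exp(-1.0), rel=1e-12)


class TestGating:
    def test_exponential_decay_time_constant(self):
        s_a, s_g, s_n, n = 0.0, 1.0, 0.0, 0.0
        dt = 0.01
        for _ in range(int(18.0 / dt)):
            s_a, s_g, s_n, n = advance_gating(s_a, s_g, s_n, n, dt)
        assert s_g == pytest.approx(math.exp(-1.0), abs=2e-3)

    def test_nmda_pure_decay_without_n(self):
        s_a, s_g, s_n, n = 0.0, 0.0, 0.8, 0.0
        s_a, s_g, s_n2, n = advance_gating(s_a, s_g, s_n, n, 0.1)
        assert s_n2 == pytest.approx(0.8 * (1 - 0.1 / 80.0), rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.floats(0.05, 5.0)), min_size=1, max_size=60))
    def test_bounded_under_arbitrary_event_sequences(self, events):
        """Gating variables stay in [0,1] for any decay/increment interleaving."""
        s = np.array([0.0, 0.0, 0.0, 0.0])  # ampa, gaba, nmda, n
        W = 0.5
        for kind, dt in events:
            s = np.array(advance_gating(*s, dt))
            if kind == 1:  # MC spike: AMPA + NMDA channel opening
                s[0] += W * (1 - s[0])
                s[3] += W * (1 - s[3])
            elif kind == 2:  # GC spike
                s[1] += W * (1 - s[1])
            elif kind == 3:  # second-order kappa increment
                s[1] += 0.006 * W * (1 - s[1])
            assert np.all(s >= -1e-12) and np.all(s <= 1.0 + 1e-12)


class TestOSNDrive:
    def test_rate_bounds_and_mean(self):
        drive = OSNDrive(r_max=np.array([2.4]), phase=np.array([0.3]))
        ts = np.linspace(0, 1000.0, 6001)
        r = np.array([osn_rate(drive, t)[0] for t in ts])
        assert r.min() >= 2.4 / 2 - 1e-9
        assert r.max() <= 2.4 + 1e-9
        assert r.mean() == pytest.approx(3 * 2.4 / 4, rel=5e-3)


def _toy_network(n_mc=1, n_gc=1, gaba_distance=10.0):
    """n_mc mitral cells fully reciprocally connected to n_gc granule cells."""
    space = OBSpace(radius=100.0, glomeruli=np.zeros((1, 2)))
    mcs = [
        MitralCell(id=i, glomerulus=0, xy=(0.0, 0.0),
                   morphology=make_profile(r_max=100.0, z_m=100.0))
        for i in range(n_mc)
    ]
    gcs, syns = [], []
    for g in range(n_gc):
        morph = GranuleMorphology(
            vertex_xy=(0.0, 0.0), face_center_xy=(0.0, 0.0), r_max=80.0,
            z0=40.0, z_max=180.0, S=100.0, S_available=100.0,
        )
        gcs.append(GranuleCell(id=g, morphology=morph))
        for i in range(n_mc):
            syns.append(
                Synapse(mc_id=i, gc_id=g, location=(gaba_distance, 0.0, 100.0),
                        dendritic_distance=gaba_distance)
            )
    return Network(space=space, mitral_cells=mcs, granule_cells=gcs, synapses=syns)


class TestNetworkSimulation:
    def test_empty_network_stays_silent(self):
        net = Network(
            space=OBSpace(radius=10.0, glomeruli=np.empty((0, 2))),
            mitral_cells=[], granule_cells=[], synapses=[],
        )
        res = run_simulation(net, Protocol(duration=50.0, padding=0.0),
                             np.random.default_rng(0))
        assert res.mc_spikes == [] and res.gc_spikes == []

    def test_reciprocal_loop_inhibits_mc(self):
        """GC feedback slows the MCs; zeroing g_GABA restores the lone-cell rate."""
        net = _toy_network(n_mc=5, n_gc=30)
        mc_p = [MC_PARAMS] * 5
        gc_p = [GC_PARAMS] * net.n_gc
        kw = dict(dt=0.1, mc_params=mc_p, gc_params=gc_p)
        drive = np.full(5, 700.0)
        r_coupled = run_simulation(
            net, Protocol(duration=500.0, padding=100.0, mc_current=drive),
            np.random.default_rng(1), **kw)
        r_nogaba = run_simulation(
            net, Protocol(duration=500.0, padding=100.0, mc_current=drive, gaba_scale=0.0),
            np.random.default_rng(1), **kw)
        lone = simulate_single_cell(MC_PARAMS, 700.0, duration=500.0)
        n_coupled = len(r_coupled.mc_spikes)
        n_nogaba = len(r_nogaba.mc_spikes)
        assert n_nogaba == 5 * lone  # GABA off => independent Izhikevich units
        assert n_coupled < n_nogaba  # reciprocal inhibition engaged
        assert len(r_coupled.gc_spikes) > 0  # the MCs recruited their GCs

    def test_inactive_gcs_never_spike(self):
        net = _toy_network(n_mc=5, n_gc=10)
        res = run_simulation(
            net,
            Protocol(duration=400.0, padding=50.0, mc_current=np.full(5, 700.0),
                     gc_active_mask=np.zeros(10, dtype=bool)),
            np.random.default_rng(2),
            mc_params=[MC_PARAMS] * 5, gc_params=[GC_PARAMS] * 10,
        )
        assert res.gc_spikes == []

    def test_dt_halving_keeps_rates_stable(self):
        """Halving the Euler step leaves coupled firing rates nearly unchanged."""
        net = _toy_network(n_mc=5, n_gc=20)
        kw = dict(mc_params=[MC_PARAMS] * 5, gc_params=[GC_PARAMS] * 20)
        proto = Protocol(duration=500.0, padding=100.0, mc_current=np.full(5, 600.0))
        n1 = len(run_simulation(net, proto, np.random.default_rng(3), dt=0.1, **kw).mc_spikes)
        n2 = len(run_simulation(net, proto, np.random.default_rng(3), dt=0.05, **kw).mc_spikes)
        assert n2 == pytest.approx(n1, rel=0.2, abs=2)
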