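"""Protocol-level tests at miniature scale (small bulb, short simulations).

These exercise the full experiment pipelines end to end and assert the
scale-robust properties: inhibition is inhibitory and distance-ordered,
identical odors stay perfectly correlated, feedback bookkeeping is exact,
and neurogenesis modes respect their population accounting.
"""

import numpy as np
import pytest

from bulbnet.experiments import (
    NeurogenesisConfig,
    exp_decorrelation,
    exp_gc_feedback,
    exp_lateral_inhibition,
    exp_mc_feedback,
    exp_neurogenesis,
    make_odor_panel,
    odor_current_fn,
    select_mc_pairs,
    sliding_odor_glomeruli,
    subnetwork,
)
from bulbnet.netgen import generate_network
from bulbnet.placement import build_space, place_mitral_cells


@pytest.fixture(scope="module")
def mini_net():
    rng = np.random.default_rng(3)
    space = build_space(100.0, rng)
    mcs = place_mitral_cells(space, rng)
    return generate_network(space, mcs, rng, gc_per_mc_ratio=3)


class TestSubnetwork:
    def test_subnetwork_is_exact_restriction(self, tiny_net):
        sub, gc_ids = subnetwork(tiny_net, [0, 1])
        assert sub.n_mc == 2
        deg = tiny_net.mc_degrees()
        assert sub.mc_degrees()[0] == deg[0]
        assert sub.mc_degrees()[1] == deg[1]
        # every retained GC connects to at least one of the two MCs
        assert (sub.gc_degrees() > 0).all()


class TestLateralInhibition:
    def test_pair_selection_filters(self, tiny_net):
        pairs = select_mc_pairs(tiny_net, np.random.default_rng(0), 10,
                                degree_tol=75.0, dz_tol=5.0)
        deg = tiny_net.mc_degrees()
        z = np.array([mc.z for mc in tiny_net.mitral_cells])
        for a, b in pairs:
            assert abs(deg[a] - deg.mean()) <= 75.0
            assert abs(z[a] - z[b]) <= 5.0

    def test_inhibition_is_inhibitory_on_average(self, tiny_net):
        """Co-activating a GC-coupled partner lowers the probe MC's rate."""
        out = exp_lateral_inhibition(
            tiny_net, np.random.default_rng(1), n_pairs=8,
            duration=500.0, padding=100.0, n_bins=2, fit=False,
        )
        deltas = [r["delta_rate"] for r in out["pairs"]]
        rates = [r["rate_alone"] for r in out["pairs"]]
        assert np.mean(rates) > 30.0  # cells are firing under 700 pA
        assert np.mean(deltas) >= 0.0

    def test_too_strict_filter_raises(self, tiny_net):
        with pytest.raises(ValueError):
            select_mc_pairs(tiny_net, np.random.default_rng(0), 5, degree_tol=-1.0)


class TestDecorrelation:
    def test_identical_odors_fully_correlated_without_gcs(self, mini_net):
        """Two odors targeting the same glomeruli are perfectly correlated."""
        n_glom = len(mini_net.space.glomeruli)
        gl = np.arange(min(2, n_glom))
        panel = make_odor_panel(mini_net, np.random.default_rng(2), [gl, gl])
        # overlapping (here: all) glomeruli share strength and phase exactly
        gloms = np.array([mc.glomerulus for mc in mini_net.mitral_cells])
        tgt = np.isin(gloms, gl)
        assert np.allclose(panel.mc_I0[0][tgt], panel.mc_I0[1][tgt])
        assert np.allclose(panel.mc_phase[0][tgt], panel.mc_phase[1][tgt])
        out = exp_decorrelation(
            mini_net, np.random.default_rng(2), panel=panel,
            windows_ms=(20.0, 100.0), n_sniffs=2,
        )
        # identical targeted input; background differs, so correlation is
        # high but need not be exactly 1 across all cells
        for w in (20.0, 100.0):
            assert np.nanmean(out["by_window"][w]["nogc"]) > 0.5

    def test_gc_network_decorrelates_at_short_windows(self, mini_net):
        glsets = sliding_odor_glomeruli(len(mini_net.space.glomeruli),
                                        n_odors=2, per_odor=3, stride=2)
        out = exp_decorrelation(
            mini_net, np.random.default_rng(4), panel=make_odor_panel(
                mini_net, np.random.default_rng(4), glsets),
            windows_ms=(5.0, 100.0), n_sniffs=2,
        )
        assert set(out["decorrelation"]) == {5.0, 100.0}
        for v in out["decorrelation"].values():
            assert np.isfinite(v)


class TestGCFeedback:
    def test_same_vs_cross_network_structure(self, mini_net):
        rng = np.random.default_rng(5)
        mcs_copy = [type(mc)(id=mc.id, glomerulus=mc.glomerulus, xy=mc.xy,
                             morphology=mc.morphology) for mc in mini_net.mitral_cells]
        alt = generate_network(mini_net.space, mcs_copy, np.random.default_rng(99),
                               gc_per_mc_ratio=3)
        out = exp_gc_feedback(
            mini_net, alt, rng, levels=(0.1, 0.2), n_odor_glomeruli=3,
            n_sniffs=2, feedback_pa=50.0,
        )
        for v in out["same_network"] + out["cross_network"]:
            assert np.isnan(v) or -1.0 <= v <= 1.0
        assert len(out["same_network"]) == 2

    def test_oversized_level_rejected(self, mini_net):
        with pytest.raises(ValueError):
            exp_gc_feedback(mini_net, mini_net, np.random.default_rng(0),
                            levels=(0.6,), n_odor_glomeruli=2, n_sniffs=1)


class TestMCFeedback:
    def test_targeting_and_bookkeeping(self, mini_net):
        rows = exp_mc_feedback(
            mini_net, np.random.default_rng(6), fraction=0.2, n_trials=1,
            n_odor_glomeruli=3, n_sniffs=2,
        )
        n_target = max(int(round(0.2 * mini_net.n_mc)), 1)
        assert len(rows) == n_target
        deg = mini_net.mc_degrees()
        for r in rows:
            assert r["feedback_pa"] >= 0.0
            assert r["gc_degree"] == deg[r["mc_id"]]
        # feedback excites on average
        assert np.mean([r["delta_rate"] for r in rows]) > 0.0


@pytest.fixture(scope="module")
def panel(mini_net):
    n_glom = len(mini_net.space.glomeruli)
    odsets = [np.array([i % n_glom, (i + 1) % n_glom]) for i in range(0, 8, 2)]
    return make_odor_panel(mini_net, np.random.default_rng(3), odsets)


class TestNeurogenesis:

    def test_control_conserves_population(self, mini_net, panel):
        out = exp_neurogenesis(
            mini_net, np.random.default_rng(11), panel,
            NeurogenesisConfig(mode="control", rounds=2, target_ratio=5.0),
        )
        assert out["n_gc_final"] == mini_net.n_gc
        assert len(out["history"]) == 3

    def test_addition_grows_by_schedule(self, mini_net, panel):
        cfg = NeurogenesisConfig(mode="addition", rounds=2, target_ratio=5.0)
        out = exp_neurogenesis(mini_net, np.random.default_rng(11), panel, cfg)
        per_round = int(round((5.0 * mini_net.n_mc - mini_net.n_gc) / 2))
        assert out["n_gc_final"] == mini_net.n_gc + 2 * per_round

    def test_guided_mode_prefers_active_mcs(self, mini_net, panel):
        out = exp_neurogenesis(
            mini_net, np.random.default_rng(11), panel,
            NeurogenesisConfig(mode="guided", rounds=2, target_ratio=5.0),
        )
        assert out["n_gc_final"] > mini_net.n_gc
        # anatomy constrains newcomers: well-connected MCs keep gaining
        from scipy import stats
        rho = stats.spearmanr(out["initial_mc_degree"], out["degree_change"])
        assert rho.statistic > 0.0

    def test_baseline_removes_least_active(self, mini_net, panel):
        out = exp_neurogenesis(
            mini_net, np.random.default_rng(11), panel,
            NeurogenesisConfig(mode="baseline", rounds=1, target_ratio=5.0),
        )
        assert out["n_gc_final"] == mini_net.n_gc

    def test_unknown_mode_rejected(self, mini_net, panel):
        with pytest.raises(ValueError):
            exp_neurogenesis(
                mini_net, np.random.default_rng(0), panel,
                NeurogenesisConfig(mode="apoptosis", rounds=1),
            )
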