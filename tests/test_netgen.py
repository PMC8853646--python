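import math

import numpy as np
import pytest
from scipy import stats

from bulbnet.netgen import (
    calibrate_constant_probability,
    generate_network,
    network_statistics,
    sample_synapse_location,
    shared_gc_by_distance,
)
from bulbnet.placement import build_space, place_mitral_cells


@pytest.fixture(scope="module")
def di_net(tiny_net):
    """Distance-independent control with the same cells and mean degree."""
    rng = np.random.default_rng(43)
    space = build_space(120.0, rng)
    mcs = place_mitral_cells(space, rng)
    p = calibrate_constant_probability(tiny_net)
    return generate_network(
        space, mcs, rng, gc_per_mc_ratio=3, mode="distance_independent", p_constant=p
    )


class TestWiringInvariants:
    def test_degree_conservation(self, tiny_net):
        assert tiny_net.mc_degrees().sum() == len(tiny_net.synapses)
        assert tiny_net.gc_degrees().sum() == len(tiny_net.synapses)

    def test_target_gc_count(self, tiny_net):
        assert tiny_net.n_gc == 3 * tiny_net.n_mc

    def test_no_disconnected_gcs(self, tiny_net):
        assert (tiny_net.gc_degrees() > 0).all()

    def test_spine_budget_respected(self, tiny_net):
        deg = tiny_net.gc_degrees()
        for gc in tiny_net.granule_cells:
            assert deg[gc.id] <= gc.morphology.S_available

    def test_occupancy_matches_degree(self, tiny_net):
        deg = tiny_net.mc_degrees()
        for mc in tiny_net.mitral_cells:
            assert mc.n_preexisting == deg[mc.id]

    def test_at_most_one_synapse_per_pair(self, tiny_net):
        pairs = [(s.mc_id, s.gc_id) for s in tiny_net.synapses]
        assert len(pairs) == len(set(pairs))

    def test_synapse_geometry(self, tiny_net):
        """Synapses sit on the MC disk inside the GC cone cross-section."""
        for s in tiny_net.synapses[::25]:
            mc = tiny_net.mitral_cells[s.mc_id]
            gc = tiny_net.granule_cells[s.gc_id].morphology
            x, y, z = s.location
            assert z == pytest.approx(mc.z)
            r = math.hypot(x - mc.xy[0], y - mc.xy[1])
            assert r == pytest.approx(s.dendritic_distance, abs=1e-9)
            assert s.dendritic_distance <= mc.morphology.r_max + 1e-9
            assert gc.z0 < z <= gc.z_max
            t = (z - gc.z0) / (gc.z_max - gc.z0)
            cx, cy = gc.center_xy_at(z)
            assert math.hypot(x - cx, y - cy) <= gc.r_max * t + 1e-6

    def test_bad_ratio_raises(self, tiny_net):
        with pytest.raises(ValueError):
            generate_network(
                tiny_net.space, tiny_net.mitral_cells,
                np.random.default_rng(0), gc_per_mc_ratio=0,
            )


class TestDegreeStructure:
    def test_type_one_connects_more(self, tiny_net):
        s = network_statistics(tiny_net, rng=np.random.default_rng(0))
        assert s["mc_degree_mean_type1"] > s["mc_degree_mean_type2"]

    def test_sister_overlap_exceeds_nonsister(self, tiny_net):
        s = network_statistics(tiny_net, rng=np.random.default_rng(0))
        assert s["sister_shared_fraction_mean"] > s["nonsister_shared_fraction_mean"]
        assert 0.0 < s["sister_shared_fraction_mean"] < 1.0

    def test_shared_gcs_decrease_with_distance(self, tiny_net):
        """Geometric wiring: shared-GC count falls off with inter-soma distance."""
        rng = np.random.default_rng(1)
        centers, means, counts = shared_gc_by_distance(
            tiny_net, bin_width=60.0, n_bins=6, rng=rng, max_pairs=4000
        )
        valid = counts > 10
        assert means[valid][0] > means[valid][-1]
        d, m = centers[valid], means[valid]
        assert stats.spearmanr(d, m).statistic < 0

    def test_distance_independent_is_flat(self, di_net):
        """S2 control: shared-GC count does not fall with distance."""
        rng = np.random.default_rng(1)
        centers, means, counts = shared_gc_by_distance(
            di_net, bin_width=60.0, n_bins=6, rng=rng, max_pairs=4000
        )
        valid = counts > 10
        m = means[valid]
        # flat within 25% of the overall mean, no systematic decay
        assert np.all(np.abs(m - m.mean()) < 0.25 * m.mean() + 1.0)

    def test_distance_independent_degrees_near_normal(self, di_net):
        """S2 control: MC degrees approximately Gaussian (low skewness)."""
        deg = di_net.mc_degrees().astype(float)
        geo_skew = stats.skew
        assert abs(geo_skew(deg)) < 0.75

    def test_geometric_mc_degrees_right_skewed(self, tiny_net):
        deg = tiny_net.mc_degrees().astype(float)
        assert stats.skew(deg) > 0.5


class TestSynapseLocationSampler:
    @pytest.mark.parametrize("offset", [0.0, 20.0])
    def test_radial_density_follows_dendrite(self, tiny_net, offset):
        """In a containment case the radial CDF matches f(r)/f(r_max) (KS)."""
        from bulbnet.morphology import GranuleMorphology, mc_cumulative_length
        from bulbnet.placement import GranuleCell, MitralCell

        from .conftest import make_profile

        # a small disk entirely inside a wide cone cross-section
        mc = MitralCell(id=0, glomerulus=0, xy=(0.0, 0.0),
                        morphology=make_profile(r_max=90.0, z_m=100.0))
        # cone radius at z=100 is 200*(100-40)/(130-40) = 133 um, so the
        # 90-um disk is fully contained for both offsets (s + r_m <= r_g)
        gc = GranuleCell(id=0, morphology=GranuleMorphology(
            vertex_xy=(offset, 0.0), face_center_xy=(offset, 0.0),
            r_max=200.0, z0=40.0, z_max=130.0, S=500.0, S_available=400.0,
        ))
        rng = np.random.default_rng(2)
        rs = np.array(
            [
                sample_synapse_location(mc, gc, tiny_net.space, rng)[1]
                for _ in range(3000)
            ]
        )
        f_tot = mc_cumulative_length(mc.morphology.r_max, mc.morphology)
        u = mc_cumulative_length(rs, mc.morphology) / f_tot
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_disjoint_pair_raises(self, tiny_net):
        from bulbnet.morphology import GranuleMorphology
        from bulbnet.placement import GranuleCell

        mc = tiny_net.mitral_cells[0]
        far_gc = GranuleCell(
            id=0,
            morphology=GranuleMorphology(
                vertex_xy=(10_000.0, 0.0), face_center_xy=(10_000.0, 0.0),
                r_max=80.0, z0=10.0, z_max=190.0, S=100.0, S_available=100.0,
            ),
        )
        with pytest.raises(ValueError):
            sample_synapse_location(mc, far_gc, tiny_net.space, np.random.default_rng(0))
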