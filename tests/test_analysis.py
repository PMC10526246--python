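import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dpdshear as d
from dpdshear.analysis import (
    classify_phase,
    cluster_beads,
    density_map_2d,
    density_profile,
    gyration_eigenvalues,
    gyration_tensor,
    mean_shape_factor,
    mixing_counts,
    segment_stages,
    shape_factor,
    unwrap_chain,
)
from dpdshear.builder import minimum_image


def _rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestDensity:
    def test_uniform_water_density_near_rho(self, ff):
        spec = d.SystemSpec(box_length=10.0, n_lipids=0, seed=9)
        system, _ = d.build_system(spec, ff)
        prof = density_profile(system, "z", 10)
        # each bin holds ~300 beads; 3 sigma Poisson band around rho = 3
        sigma = np.sqrt(300) / 100.0
        assert np.all(np.abs(prof.density["W"] - 3.0) < 3 * sigma + 0.05)

    def test_profiles_integrate_to_bead_counts(self, classifier_spec):
        system, _ = d.make_fixture("flat_bilayer", classifier_spec)
        prof = density_profile(system, "z", 37)
        for label in ("H1", "T1", "W", "H2", "T2"):
            expected = int(np.sum(system.species == d.forcefield.SPECIES_INDEX[label]))
            assert prof.integrate(label) == pytest.approx(expected, abs=1e-8)

    def test_empty_species_subset_is_zero(self, classifier_spec):
        system, _ = d.make_fixture("flat_bilayer", classifier_spec.replace(n_lipids=4))
        prof = density_profile(system, "z", 10, species=["T2"])
        assert prof.integrate("T2") == pytest.approx(
            int(np.sum(system.species == 4)), abs=1e-8
        )

    def test_2d_map_sees_the_pore(self, classifier_spec):
        holed, _ = d.make_fixture("perforated_bilayer", classifier_spec, hole_radius=3.0)
        flat, _ = d.make_fixture("flat_bilayer", classifier_spec)
        # 2-rc cells: wider than the fixture's chain lattice spacing, so only
        # a genuine pore (diameter 6 rc) empties a cell
        m_holed = density_map_2d(holed, "xy", 8, species=["H1", "T1", "H2", "T2"])
        m_flat = density_map_2d(flat, "xy", 8, species=["H1", "T1", "H2", "T2"])
        occ_holed = sum(m_holed.values())
        occ_flat = sum(m_flat.values())
        assert np.sum(occ_holed == 0) > 0
        assert np.sum(occ_flat == 0) == 0

    def test_bin_count_validation(self, classifier_spec):
        system, _ = d.make_fixture("flat_bilayer", classifier_spec)
        with pytest.raises(ValueError):
            density_profile(system, "z", 1)


class TestGyration:
    def test_single_bead_zero_tensor(self):
        g = gyration_tensor(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(g, 0.0)
        assert shape_factor(gyration_eigenvalues(g)) == 0.0

    def test_two_beads_on_axis(self):
        g = gyration_tensor(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
        assert g[0, 0] == pytest.approx(1.0)  # d^2/4 with d=2
        assert np.abs(g - np.diag([1.0, 0, 0])).max() < 1e-12

    def test_matches_double_sum_form(self):
        """Tensor about the centroid equals the O(N^2) pair double-sum form:
        Rg2_ab = (1 / 2 N^2) sum_ij (ri_a - rj_a)(ri_b - rj_b)."""
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(17, 3))
        g = gyration_tensor(coords)
        n = len(coords)
        brute = np.zeros((3, 3))
        for i in range(n):
            for j in range(n):
                dv = coords[i] - coords[j]
                brute += np.outer(dv, dv)
        brute /= 2 * n * n
        assert np.abs(g - brute).max() < 1e-12

    def test_isotropic_eigenvalues_give_zero(self):
        assert shape_factor(np.array([2.0, 2.0, 2.0])) == pytest.approx(0.0)

    def test_collinear_chain_gives_one(self):
        coords = np.linspace(0, 5, 9)[:, None] * np.array([1.0, 0, 0])
        delta = shape_factor(gyration_eigenvalues(gyration_tensor(coords)))
        assert delta == pytest.approx(1.0)

    def test_planar_ring_value(self):
        th = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        ring = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
        delta = shape_factor(gyration_eigenvalues(gyration_tensor(ring)))
        assert delta == pytest.approx(0.25, abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(12, 3))
        delta = shape_factor(gyration_eigenvalues(gyration_tensor(coords)))
        assert 0.0 <= delta <= 1.0
        moved = coords @ _rotation(rng).T + rng.normal(size=3)
        delta2 = shape_factor(gyration_eigenvalues(gyration_tensor(moved)))
        assert abs(delta - delta2) < 1e-10

    def test_unwrap_crosses_boundary(self):
        box = 10.0
        wrapped = np.array([[9.5, 1.0, 1.0], [0.2, 1.0, 1.0], [0.9, 1.0, 1.0]])
        un = unwrap_chain(wrapped, box)
        np.testing.assert_allclose(un[:, 0], [9.5, 10.2, 10.9])

    def test_straight_chains_give_series_of_ones(self, ff, classifier_spec):
        system, topo = d.make_fixture("flat_bilayer", classifier_spec.replace(n_lipids=40))
        series = mean_shape_factor([system], topo)
        assert np.allclose(series.per_chain, 1.0)
        assert series.stable_mean(0) == pytest.approx(1.0)
        assert series.stable_mean_pooled() == pytest.approx(1.0)


class TestMixing:
    @pytest.fixture(scope="class")
    def full_scale_bilayer(self):
        spec = d.SystemSpec(
            box_length=30.0, n_lipids=2400,
            lipid_I=d.lipid_type_I(2), lipid_II=d.lipid_type_II(4), seed=0,
        )
        return d.make_fixture("flat_bilayer", spec)

    def test_initial_two_leaflet_counts(self, full_scale_bilayer):
        system, topo = full_scale_bilayer
        mc = mixing_counts(system, topo)
        assert (mc.n_type_I_right, mc.n_type_II_left) == (1200, 1200)
        assert mc.n_type_I == mc.n_type_II == 1200

    def test_counts_drop_by_constructed_translocations(self, full_scale_bilayer):
        system, topo = full_scale_bilayer
        system = system.copy()
        mc0 = mixing_counts(system, topo)
        k = 9
        moved = 0
        for c in range(topo.n_chains):
            if topo.chain_type[c] == 0 and moved < k:
                head = topo.chain_start[c]
                system.positions[head, 2] = mc0.midplane - 2.0
                moved += 1
        mc = mixing_counts(system, topo, normal_axis="z")
        assert mc.n_type_I_right == 1200 - k
        assert mc.n_type_II_left == 1200

    def test_mirror_symmetry(self, full_scale_bilayer):
        system, topo = full_scale_bilayer
        mirrored = system.copy()
        mirrored.positions[:, 2] = (-mirrored.positions[:, 2]) % mirrored.box
        mc = mixing_counts(mirrored, topo, normal_axis="z")
        # mirroring moves every type-I chain to the left and type-II right
        assert mc.n_type_I_right == 0
        assert mc.n_type_II_left == 0

    def test_complement_conservation(self, full_scale_bilayer):
        system, topo = full_scale_bilayer
        mc = mixing_counts(system, topo)
        left_I = mc.n_type_I - mc.n_type_I_right
        assert left_I + mc.n_type_I_right == 1200


class TestClustering:
    def test_single_chain_single_cluster(self):
        pos = np.linspace(0, 3, 10)[:, None] * np.array([1.0, 0, 0]) + 5.0
        cs = cluster_beads(pos, 20.0, cutoff=0.5)
        assert cs.n_clusters == 1

    def test_two_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (20, 3)) + 2.0
        b = rng.uniform(0, 1, (20, 3)) + 10.0
        cs = cluster_beads(np.vstack([a, b]), 20.0, cutoff=1.0)
        assert cs.n_clusters == 2
        assert sorted(cs.sizes) == [20, 20]

    def test_group_straddling_boundary_is_one_cluster(self):
        """Oracle: brute-force minimum-image pairwise connectivity."""
        box = 10.0
        pos = np.array([[9.6, 5, 5], [9.9, 5, 5], [0.2, 5, 5], [0.5, 5, 5]])
        cs = cluster_beads(pos, box, cutoff=0.5)
        assert cs.n_clusters == 1
        # brute-force oracle
        n = len(pos)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                dv = minimum_image(pos[i] - pos[j], box)
                adj[i, j] = np.linalg.norm(dv) <= 0.5
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(adj)
        assert n_comp == cs.n_clusters

    def test_agreement_with_brute_force_on_random_system(self):
        rng = np.random.default_rng(7)
        box, cutoff = 8.0, 0.9
        pos = rng.uniform(0, box, (300, 3))
        cs = cluster_beads(pos, box, cutoff)
        n = len(pos)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            dv = minimum_image(pos - pos[i], box)
            adj[i] = np.linalg.norm(dv, axis=1) <= cutoff
        from scipy.sparse.csgraph import connected_components

        n_comp, labels = connected_components(adj)
        assert n_comp == cs.n_clusters
        # identical partitions up to relabeling
        mapping = {}
        for a, b in zip(labels, cs.labels):
            assert mapping.setdefault(a, b) == b

    def test_periodic_spanning_detection(self):
        box = 10.0
        xs = np.arange(0, 10, 0.5)
        pos = np.stack([xs, np.full_like(xs, 5.0), np.full_like(xs, 5.0)], axis=1)
        cs = cluster_beads(pos, box, cutoff=0.6)
        assert cs.n_clusters == 1
        assert cs.spans[0].tolist() == [True, False, False]


class TestClassifier:
    @pytest.mark.parametrize(
        "kind, expected",
        [
            ("flat_bilayer", "DL"),
            ("perforated_bilayer", "PDL"),
            ("spherical_micelle", "micelle"),
            ("vesicle_shell", "vesicle"),
            ("stacked_discs", "HD"),
            ("cylindrical_micelle", "micelle"),
        ],
    )
    def test_fixture_labels(self, classifier_spec, kind, expected):
        spec = classifier_spec
        if kind == "vesicle_shell":
            spec = spec.replace(
                lipid_I=d.lipid_type_I(2), lipid_II=d.lipid_type_II(2), n_lipids=500
            )
        system, topo = d.make_fixture(kind, spec)
        assert classify_phase(system, topo).label == expected

    def test_classifier_permutation_invariant(self, classifier_spec):
        system, topo = d.make_fixture("spherical_micelle", classifier_spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(system.n_beads)
        shuffled = d.ParticleSystem(
            system.positions[perm], system.velocities[perm], system.species[perm],
            system.box, system.time,
        )
        # labels only depend on geometry + species, not bead order
        assert classify_phase(shuffled, topo).label == classify_phase(system, topo).label

    def test_no_lipids_unclassified(self, ff):
        spec = d.SystemSpec(box_length=6.0, n_lipids=0, seed=0)
        system, topo = d.build_system(spec, ff)
        assert classify_phase(system, topo).label == "unclassified"


class TestStages:
    def test_two_segment_series(self):
        t = np.linspace(0, 3000, 600)
        y = np.where(t < 800, 100 - 0.1 * t, 20 - 0.002 * (t - 800))
        seg = segment_stages(t, y)
        assert seg.n_stages == 2
        assert seg.boundaries[0] == pytest.approx(800, abs=30)

    def test_three_segment_noisy_series(self):
        t = np.linspace(0, 3000, 600)
        y = np.piecewise(
            t,
            [t < 750, (t >= 750) & (t < 1780), t >= 1780],
            [lambda x: 100 - 0.08 * x, lambda x: 40 - 0.01 * (x - 750), lambda x: 29.7 + 0 * x],
        )
        y = y + np.random.default_rng(0).normal(0, 0.3, len(t))
        seg = segment_stages(t, y)
        assert seg.n_stages == 3
        assert seg.boundaries[0] == pytest.approx(750, abs=100)
        assert seg.boundaries[1] == pytest.approx(1780, abs=150)

    def test_constant_series_single_stage(self):
        t = np.linspace(0, 100, 200)
        seg = segment_stages(t, np.full(200, 7.0))
        assert seg.n_stages == 1
        assert seg.warning is not None

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            segment_stages(np.arange(10), np.arange(10.0))
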