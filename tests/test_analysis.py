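"""Trajectory statistics against independent brute-force oracles and
closed-form values."""

import numpy as np
import pytest
from scipy import stats

from sbstraffic.analysis import (
    binder_exclusion,
    binder_occupancy,
    bound_fraction,
    contact_matrix,
    correspondence,
    coverage,
    gyration_and_density,
    kl_divergence,
    loop_traffic_ratio,
    traffic_profile,
)
from sbstraffic.model import PolymerTopology, SimulationConfig, Trajectory

from conftest import (
    brute_contact_matrix,
    brute_cross_counts,
    pairwise_dist,
    synthetic_trajectory,
)


def _manual_trajectory(mono, binders, tracers, L=50.0, anchors=(), n_snapshots=1):
    """Single- or repeated-snapshot trajectory from explicit coordinates."""
    mono = np.asarray(mono, float)
    binders = np.asarray(binders, float).reshape(-1, 3) if len(binders) else np.empty((0, 3))
    tracers = np.asarray(tracers, float).reshape(-1, 3) if len(tracers) else np.empty((0, 3))
    N = len(mono)
    topo = PolymerTopology(n_monomers=N, anchor_indices=tuple(anchors),
                           phi=max(len(anchors), 0.25) / N if anchors else 0.25 / N)
    config = SimulationConfig(
        topology=topo, epsilon=1.0, n_tracers=len(tracers), box_edge=L,
        n_equil=0, n_total=n_snapshots, sample_every=1, seed=0,
        include_binders=bool(len(binders)),
    )
    if config.n_binders != len(binders):
        raise ValueError("binder count must be 2x anchor count")
    pos = np.vstack([mono, binders, tracers])
    positions = np.repeat(pos[None, :, :], n_snapshots, axis=0)
    return Trajectory(positions=positions, steps=np.arange(1, n_snapshots + 1),
                      species=config.species_codes(), config=config)


class TestContactMatrix:
    def test_pair_within_threshold_counts_once(self):
        mono = [[25, 25, 25], [10, 10, 10], [40, 40, 40], [25, 26.5, 25]]
        traj = _manual_trajectory(mono, [], [])
        cm = contact_matrix(traj, t=2.0)
        assert cm.H[0, 3] == 1 and cm.H[3, 0] == 1
        assert cm.H.sum() == 2

    def test_pair_beyond_threshold_does_not_count(self):
        mono = [[25, 25, 25], [10, 10, 10], [40, 40, 40], [25, 27.5, 25]]
        traj = _manual_trajectory(mono, [], [])
        assert contact_matrix(traj, t=2.0).H.sum() == 0

    def test_contact_through_periodic_boundary(self):
        mono = [[0.5, 0, 0], [10, 10, 10], [20, 20, 20], [49.0, 0, 0]]
        traj = _manual_trajectory(mono, [], [])
        cm = contact_matrix(traj, t=2.0)
        assert cm.H[0, 3] == 1  # wrapped distance 1.5

    def test_threshold_comparison_is_strict(self):
        mono = [[25, 25, 25], [10, 10, 10], [40, 40, 40], [25, 27.0, 25]]
        traj = _manual_trajectory(mono, [], [])
        assert contact_matrix(traj, t=2.0).H[0, 3] == 0

    def test_bonded_neighbors_excluded_by_default(self):
        mono = [[25, 25, 25], [26.2, 25, 25], [27.4, 25, 25]]
        traj = _manual_trajectory(mono, [], [])
        cm = contact_matrix(traj, t=2.0)
        assert cm.H.sum() == 0
        cm_incl = contact_matrix(traj, t=2.0, exclude_bonded=False)
        assert cm_incl.H[0, 1] == 1 and cm_incl.H[1, 2] == 1

    def test_snapshots_accumulate(self):
        mono = [[25, 25, 25], [10, 10, 10], [40, 40, 40], [25, 26.5, 25]]
        traj = _manual_trajectory(mono, [], [], n_snapshots=5)
        assert contact_matrix(traj, t=2.0).H[0, 3] == 5

    def test_row_sum_matches_matrix(self):
        traj = synthetic_trajectory(seed=5, N=25, box_edge=8.0)
        cm = contact_matrix(traj)
        assert np.array_equal(cm.row_sum, cm.H.sum(axis=1))

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_on_random_systems(self, seed):
        traj = synthetic_trajectory(seed=seed, N=20, n_tracers=5, box_edge=9.0,
                                    n_snapshots=4)
        cm = contact_matrix(traj, t=2.0)
        expect = sum(
            brute_contact_matrix(traj.positions[s, :20], traj.box_edge, 2.0)
            for s in range(4)
        )
        assert np.array_equal(cm.H, expect)


class TestTrafficProfile:
    def test_single_tracer_contact(self):
        mono = [[float(i), 25, 25] for i in range(20, 30)]
        tracer = [[25.0, 26.9, 25]]
        traj = _manual_trajectory(mono, [], tracer)
        tp = traffic_profile(traj, t=2.0)
        assert tp.C[5] == 1
        assert tp.C[[0, 1, 2, 8, 9]].sum() == 0

    def test_two_tracers_sum(self):
        mono = [[float(i), 25, 25] for i in range(20, 30)]
        tracers = [[25.0, 26.9, 25], [25.0, 23.1, 25]]
        traj = _manual_trajectory(mono, [], tracers)
        assert traffic_profile(traj, t=2.0).C[5] == 2

    def test_requires_tracers(self):
        traj = _manual_trajectory([[25, 25, 25], [30, 30, 30]], [], [])
        with pytest.raises(ValueError, match="tracer"):
            traffic_profile(traj)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_on_random_systems(self, seed):
        traj = synthetic_trajectory(seed=100 + seed, N=15, n_tracers=6,
                                    box_edge=8.0, n_snapshots=3)
        tp = traffic_profile(traj, t=2.0)
        tr = traj.tracer_slice
        expect = sum(
            brute_cross_counts(traj.positions[s, :15], traj.positions[s, tr],
                               traj.box_edge, 2.0)
            for s in range(3)
        )
        assert np.array_equal(tp.C, expect)


class TestKLDivergence:
    def test_identical_profiles_give_zero(self):
        c = np.array([3.0, 1.0, 2.0, 4.0])
        assert kl_divergence(c, 5 * c) == pytest.approx(0.0, abs=1e-15)

    def test_worked_example_half_half(self):
        got = kl_divergence(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        expect = 0.5 * np.log(0.5) + 0.5 * np.log(1.5)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(-0.1438410362258904, abs=1e-12)

    def test_worked_example_zero_term_convention(self):
        got = kl_divergence(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert got == pytest.approx(np.log(0.5), abs=1e-12)

    def test_never_positive(self, rng):
        for _ in range(50):
            c = rng.integers(0, 20, size=30).astype(float)
            r = rng.integers(0, 20, size=30).astype(float)
            if c.sum() == 0 or r.sum() == 0:
                continue
            assert kl_divergence(c, r) <= 1e-12

    def test_empty_support_in_r_handled_by_pseudocount(self):
        c = np.array([2.0, 2.0, 0.0])
        r = np.array([4.0, 0.0, 4.0])
        assert np.isfinite(kl_divergence(c, r))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.zeros(3), np.ones(3))


class TestCorrespondence:
    def test_scaled_profiles_perfectly_correspond(self):
        traj = synthetic_trajectory(seed=7, N=30, box_edge=9.0, n_snapshots=5)
        cm = contact_matrix(traj)
        tp = traffic_profile(traj)
        tp.C = 2 * cm.row_sum  # force exact proportionality
        res = correspondence(cm, tp)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.d_kl == pytest.approx(0.0, abs=1e-12)

    def test_reversed_profile_anticorrelates(self):
        traj = synthetic_trajectory(seed=8, N=30, box_edge=9.0, n_snapshots=5)
        cm = contact_matrix(traj)
        tp = traffic_profile(traj)
        tp.C = cm.row_sum[::-1].copy() + np.arange(30)  # monotone vs reversed
        res = correspondence(cm, tp)
        if res.pearson_r is not None:
            corr_direct = stats.pearsonr(tp.C, cm.row_sum).statistic
            assert res.pearson_r == pytest.approx(corr_direct)

    def test_matches_two_pass_formula_on_random_profiles(self, rng):
        x = rng.integers(0, 50, 20).astype(float)
        y = rng.integers(0, 50, 20).astype(float)
        sx, sy = x - x.mean(), y - y.mean()
        expect = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        traj = synthetic_trajectory(seed=9, N=20, box_edge=9.0)
        cm = contact_matrix(traj)
        cm.H = np.diag(np.zeros(20)).astype(np.int64)  # row sums replaced below
        cm.H[0] = 0
        tp = traffic_profile(traj)
        tp.C = x.astype(np.int64)
        cm2 = cm
        cm2.H = np.zeros((20, 20), np.int64)
        cm2.H[np.arange(20), (np.arange(20) + 2) % 20] = y.astype(np.int64)
        res = correspondence(cm2, tp)
        assert res.pearson_r == pytest.approx(
            stats.pearsonr(x, cm2.row_sum).statistic
        )
        # and scipy itself agrees with the textbook two-pass formula
        assert stats.pearsonr(x, y).statistic == pytest.approx(expect)

    def test_zero_variance_reported_as_missing(self):
        traj = synthetic_trajectory(seed=10, N=10, box_edge=9.0)
        cm = contact_matrix(traj)
        cm.H = np.zeros((10, 10), np.int64)
        tp = traffic_profile(traj)
        tp.C = np.ones(10, np.int64)
        res = correspondence(cm, tp)
        assert res.pearson_r is None


class TestCoverage:
    def test_full_coverage(self):
        tp = traffic_profile(synthetic_trajectory(seed=11, N=10, box_edge=4.0,
                                                  n_tracers=20, n_snapshots=5))
        tp.C = np.ones(10, np.int64)
        assert coverage(tp) == 100.0

    def test_zero_coverage(self):
        tp = traffic_profile(synthetic_trajectory(seed=11, N=10, box_edge=4.0))
        tp.C = np.zeros(10, np.int64)
        assert coverage(tp) == 0.0

    def test_partial_coverage(self):
        tp = traffic_profile(synthetic_trajectory(seed=11, N=10, box_edge=4.0))
        tp.C = np.array([1, 3, 0, 0, 2, 0, 0, 0, 5, 0], np.int64)
        assert coverage(tp) == 40.0


class TestBinderExclusion:
    def test_disjoint_occupancy_is_negative(self):
        mono = [[20.0 + 1.2 * i, 25, 25] for i in range(10)]
        anchors = (0, 1)
        binders = [[20.0, 26.5, 25], [21.2, 26.5, 25],
                   [20.0, 23.5, 25], [21.2, 23.5, 25]]
        tracers = [[27.2 + 1.2, 26.5, 25], [29.6, 26.5, 25]]
        traj = _manual_trajectory(mono, binders, tracers, anchors=anchors)
        r = binder_exclusion(traj, t=2.0)
        assert r is not None and r < 0

    def test_proportional_profiles_give_unit_correlation(self):
        # tracer and two binders contact exactly the same monomer pair
        # (one from above, one from below); two more binders are far away
        mono = [[20.0 + 1.2 * i, 25, 25] for i in range(10)]
        anchors = (3, 4)
        tracers = [[24.2, 26.8, 25]]
        binders = [[24.2, 26.8, 25], [24.2, 23.2, 25],
                   [40.0, 40, 40], [42.0, 40, 40]]
        traj = _manual_trajectory(mono, binders, tracers, anchors=anchors)
        tp = traffic_profile(traj, t=2.0)
        bo = binder_occupancy(traj, t=2.0)
        assert np.array_equal(bo.C, 2 * tp.C)
        assert binder_exclusion(traj, t=2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_occupancy_equals_brute_force(self, seed):
        traj = synthetic_trajectory(seed=200 + seed, N=15, n_anchors=3,
                                    n_tracers=4, box_edge=8.0, n_snapshots=3)
        bo = binder_occupancy(traj, t=2.0)
        b = traj.binder_slice
        expect = sum(
            brute_cross_counts(traj.positions[s, :15], traj.positions[s, b],
                               traj.box_edge, 2.0)
            for s in range(3)
        )
        assert np.array_equal(bo.C, expect)


class TestGyrationAndDensity:
    def test_three_bead_rod(self):
        mono = [[24.0, 25, 25], [25.0, 25, 25], [26.0, 25, 25]]
        traj = _manual_trajectory(mono, [], [])
        r_gyr, rho = gyration_and_density(traj)
        assert r_gyr == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        assert rho == pytest.approx(3 * (1 / r_gyr) ** 3)

    def test_ring_of_known_radius(self):
        # 100 beads on a circle of radius 10: r_gyr = 10, rho = 0.1 N / 1000
        theta = 2 * np.pi * np.arange(100) / 100
        mono = np.stack([25 + 10 * np.cos(theta), 25 + 10 * np.sin(theta),
                         np.full(100, 25.0)], axis=1)
        traj = _manual_trajectory(mono, [], [])
        r_gyr, rho = gyration_and_density(traj)
        assert r_gyr == pytest.approx(10.0, rel=1e-9)
        assert rho == pytest.approx(100 * (1 / 10.0) ** 3)

    def test_unwrapping_handles_boundary_crossing(self):
        # straight chain crossing the periodic boundary
        xs = (np.arange(10) * 1.2 + 45.0) % 50.0
        mono = np.stack([xs, np.full(10, 25.0), np.full(10, 25.0)], axis=1)
        traj = _manual_trajectory(mono, [], [])
        r_gyr, _ = gyration_and_density(traj)
        straight = np.arange(10) * 1.2
        expect = np.sqrt(np.mean((straight - straight.mean()) ** 2))
        assert r_gyr == pytest.approx(expect, rel=1e-9)


class TestBoundFraction:
    def test_always_bound(self):
        mono = [[float(i) + 20, 25, 25] for i in range(10)]
        traj = _manual_trajectory(mono, [], [[25.0, 26.5, 25]], n_snapshots=4)
        assert bound_fraction(traj) == 100.0

    def test_never_bound(self):
        mono = [[float(i) + 20, 25, 25] for i in range(10)]
        traj = _manual_trajectory(mono, [], [[5.0, 5, 5]], n_snapshots=4)
        assert bound_fraction(traj) == 0.0

    def test_mixed_observations(self):
        mono = [[float(i) + 20, 25, 25] for i in range(10)]
        # tracer 1 bound, tracer 2 free, over 2 snapshots, then move t2 in
        traj = _manual_trajectory(mono, [], [[25.0, 26.5, 25], [5.0, 5, 5]],
                                  n_snapshots=2)
        traj.positions[1, 11] = [25.0, 23.5, 25.0]
        assert bound_fraction(traj) == pytest.approx(75.0)


class TestLoopTrafficRatio:
    def test_ratio_arithmetic(self):
        topo = PolymerTopology(n_monomers=20, anchor_indices=(5, 14), phi=0.1)
        from sbstraffic.analysis import TrafficProfile

        C = np.ones(20, np.int64)
        C[5] = C[14] = 6
        tp = TrafficProfile(C=C, n_snapshots=1, n_tracers=1)
        # interior: >= 5 from both anchors and the ends -> empty at halo 5
        ratio = loop_traffic_ratio(tp, topo, halo=3)
        assert ratio == pytest.approx(6.0)

    def test_no_interior_left_raises(self):
        topo = PolymerTopology(n_monomers=10, anchor_indices=(4, 5), phi=0.2)
        from sbstraffic.analysis import TrafficProfile

        tp = TrafficProfile(C=np.ones(10, np.int64), n_snapshots=1, n_tracers=1)
        with pytest.raises(ValueError):
            loop_traffic_ratio(tp, topo, halo=5)


class TestAgainstMDAnalysis:
    """Cross-check periodic distance handling against an established
    molecular-analysis library."""

    def test_distance_array_agreement(self):
        MDAnalysis = pytest.importorskip("MDAnalysis")
        from MDAnalysis.lib.distances import distance_array

        rng = np.random.default_rng(42)
        L = 20.0
        a = rng.uniform(0, L, (12, 3))
        b = rng.uniform(0, L, (8, 3))
        box = np.array([L, L, L, 90.0, 90.0, 90.0], dtype=np.float32)
        ours = pairwise_dist(a, b, L)
        theirs = distance_array(a.astype(np.float64), b.astype(np.float64), box=box)
        assert np.allclose(ours, theirs, atol=1e-5)

    def test_contact_counts_agree_with_mdanalysis_distances(self):
        MDAnalysis = pytest.importorskip("MDAnalysis")
        from MDAnalysis.lib.distances import distance_array

        traj = synthetic_trajectory(seed=77, N=18, n_tracers=6, box_edge=10.0,
                                    n_snapshots=2)
        tp = traffic_profile(traj, t=2.0)
        L = traj.box_edge
        box = np.array([L, L, L, 90.0, 90.0, 90.0], dtype=np.float32)
        tr = traj.tracer_slice
        expect = np.zeros(18, np.int64)
        for s in range(2):
            d = distance_array(traj.positions[s, :18], traj.positions[s, tr], box=box)
            expect += (d < 2.0).sum(axis=1)
        assert np.array_equal(tp.C, expect)
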