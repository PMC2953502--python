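import itertools

import numpy as np
import pytest

from foldpath import (
    Chain,
    ClusterDefinition,
    FixtureSpec,
    FoldingConfig,
    build_Q,
    closed_loop_matrix,
    compute_contact_map,
    connectivity_matrix,
    contact_events,
    cost_decay_series,
    effective_contact_order,
    fraction_contacts,
    lqr_cost_integrals,
    make_fixture,
    pair_distance_series,
    radius_of_gyration,
    run_folding,
    simulate_segment,
    solve_lqr,
    time_to_half_rg_gap,
)
from foldpath.folding_engine import FoldingTrajectory
from foldpath.lqr_synthesis import LQRProblem
from foldpath.observables import load_clusters, rg_series

TURN = ClusterDefinition("turn", (7, 12), (7, 12))
INTERHELIX = ClusterDefinition("interhelix", (1, 8), (13, 20))


def manual_trajectory(native, coords_per_time, times, config=None):
    """Hand-assembled trajectory from explicit absolute coordinates."""
    config = config or FoldingConfig()
    coords = np.asarray(coords_per_time, dtype=float)
    states = coords - native.coords[None]
    return FoldingTrajectory(
        native=native,
        times=np.asarray(times, dtype=float),
        states=states,
        contact_maps=[compute_contact_map(native, config.cutoff)],
        gains=[],
        cycle_times=np.array([0.0]),
        converged=True,
        cycles_used=0,
        config=config,
    )


class TestFractionContacts:
    def test_native_conformation_scores_one_everywhere(self, hairpin):
        traj = manual_trajectory(hairpin, [hairpin.coords, hairpin.coords], [0.0, 1.0])
        for cluster in (TURN, INTERHELIX):
            assert np.all(fraction_contacts(traj, cluster) == 1.0)

    def test_extended_start_has_no_nonlocal_contacts(self, hairpin_traj):
        f = fraction_contacts(hairpin_traj, INTERHELIX)
        assert f.iloc[0] == 0.0
        assert f.iloc[-1] == 1.0

    def test_nonnative_contacts_push_fraction_above_one(self):
        # region holds 2 native pairs; a squeezed conformation forms 3
        native = Chain(np.array(
            [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [7.6, 3.8, 0], [3.8, 3.8, 0]],
            dtype=float,
        ))
        region = ClusterDefinition("blob", (1, 5), (1, 5))
        native_map = compute_contact_map(native, 5.0)
        cluster_native = region.native_pairs(native_map)
        squeezed = native.coords * 0.6
        traj = manual_trajectory(native, [squeezed],
                                 [0.0], FoldingConfig(cutoff=5.0))
        f = fraction_contacts(traj, region)
        formed = compute_contact_map(Chain(squeezed), 5.0).pairs
        assert f.iloc[0] == pytest.approx(len(formed) / len(cluster_native))
        assert f.iloc[0] > 1.0

    def test_rigid_motion_leaves_fraction_unchanged(self, hairpin, hairpin_traj):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = manual_trajectory(
            Chain(hairpin.coords @ rot.T + 5.0),
            hairpin_traj.coordinates @ rot.T + 5.0,
            hairpin_traj.times,
        )
        np.testing.assert_allclose(
            fraction_contacts(moved, TURN).to_numpy(),
            fraction_contacts(hairpin_traj, TURN).to_numpy(),
        )

    def test_empty_cluster_rejected(self, hairpin_traj):
        lonely = ClusterDefinition("empty", (1, 2), (15, 16))
        with pytest.raises(ValueError, match="empty cluster"):
            fraction_contacts(hairpin_traj, lonely)

    def test_cluster_yaml_round_trip(self, tmp_path):
        path = tmp_path / "clusters.yaml"
        path.write_text(
            "clusters:\n"
            "  - {name: T2, i_start: 7, i_end: 12, j_start: 7, j_end: 12}\n"
            "  - {name: b1-4, i_start: 1, i_end: 8, j_start: 13, j_end: 20}\n"
        )
        clusters = load_clusters(path)
        assert [c.name for c in clusters] == ["T2", "b1-4"]
        assert clusters[1].j_range == (13, 20)


class TestContactEvents:
    def test_native_start_run_forms_everything_at_time_zero(self, hairpin):
        traj = manual_trajectory(hairpin, [hairpin.coords, hairpin.coords], [0.0, 1.0])
        events = contact_events(traj)
        native_pairs = compute_contact_map(hairpin, 7.0).pairs
        native_events = {e.pair for e in events if e.is_native}
        assert native_events == native_pairs
        assert all(e.t_init == 0.0 for e in events if e.is_native)

    def test_local_contacts_initiate_before_nonlocal(self, hairpin_traj):
        events = contact_events(hairpin_traj)
        local = [e.t_init for e in events if e.is_native and e.pair[1] - e.pair[0] <= 6]
        nonlocal_ = [e.t_init for e in events
                     if e.is_native and e.pair[1] - e.pair[0] >= 12]
        assert len(local) >= 5 and len(nonlocal_) >= 3
        assert np.median(local) < np.median(nonlocal_)

    def test_breaking_and_reforming_delays_completion(self):
        # pair (1, 3) formed at t=0, broken at t=1, re-formed from t=2 on
        native = Chain(np.array([[0, 0, 0], [3.8, 0, 0], [5.0, 3.0, 0]], dtype=float))
        apart = native.coords.copy()
        apart[2] = [20.0, 0, 0]
        traj = manual_trajectory(
            native, [native.coords, apart, native.coords, native.coords],
            [0.0, 1.0, 2.0, 3.0],
        )
        event = {e.pair: e for e in contact_events(traj)}[(1, 3)]
        assert event.t_init == 0.0
        assert event.t_complete == 2.0
        assert event.t_complete > event.t_init

    def test_converged_run_recovers_exactly_the_native_pair_set(self, hairpin, hairpin_traj):
        native_pairs = compute_contact_map(hairpin, 7.0).pairs
        events = contact_events(hairpin_traj)
        completed_native = {e.pair for e in events if e.is_native}
        assert completed_native == native_pairs

    def test_short_trajectory_rejected(self, hairpin):
        traj = manual_trajectory(hairpin, [hairpin.coords], [0.0])
        with pytest.raises(ValueError, match="2 recorded times"):
            contact_events(traj)


class TestRadiusOfGyration:
    def test_coincident_points_give_zero(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_two_points_give_half_distance(self):
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(3.0)

    def test_rigid_motion_invariance_and_dilation_scaling(self, hairpin, rng):
        base = radius_of_gyration(hairpin)
        theta = rng.uniform(0, np.pi)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        assert radius_of_gyration(hairpin.coords @ rot.T + 7.7) == pytest.approx(base)
        assert radius_of_gyration(2.5 * hairpin.coords) == pytest.approx(2.5 * base)

    def test_rg_approaches_native_value_on_converged_run(self, hairpin, hairpin_traj):
        series = rg_series(hairpin_traj)
        assert abs(series.iloc[-1] - radius_of_gyration(hairpin)) < 0.5
        assert time_to_half_rg_gap(hairpin_traj) > 0


class TestPairDistances:
    def test_native_start_is_constant_series(self, hairpin):
        traj = manual_trajectory(hairpin, [hairpin.coords] * 3, [0.0, 1.0, 2.0])
        series = pair_distance_series(traj, 2, 9)
        native_d = np.linalg.norm(hairpin.coords[1] - hairpin.coords[8])
        np.testing.assert_allclose(series.to_numpy(), native_d)

    def test_covalent_neighbours_start_at_virtual_bond_length(self, hairpin_traj):
        series = pair_distance_series(hairpin_traj, 4, 5)
        assert series.iloc[0] == pytest.approx(3.8)

    def test_native_contacts_end_within_cutoff(self, hairpin, hairpin_traj):
        for i, j in sorted(compute_contact_map(hairpin, 7.0).pairs)[:10]:
            assert pair_distance_series(hairpin_traj, i, j).iloc[-1] <= 7.0

    def test_out_of_range_indices_rejected(self, hairpin_traj):
        with pytest.raises(ValueError):
            pair_distance_series(hairpin_traj, 0, 5)


class TestCostDecay:
    def test_zero_deviation_costs_nothing(self, hairpin):
        config = FoldingConfig()
        cmap = compute_contact_map(hairpin, config.cutoff)
        gamma = connectivity_matrix(cmap)
        gain = solve_lqr(LQRProblem(gamma=gamma, Q=build_Q(cmap, config.epsilon),
                                    alpha=1.0, epsilon=config.epsilon))
        traj = FoldingTrajectory(
            native=hairpin, times=np.array([0.0, 1.0]),
            states=np.zeros((2, 20, 3)), contact_maps=[cmap], gains=[gain],
            cycle_times=np.array([0.0]), converged=True, cycles_used=1,
            config=config,
        )
        frame = cost_decay_series(traj)
        assert np.all(frame["state_term"] == 0) and np.all(frame["control_term"] == 0)

    def test_quadrature_matches_lyapunov_closed_form(self, hairpin):
        # one fixed controller simulated to near-extinction: integrating the
        # instantaneous series must reproduce the Lyapunov cost integrals
        config = FoldingConfig(alpha=1.0, epsilon=1e-2)
        cmap = compute_contact_map(hairpin, config.cutoff)
        gamma = connectivity_matrix(cmap)
        Q = build_Q(cmap, config.epsilon)
        gain = solve_lqr(LQRProblem(gamma=gamma, Q=Q, alpha=1.0, epsilon=1e-2))
        a_cl = closed_loop_matrix(gamma, gain)
        x0 = np.linspace(-1, 1, 60).reshape(20, 3)
        duration, dt = 400.0, 0.02
        times, states = simulate_segment(a_cl, x0, duration, dt)
        traj = FoldingTrajectory(
            native=hairpin, times=times, states=states, contact_maps=[cmap],
            gains=[gain], cycle_times=np.array([0.0]), converged=True,
            cycles_used=1, config=config,
        )
        frame = cost_decay_series(traj)
        state_ref, control_ref = lqr_cost_integrals(
            a_cl, gain.K, Q, np.eye(20), 1.0, x0
        )
        assert np.trapezoid(frame["state_term"], times) == pytest.approx(
            state_ref, rel=0.01
        )
        assert np.trapezoid(frame["control_term"], times) == pytest.approx(
            control_ref, rel=0.01
        )

    def test_smaller_alpha_decays_energy_faster(self, hairpin):
        def state_term_halving_time(alpha):
            traj = run_folding(hairpin, FoldingConfig(alpha=alpha, max_cycles=500))
            frame = cost_decay_series(traj)
            s = frame["state_term"].to_numpy()
            return frame["time"].to_numpy()[np.nonzero(s <= 0.5 * s[0])[0][0]]

        assert state_term_halving_time(0.1) < state_term_halving_time(1.0)


def brute_force_shortest_path(i, j, formed, n):
    """Exhaustive oracle: breadth over all simple paths via edge sets."""
    edges = {(k, k + 1) for k in range(1, n)} | {
        (min(a, b), max(a, b)) for a, b in formed
    }
    frontier, seen, depth = {i}, {i}, 0
    while frontier:
        if j in frontier:
            return depth
        nxt = set()
        for node in frontier:
            for a, b in edges:
                if a == node and b not in seen:
                    nxt.add(b)
                if b == node and a not in seen:
                    nxt.add(a)
        seen |= nxt
        frontier = nxt
        depth += 1
    raise AssertionError("path graph is always connected")


class TestEffectiveContactOrder:
    def test_no_contacts_reduces_to_contact_order(self):
        for i, j in [(1, 10), (3, 7), (5, 6)]:
            assert effective_contact_order(i, j, set(), 10) == j - i

    def test_single_shortcut_worked_example(self):
        # 1->3 (2 steps), 3->8 via the contact (1), 8->10 (2): ECO = 5
        assert effective_contact_order(1, 10, {(3, 8)}, 10) == 5

    def test_matches_exhaustive_enumeration_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            n_extra = int(rng.integers(0, 6))
            formed = set()
            while len(formed) < n_extra:
                i, j = sorted(rng.choice(np.arange(1, n + 1), 2, replace=False))
                if j > i + 1:
                    formed.add((int(i), int(j)))
            for i, j in itertools.combinations(range(1, n + 1), 2):
                assert effective_contact_order(i, j, formed, n) == \
                    brute_force_shortest_path(i, j, formed, n)

    def test_adding_contacts_never_increases_eco(self, rng):
        n = 12
        formed = set()
        pairs = [(i, j) for i, j in itertools.combinations(range(1, n + 1), 2)]
        previous = {p: effective_contact_order(*p, formed, n) for p in pairs}
        for _ in range(6):
            i, j = sorted(rng.choice(np.arange(1, n + 1), 2, replace=False))
            if j <= i + 1:
                continue
            formed.add((int(i), int(j)))
            current = {p: effective_contact_order(*p, formed, n) for p in pairs}
            assert all(current[p] <= previous[p] for p in pairs)
            previous = current
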