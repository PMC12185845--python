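import numpy as np
import pytest

from calyxpath import gate_dynamics as gd
from calyxpath import synthetic
from calyxpath.traj_io import Trajectory

from conftest import rigid_transform


def make_traj(coords_frames, topology, box=200.0):
    coords = np.asarray(coords_frames, dtype=float)
    n = coords.shape[0]
    return Trajectory(
        topology=topology,
        coordinates=coords,
        times=np.arange(n) * 0.2,
        box=np.tile([box, box, box], (n, 1)),
    )


@pytest.fixture(scope="module")
def scaffold():
    return synthetic._scaffold_topology(4)


class TestSuperpose:
    def test_rigid_motion_removed_exactly(self, binding_scenario):
        _, traj, _, _ = binding_scenario
        base = traj.slice_frames(slice(0, 5))
        moved = base.coordinates.copy()
        for f in range(1, 5):
            moved[f] = rigid_transform(
                base.coordinates[0], angle=0.3 * f, axis=[1, 2, 3],
                shift=[5.0 * f, -2.0, 1.0],
            )
        traj2 = Trajectory(
            topology=base.topology, coordinates=moved, times=base.times
        )
        sel = np.flatnonzero(base.topology.is_protein)
        sup = gd.superpose_frames(traj2, 0, sel)
        for f in range(5):
            np.testing.assert_allclose(
                sup.coordinates[f][sel], base.coordinates[0][sel], atol=1e-8
            )

    def test_identity_input_unchanged(self, binding_scenario):
        _, traj, _, _ = binding_scenario
        base = traj.slice_frames(slice(0, 3))
        same = Trajectory(
            topology=base.topology,
            coordinates=np.repeat(base.coordinates[:1], 3, axis=0),
            times=base.times,
        )
        sup = gd.superpose_frames(same, 0)
        np.testing.assert_allclose(sup.coordinates, same.coordinates, atol=1e-10)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(7)
        base = rng.random((20, 3)) * 10
        rotated = rigid_transform(base, angle=1.1, axis=[0.3, -1, 2], shift=[3, 4, 5])
        from calyxpath.gate_dynamics import _kabsch

        rot, mc, rc = _kabsch(rotated, base, np.ones(20))
        np.testing.assert_allclose((rotated - mc) @ rot.T + rc, base, atol=1e-8)

    def test_idempotence(self, binding_scenario):
        _, traj, _, _ = binding_scenario
        short = traj.slice_frames(slice(0, 10))
        once = gd.superpose_frames(short, 0)
        twice = gd.superpose_frames(once, 0)
        assert np.abs(twice.coordinates - once.coordinates).max() < 1e-8

    def test_collinear_selection_rejected(self, scaffold):
        coords = np.zeros((1, scaffold.n_atoms, 3))
        coords[0, :, 0] = np.arange(scaffold.n_atoms)  # all on the x axis
        traj = make_traj(coords, scaffold)
        with pytest.raises(ValueError, match="non-collinear"):
            gd.superpose_frames(traj, 0, np.array([0, 1, 2, 3]))


class TestComDistance:
    def test_3_4_5_triangle(self, scaffold):
        coords = np.zeros((1, scaffold.n_atoms, 3))
        coords[0, 1] = [3.0, 4.0, 0.0]
        traj = make_traj(coords, scaffold)
        trace = gd.com_distance_trace(traj, [0], [1])
        assert trace.values[0] == pytest.approx(5.0)

    def test_centroid_coincidence(self, scaffold):
        coords = np.zeros((1, scaffold.n_atoms, 3))
        coords[0, 0] = [0.0, 0.0, 0.0]
        coords[0, 1] = [2.0, 0.0, 0.0]
        coords[0, 2] = [1.0, 0.0, 0.0]
        traj = make_traj(coords, scaffold)
        # atoms 0,1 are both glycine CA (equal mass); COM at x=1
        trace = gd.com_distance_trace(traj, [0, 1], [2])
        assert trace.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_weighted_centroid(self, binding_scenario):
        _, traj, _, _ = binding_scenario
        rng = np.random.default_rng(2)
        ga = rng.choice(traj.topology.n_atoms, 5, replace=False)
        gb = rng.choice(traj.topology.n_atoms, 5, replace=False)
        trace = gd.com_distance_trace(traj, ga, gb)
        m = traj.topology.mass
        for f in (0, 100, 500):
            ca = sum(m[i] * traj.coordinates[f, i] for i in ga) / m[ga].sum()
            cb = sum(m[i] * traj.coordinates[f, i] for i in gb) / m[gb].sum()
            assert trace.values[f] == pytest.approx(
                np.linalg.norm(ca - cb), abs=1e-10
            )

    def test_empty_group_rejected(self, binding_scenario):
        _, traj, _, _ = binding_scenario
        with pytest.raises(ValueError, match="non-empty"):
            gd.com_distance_trace(traj, [], [0])


class TestGateDistance:
    def test_matches_generator_series(self, binding_scenario):
        _, traj, _, traces = binding_scenario
        trace = gd.gate_distance_trace(traj)
        np.testing.assert_allclose(trace.values, traces.gate, atol=1e-10)

    def test_missing_atoms_error_lists_candidates(self, peptide_topology):
        coords = np.zeros((1, peptide_topology.n_atoms, 3))
        traj = Trajectory(
            topology=peptide_topology, coordinates=coords, times=[0.0]
        )
        with pytest.raises(ValueError, match="cannot resolve gate atoms"):
            gd.gate_distance_trace(traj)


class TestClassifyGate:
    @pytest.mark.parametrize(
        "value,closed",
        [(3.39, True), (3.40, False), (0.0, True), (3.3999999, True)],
    )
    def test_strict_threshold(self, value, closed):
        trace = gd.DistanceTrace(
            times=[0.0], values=[value], definition="gate_y82_s34"
        )
        assert gd.classify_gate(trace)[0] == closed

    def test_alternating_series(self):
        vals = np.tile([3.0, 4.0], 25)
        trace = gd.DistanceTrace(
            times=np.arange(50.0), values=vals, definition="gate_y82_s34"
        )
        closed = gd.classify_gate(trace)
        assert closed.sum() == 25
        assert np.array_equal(closed, np.tile([True, False], 25))


class TestSolvation:
    def test_planted_counts_recovered(self, binding_scenario):
        spec, traj, _, traces = binding_scenario
        solv = gd.solvation_trace(traj, bulk_reference=spec.bulk_shell)
        expected = (
            np.clip(
                np.round(traces.solvation * spec.bulk_shell), 0, spec.n_waters
            ) / spec.bulk_shell
        )
        np.testing.assert_allclose(solv.fraction, expected, atol=1e-12)

    def test_step_b_level_near_60_percent(self, binding_scenario):
        spec, traj, states, _ = binding_scenario
        solv = gd.solvation_trace(traj, bulk_reference=spec.bulk_shell)
        b = states.states == "b_pocket_closed"
        e = states.states == "e_site_closed"
        assert solv.fraction[b].mean() == pytest.approx(0.60, abs=0.05)
        assert solv.fraction[e].mean() == pytest.approx(0.0, abs=0.1)

    def test_auto_reference_normalises_bulk_to_one(self):
        spec = synthetic.BindingScenarioSpec(
            schedule=[("unbound", 30.0)], seed=4
        )
        traj, _, _ = synthetic.gen_binding_trajectory(spec)
        solv = gd.solvation_trace(traj, bulk_reference="auto")
        se = solv.fraction.std() / np.sqrt(len(solv.fraction))
        assert abs(solv.fraction.mean() - 1.0) <= max(2 * se, 1e-9)

    def test_auto_without_bulk_frames_errors(self):
        spec = synthetic.BindingScenarioSpec(
            schedule=[("e_site_closed", 10.0)], seed=4
        )
        traj, _, _ = synthetic.gen_binding_trajectory(spec)
        with pytest.raises(ValueError, match="bulk_reference"):
            gd.solvation_trace(traj, bulk_reference="auto")


class TestBindingEvents:
    def make_trace(self, values):
        return gd.DistanceTrace(
            times=np.arange(len(values)) * 0.2,
            values=np.asarray(values, dtype=float),
            definition="com_f100",
        )

    def test_single_crossing_long_dwell(self):
        vals = np.linspace(20, 1, 80)
        trace = self.make_trace(vals)
        events = gd.detect_binding_events(trace)
        assert len(events) == 1
        first_below = np.argmax(vals < 5.0)
        assert events[0].entry_time == pytest.approx(trace.times[first_below])
        assert events[0].sustained

    def test_short_dip_filtered(self):
        vals = np.full(50, 8.0)
        vals[20:23] = 4.0  # 3 frames < min_dwell_frames=5
        assert gd.detect_binding_events(self.make_trace(vals)) == []

    def test_planted_batch_count(self):
        traces, n_planted = synthetic.gen_binding_batch(seed=0)
        events = [e for t in traces for e in gd.detect_binding_events(t)]
        assert len(events) == n_planted
        assert all(e.sustained for e in events)


class TestAssignStates:
    def test_planted_labels_recovered(self, binding_scenario):
        spec, _, states, traces = binding_scenario
        dist = gd.DistanceTrace(
            traces.times, traces.distance, definition="com_f100"
        )
        gate = gd.DistanceTrace(
            traces.times, traces.gate, definition="gate_y82_s34"
        )
        seq = gd.assign_states(dist, gd.classify_gate(gate))
        assert np.mean(seq.states == states.states) >= 0.95

    def test_constant_bound_closed_is_all_e(self):
        n = 30
        dist = gd.DistanceTrace(
            np.arange(n) * 0.2, np.full(n, 2.0), definition="com_f100"
        )
        seq = gd.assign_states(dist, np.ones(n, dtype=bool))
        assert set(seq.states) == {"e_site_closed"}

    def test_state_order_is_mechanistic_subsequence(self):
        # monotone approach with one gate opening: labels must appear in
        # (unbound, a, b, c, d, e) order
        n = 300
        d = np.linspace(20, 1, n)
        gate_closed = np.ones(n, dtype=bool)
        gate_closed[(d < 10) & (d > 3)] = False  # open during entry
        dist = gd.DistanceTrace(np.arange(n) * 0.2, d, definition="com_f100")
        seq = gd.assign_states(dist, gate_closed)
        order = {s: i for i, s in enumerate(gd.STATES)}
        codes = [order[s] for s in seq.states]
        seen = []
        for c in codes:
            if not seen or c != seen[-1]:
                seen.append(c)
        assert seen == sorted(seen)

    def test_gate_state_consistency_postfilter(self, binding_scenario):
        spec, _, _, traces = binding_scenario
        dist = gd.DistanceTrace(
            traces.times, traces.distance, definition="com_f100"
        )
        gate = gd.DistanceTrace(
            traces.times, traces.gate, definition="gate_y82_s34"
        )
        closed = gd.classify_gate(gate)
        seq = gd.assign_states(dist, closed)
        # away from median-filter boundaries, open states imply open gate
        w = gd.GateParams().min_dwell_frames
        interior = np.zeros(len(closed), dtype=bool)
        interior[w:-w] = True
        # only test frames whose whole filter window agrees on gate state
        stable = np.array([
            closed[max(0, i - w): i + w + 1].all()
            or (~closed[max(0, i - w): i + w + 1]).all()
            for i in range(len(closed))
        ])
        sel = interior & stable
        open_states = np.isin(seq.states, ["c_entry_open", "d_site_open"])
        closed_states = np.isin(
            seq.states, ["b_pocket_closed", "e_site_closed"]
        )
        assert not np.any(open_states[sel] & closed[sel])
        assert not np.any(closed_states[sel] & ~closed[sel])

    def test_mismatched_lengths_rejected(self):
        dist = gd.DistanceTrace(
            np.arange(5.0), np.full(5, 2.0), definition="com_f100"
        )
        with pytest.raises(ValueError, match="length"):
            gd.assign_states(dist, np.ones(4, dtype=bool))
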