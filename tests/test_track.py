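"""Backward Kalman filtering, hypothesis expansion, joint selection."""

import itertools

import numpy as np
import pytest

from angiotrack import track as tk
from oracles import oracle_track_chains


class FlatInterface:
    def __init__(self, y):
        self._y = y

    def y(self, x):
        return self._y


class TestKalmanFilter:
    def test_backward_predict_moves_against_velocity(self):
        params = tk.KalmanParams.default()
        st = tk.CellState(mean=[10, 20, 2, 3], cov=np.eye(4))
        pred = tk.kf_predict(st, params)
        assert np.allclose(pred.mean, [8, 17, 2, 3])

    def test_zero_velocity_keeps_position(self):
        params = tk.KalmanParams.default()
        st = tk.CellState(mean=[5, 6, 0, 0], cov=np.eye(4))
        assert np.allclose(tk.kf_predict(st, params).position, [5, 6])

    def test_zero_noise_keeps_zero_covariance(self):
        params = tk.KalmanParams.default(q_pos=0, q_vel=0)
        st = tk.CellState(mean=np.zeros(4), cov=np.zeros((4, 4)))
        assert np.allclose(tk.kf_predict(st, params).cov, 0.0)

    def test_gate_distance_euclidean_case(self):
        params = tk.KalmanParams.default(r=0.5, gate_gamma=30.0)
        pred = tk.CellState(mean=[0, 0, 0, 0], cov=np.diag([.5, .5, 1, 1]))
        g = tk.kf_gate(pred, [3.0, 4.0], params)   # S = I
        assert abs(g.d2 - 25.0) < 1e-9
        assert g.in_gate

    def test_gate_zero_innovation(self):
        params = tk.KalmanParams.default()
        pred = tk.CellState(mean=[7, 8, 1, 1], cov=np.eye(4))
        g = tk.kf_gate(pred, [7.0, 8.0], params)
        assert g.d2 == 0.0 and g.in_gate

    def test_gate_matches_dense_solve(self, rng):
        params = tk.KalmanParams.default()
        A = rng.normal(0, 1, (4, 4))
        pred = tk.CellState(mean=rng.normal(0, 10, 4), cov=A @ A.T + np.eye(4))
        z = rng.normal(0, 10, 2)
        g = tk.kf_gate(pred, z, params)
        S = params.H @ pred.cov @ params.H.T + params.R
        expect = (z - pred.position) @ np.linalg.solve(S, z - pred.position)
        assert abs(g.d2 - expect) < 1e-9

    def test_update_limits(self):
        params_big = tk.KalmanParams.default(r=1e12)
        pred = tk.CellState(mean=[10, 10, 1, 1], cov=np.eye(4))
        g = tk.kf_gate(pred, [50.0, 60.0], params_big)
        post = tk.kf_update(pred, g, params_big)
        assert np.linalg.norm(post.mean - pred.mean) \
            < 1e-6 * np.linalg.norm(pred.mean)
        params_zero = tk.KalmanParams.default(r=0.0)
        g = tk.kf_gate(pred, [12.0, 13.0], params_zero)
        post = tk.kf_update(pred, g, params_zero)
        assert np.allclose(post.position, [12.0, 13.0])

    def test_noise_free_constant_velocity_recovered_exactly(self):
        """Q = R = 0 on linear truth: posteriors equal truth to 1e-9."""
        params = tk.KalmanParams.default(q_pos=0, q_vel=0, r=0)
        v = np.array([5.0, -3.0])
        end = np.array([100.0, 80.0])
        t = 6
        positions = [end - v * (t - 1 - k) for k in range(t)]
        st = tk.velocity_init([end], params=params)[0]
        for k in range(t - 1, 0, -1):
            pred = tk.kf_predict(st, params)
            g = tk.kf_gate(pred, positions[k - 1], params)
            st = tk.kf_update(pred, g, params)
            assert np.abs(st.position - positions[k - 1]).max() < 1e-9


class TestEventWeights:
    def test_association_probability_unit_covariance(self):
        g = tk.GateResult(innovation=np.zeros(2), S=np.eye(2),
                          K=np.zeros((4, 2)), d2=0.0, in_gate=True)
        assert abs(tk.association_probability(g) - 1 / (2 * np.pi)) < 1e-12

    def test_association_probability_monotone_in_distance(self):
        S = np.diag([4.0, 9.0])
        probs = [tk.association_probability(
            tk.GateResult(np.zeros(2), S, np.zeros((4, 2)), d2, True))
            for d2 in (0.0, 1.0, 2.5, 5.0)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_association_probability_covariance_scaling(self):
        g1 = tk.GateResult(np.zeros(2), np.eye(2), np.zeros((4, 2)), 0.0,
                           True)
        g3 = tk.GateResult(np.zeros(2), 3.0 * np.eye(2),
                           np.zeros((4, 2)), 0.0, True)
        ratio = tk.association_probability(g1) \
            / tk.association_probability(g3)
        assert abs(ratio - 3.0) < 1e-12

    def test_monolayer_probability_printed_parameters(self):
        cfg = tk.MhtConfig()
        assert abs(tk.monolayer_probability(1600.0, cfg)
                   - 100.0 ** (-2.47)) < 1e-15

    def test_monolayer_probability_increases_toward_interface(self):
        cfg = tk.MhtConfig()
        assert tk.monolayer_probability(1000.0, cfg) \
            < tk.monolayer_probability(1400.0, cfg)

    def test_monolayer_probability_domain_error(self):
        cfg = tk.MhtConfig()
        with pytest.raises(ValueError):
            tk.monolayer_probability(cfg.b1, cfg)


class TestVelocityInit:
    def test_zero_velocity_and_inflated_variance(self):
        states = tk.velocity_init([[10.0, 20.0], [30.0, 40.0]],
                                  pos_var=4.0, vel_factor=500.0)
        for st in states:
            assert np.allclose(st.mean[2:], 0.0)
            assert st.cov[2, 2] == 500.0 * st.cov[0, 0]
            assert st.cov[2, 2] > st.cov[0, 0]

    def test_deterministic(self):
        a = tk.velocity_init([[1.0, 2.0]])
        b = tk.velocity_init([[1.0, 2.0]])
        assert np.array_equal(a[0].cov, b[0].cov)
        assert np.array_equal(a[0].mean, b[0].mean)


class TestExpandHypotheses:
    def test_three_detections_plus_entry_gives_four_children(self):
        """Deferred association scenario: three gated observations and
        the interface hypothesis; all kept at M = 4 and the normalised
        probabilities sum to one."""
        params = tk.KalmanParams.default()
        cfg = tk.MhtConfig(p_unobserved=0.0, b1=936.0, entry_band=300.0)
        st = tk.velocity_init([[400.0, 520.0]], params=params)[0]
        branch = tk.HypothesisBranch(track_id=0, states=(st,))
        dets = np.array([[395.0, 480.0], [410.0, 490.0], [385.0, 500.0]])
        new, diag = tk.expand_hypotheses([branch], dets, params, cfg,
                                         interface=FlatInterface(530.0))
        assert diag["n_children"] == 4
        assert len(new) == 4
        assert abs(diag["norm_sums"][0] - 1.0) < 1e-12
        kinds = sorted(br.events[-1][0] for br in new)
        assert kinds == ["entry", "obs", "obs", "obs"]
        entry = [br for br in new if br.terminated]
        assert len(entry) == 1

    def test_branch_cap_respected(self):
        params = tk.KalmanParams.default()
        cfg = tk.MhtConfig(M=2, p_unobserved=0.1)
        st = tk.velocity_init([[100.0, 100.0]], params=params)[0]
        branch = tk.HypothesisBranch(track_id=0, states=(st,))
        dets = np.array([[100.0, 95.0], [105.0, 100.0], [95.0, 105.0]])
        new, _ = tk.expand_hypotheses([branch], dets, params, cfg)
        assert len(new) <= 2

    def test_normalisation_sums_every_expansion(self):
        params = tk.KalmanParams.default()
        cfg = tk.MhtConfig()
        rng = np.random.default_rng(5)
        branches = [tk.HypothesisBranch(
            track_id=0, states=(tk.velocity_init(
                [rng.uniform(50, 400, 2)], params=params)[0],))]
        for _ in range(3):
            dets = rng.uniform(50, 400, (4, 2))
            branches, diag = tk.expand_hypotheses(branches, dets, params,
                                                  cfg)
            for s in diag["norm_sums"]:
                assert abs(s - 1.0) < 1e-12


class TestHypothesisCount:
    def test_enumerated_hypotheses_follow_geometric_growth(self):
        """Two end-point cells, three frames, exactly four children per
        branch: the final expansion enumerates N0 * M**(t-1) = 32."""
        params = tk.KalmanParams.default()
        cfg = tk.MhtConfig(M=4, p_unobserved=0.0, prune_epsilon=0.0,
                           joint_selection=False)
        endpoints = np.array([[200.0, 500.0], [600.0, 500.0]])
        # four detections stay gated around each (stationary) cell in
        # every frame: exactly M children per branch, no terminations
        dets = []
        for k in range(3):
            rows = []
            for cx in (200.0, 600.0):
                for dx, dy in ((-6, 0), (6, 0), (0, -6), (0, 6)):
                    rows.append([cx + dx, 500.0 + dy])
            dets.append(np.array(rows))
        res = tk.run_backward_mht(endpoints, dets, params=params,
                                  config=cfg)
        n0, M, t = 2, 4, 3
        assert res.diagnostics["per_step_children"][0] == n0 * M
        assert res.diagnostics["n_final_hypotheses"] == n0 * M ** (t - 1)


class TestJointSelectionOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_selection_equals_exhaustive_enumeration(self, seed):
        """On instances with <= 3 cells x <= 3 frames the selected
        hypothesis equals brute force over all constraint-satisfying
        event assignments under the same scoring."""
        rng = np.random.default_rng(100 + seed)
        n_cells = int(rng.integers(2, 4))
        t = 3
        endpoints = np.column_stack([rng.uniform(100, 700, n_cells),
                                     rng.uniform(300, 520, n_cells)])
        dets = [np.column_stack([rng.uniform(100, 700, 3),
                                 rng.uniform(300, 540, 3)])
                for _ in range(t)]
        params = tk.KalmanParams.default(q_vel=400.0)
        cfg = tk.MhtConfig(M=64, b1=936.0, prune_epsilon=0.0,
                           entry_band=300.0, enforce_ordering=False,
                           max_joint_candidates=60000)
        iface = FlatInterface(560.0)
        res = tk.run_backward_mht(endpoints, dets, params=params,
                                  config=cfg, interface=iface)
        assert res.diagnostics.get("joint_selection_mode") == "exhaustive"
        # oracle: independent per-track enumeration + product argmax
        per_track = [oracle_track_chains(p, dets, params, cfg, iface)
                     for p in endpoints]
        best, best_score = None, -np.inf
        for combo in itertools.product(*per_track):
            sc = tk.score_joint(list(combo), t - 1, cfg)[0]
            if sc > best_score:
                best, best_score = combo, sc
        got = tuple(br.events for br in res.selected)
        want = tuple(br.events for br in best)
        assert got == want


class TestTrackingEndToEnd:
    def test_unambiguous_noise_free_track_recovered(self):
        params = tk.KalmanParams.default()
        cfg = tk.MhtConfig(joint_selection=False)
        positions = [np.array([[100.0 + 30 * k, 400.0 - 10 * k]])
                     for k in range(4)]
        res = tk.run_backward_mht(positions[-1], positions,
                                  params=params, config=cfg)
        br = res.selected[0]
        assert all(ev == ("obs", 0) for ev in br.events)
        for s, ev in enumerate(br.events):
            frame = res.endpoint_frame - s - 1
            assert np.abs(br.states[s + 1].position
                          - positions[frame][0]).max() < 1.0

    def test_division_and_entry_lineage_recovered(self):
        """A division (two daughters merging backward onto the parent)
        and a monolayer entry produce the matching lineage forest."""
        params = tk.KalmanParams.default()
        cfg = tk.MhtConfig(b1=936.0, entry_band=200.0)
        # frames 0..3; cell A moves up; divides between 1 and 2;
        # cell E enters at frame 2 near the interface
        a0, a1 = np.array([300.0, 500.0]), np.array([300.0, 460.0])
        d1_2, d2_2 = np.array([288.0, 420.0]), np.array([312.0, 420.0])
        d1_3, d2_3 = np.array([286.0, 380.0]), np.array([314.0, 380.0])
        e2, e3 = np.array([500.0, 680.0]), np.array([500.0, 640.0])
        dets = [np.array([a0]), np.array([a1]),
                np.array([d1_2, d2_2, e2]),
                np.array([d1_3, d2_3, e3])]
        endpoints = np.array([d1_3, d2_3, e3])
        res = tk.run_backward_mht(endpoints, dets, params=params,
                                  config=cfg,
                                  interface=FlatInterface(700.0))
        lineage = res.lineage
        divisions = lineage.division_nodes()
        assert len(divisions) == 1
        assert len(divisions[0].children) == 2
        entry_nodes = [n for n in lineage.nodes if n.event == "entry"]
        assert len(entry_nodes) == 1
        assert sorted(divisions[0].track_ids) == [0, 1]

    def test_requires_cells_and_frames(self):
        with pytest.raises(ValueError):
            tk.run_backward_mht(np.empty((0, 2)), [np.empty((0, 2))] * 3)
        with pytest.raises(ValueError):
            tk.run_backward_mht([[1.0, 2.0]], [np.empty((0, 2))])
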