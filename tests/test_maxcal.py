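import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketswitch import maxcal as MC
from pocketswitch.dynamics import stream
from pocketswitch.states import StateDecomposition
from pocketswitch.toy_systems import InvalidParameterError


def chain_adjacency(n):
    adj = np.eye(n, dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


def random_reversible(n, seed, lag_time=1.0):
    """Random reversible chain from a symmetric flux matrix."""
    rng = stream(seed, 4711)
    x = rng.uniform(0.2, 1.0, (n, n))
    x = (x + x.T) / 2
    x *= 0.8 / (2 * np.sum(np.triu(x, 1)) + np.trace(x))
    pi = x.sum(axis=1)
    pi = pi / pi.sum()
    p = x / x.sum(axis=1, keepdims=True)
    T = MC.TransitionMatrix(p=p, lag_time=lag_time, pi=pi,
                            adjacency=np.ones((n, n), bool), caliber=MC.caliber(p, pi))
    T.validate()
    return T


class TestMaxCalSolver:
    def test_two_state_symmetric_closed_form(self):
        T = MC.maxcal_transition_matrix(np.array([0.5, 0.5]), np.ones((2, 2), bool), 0.2)
        assert T.p[0, 1] == pytest.approx(0.2, abs=1e-12)
        assert T.p[1, 0] == pytest.approx(0.2, abs=1e-12)

    def test_two_state_asymmetric_closed_form(self):
        # detailed balance + rate constraint force pi_1 p_12 = pi_2 p_21 = r/2
        r = 0.12
        T = MC.maxcal_transition_matrix(np.array([0.75, 0.25]), np.ones((2, 2), bool), r)
        assert T.p[0, 1] == pytest.approx((r / 2) / 0.75, abs=1e-10)
        assert T.p[1, 0] == pytest.approx((r / 2) / 0.25, abs=1e-10)

    def test_three_state_path_matches_grid_search(self):
        pi = np.array([0.6, 0.3, 0.1])
        adj = chain_adjacency(3)
        T = MC.maxcal_transition_matrix(pi, adj, 0.1)
        p_star, cal_star = MC.exhaustive_maxcal(pi, adj, 0.1, resolution=1e-4)
        assert abs(T.caliber - cal_star) < 1e-6
        assert np.max(np.abs(T.p - p_star)) < 1e-3

    @pytest.mark.parametrize("pi,edges,rate", [
        ([0.5, 0.3, 0.2], [(0, 1), (1, 2), (0, 2)], 0.15),        # triangle
        ([0.4, 0.3, 0.2, 0.1], [(0, 1), (1, 2), (2, 3)], 0.08),   # path
        ([0.4, 0.3, 0.2, 0.1], [(0, 1), (1, 2), (2, 3), (3, 0)], 0.15),  # ring
        ([0.55, 0.2, 0.15, 0.1], [(0, 1), (0, 2), (0, 3)], 0.2),  # star
    ])
    def test_small_system_battery_matches_exhaustive(self, pi, edges, rate):
        pi = np.asarray(pi)
        n = pi.size
        adj = np.eye(n, dtype=bool)
        for i, j in edges:
            adj[i, j] = adj[j, i] = True
        T = MC.maxcal_transition_matrix(pi, adj, rate)
        p_star, cal_star = MC.exhaustive_maxcal(pi, adj, rate)
        assert abs(T.caliber - cal_star) < 1e-6
        assert np.max(np.abs(T.p - p_star)) < 1e-3

    def test_invariants_hold(self):
        for seed in range(5):
            rng = stream(seed, 22)
            n = int(rng.integers(3, 9))
            pi = rng.dirichlet(np.ones(n) * 2)
            T = MC.maxcal_transition_matrix(pi, chain_adjacency(n), 0.05)
            T.validate(tol=1e-8)

    def test_support_respects_adjacency(self):
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        T = MC.maxcal_transition_matrix(pi, chain_adjacency(4), 0.1)
        assert T.p[0, 2] == 0.0 and T.p[0, 3] == 0.0 and T.p[1, 3] == 0.0

    def test_infeasible_rate_reports_range(self):
        with pytest.raises(MC.InfeasibleJumpRateError, match="attainable range"):
            MC.maxcal_transition_matrix(np.array([0.99, 0.01]), np.ones((2, 2), bool), 0.5)

    def test_disconnected_graph_names_components(self):
        adj = np.eye(4, dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        adj[2, 3] = adj[3, 2] = True
        with pytest.raises(InvalidParameterError, match="disconnected"):
            MC.maxcal_transition_matrix(np.full(4, 0.25), adj, 0.1)

    def test_rate_bounds_enforced(self):
        pi = np.array([0.5, 0.5])
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(InvalidParameterError):
                MC.maxcal_transition_matrix(pi, np.ones((2, 2), bool), bad)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_caliber_is_maximal_against_perturbations(self, seed):
        # any detailed-balance-preserving redistribution of edge flux with
        # the same total rate has lower caliber
        pi = np.array([0.5, 0.3, 0.2])
        adj = chain_adjacency(3)
        r = 0.1
        T = MC.maxcal_transition_matrix(pi, adj, r)
        rng = stream(seed, 33)
        eps = rng.uniform(-0.02, 0.02) * r
        x01 = pi[0] * T.p[0, 1] + eps
        x12 = pi[1] * T.p[1, 2] - eps
        if x01 <= 0 or x12 <= 0:
            return
        p = np.zeros((3, 3))
        p[0, 1] = x01 / pi[0]; p[1, 0] = x01 / pi[1]
        p[1, 2] = x12 / pi[1]; p[2, 1] = x12 / pi[2]
        for i in range(3):
            p[i, i] = 1 - p[i].sum()
        if np.any(np.diag(p) < 0):
            return
        assert MC.caliber(p, pi) <= T.caliber + 1e-12


class TestCommittor:
    def test_indicator_when_all_states_assigned(self):
        T = random_reversible(4, 1)
        q = MC.committor(T, [0, 1], [2, 3])
        assert np.array_equal(q, [0, 0, 1, 1])

    def test_symmetric_chain_midpoint(self):
        T = MC.maxcal_transition_matrix(np.full(3, 1 / 3), chain_adjacency(3), 0.2)
        q = MC.committor(T, [0], [2])
        assert q[1] == pytest.approx(0.5, abs=1e-10)

    def test_bounded_and_boundary_exact(self):
        for seed in range(3):
            T = random_reversible(6, seed)
            q = MC.committor(T, [0], [5])
            assert q[0] == 0.0 and q[5] == 1.0
            assert np.all(q >= 0) and np.all(q <= 1)

    def test_overlapping_sets_rejected(self):
        T = random_reversible(4, 2)
        with pytest.raises(InvalidParameterError):
            MC.committor(T, [0, 1], [1, 2])

    def test_matches_monte_carlo(self):
        # committor from the linear solve vs 1e5 absorbing-chain simulations
        T = random_reversible(6, 7)
        q = MC.committor(T, [0], [5])
        rng = stream(99, 1)
        p_cum = np.cumsum(T.p, axis=1)
        n_sim = 100_000
        start = 2
        states = np.full(n_sim, start)
        active = np.ones(n_sim, dtype=bool)
        hit_b = np.zeros(n_sim, dtype=bool)
        for _ in range(5000):
            if not active.any():
                break
            idx = np.where(active)[0]
            r = rng.random(idx.size)
            nxt = (r[:, None] > p_cum[states[idx]]).sum(axis=1)
            states[idx] = nxt
            hit_b[idx[nxt == 5]] = True
            active[idx] = (nxt != 0) & (nxt != 5)
        p_hat = hit_b.mean()
        se = math.sqrt(p_hat * (1 - p_hat) / n_sim)
        assert abs(p_hat - q[start]) < 3 * se + 1e-4


class TestMFPT:
    def test_two_state_geometric(self):
        T = MC.maxcal_transition_matrix(np.array([0.5, 0.5]), np.ones((2, 2), bool),
                                        0.25, lag_time=3.0)
        assert MC.mfpt(T, [0], [1]) == pytest.approx(3.0 / T.p[0, 1], rel=1e-10)

    def test_birth_death_closed_form(self, fixtures_dir):
        import json

        case = json.loads((fixtures_dir / "birth_death_case.json").read_text())
        up = np.array(case["p_up"])
        down = np.array(case["p_down"])
        n = up.size + 1
        p = np.zeros((n, n))
        for i in range(n - 1):
            p[i, i + 1] = up[i]
            p[i + 1, i] = down[i]
        for i in range(n):
            p[i, i] = 1 - p[i].sum()
        w = [1.0]
        for i in range(n - 1):
            w.append(w[-1] * up[i] / down[i])
        pi = np.array(w) / sum(w)
        T = MC.TransitionMatrix(p=p, lag_time=1.0, pi=pi, adjacency=p > 0,
                                caliber=MC.caliber(p, pi))
        T.validate()
        expected = float(case["mfpt_0_to_4_steps"])
        assert MC.mfpt(T, [0], [n - 1]) == pytest.approx(expected, rel=1e-8)

    def test_source_inside_target_is_zero(self):
        T = random_reversible(4, 3)
        assert MC.mfpt(T, [1], [1, 2]) == 0.0

    def test_unreachable_target_raises(self):
        p = np.array([[1.0, 0.0], [0.5, 0.5]])
        T = MC.TransitionMatrix(p=p, lag_time=1.0, pi=np.array([0.999, 0.001]),
                                adjacency=np.ones((2, 2), bool), caliber=0.0)
        with pytest.raises(MC.SingularityError, match="unreachable"):
            MC.mfpt(T, [0], [1])

    def test_matches_chain_simulation(self):
        # TPT consistency: matrix MFPT vs direct chain simulation, 5 seeds
        for seed in range(5):
            T = random_reversible(5, 100 + seed, lag_time=0.5)
            m = MC.mfpt(T, [0], [4])
            sim = MC.simulate_chain_passage(T, 0, np.arange(5) == 4,
                                            n_realizations=100_000, seed=seed)
            assert abs(sim["mean"] - m) < 3 * sim["sem"]


class TestResidenceTime:
    def test_single_state_geometric_dwell(self):
        T = MC.maxcal_transition_matrix(np.array([0.5, 0.5]), np.ones((2, 2), bool),
                                        0.3, lag_time=2.0)
        q = T.p[0, 0]
        assert MC.residence_time(T, [0]) == pytest.approx(2.0 / (1 - q), rel=1e-10)

    def test_absorbing_macrostate_is_infinite(self):
        T = random_reversible(3, 5)
        with pytest.warns(UserWarning, match="no exit"):
            assert MC.residence_time(T, [0, 1, 2]) == math.inf

    def test_deeper_macrostate_dwells_longer(self):
        pi = np.array([0.90, 0.06, 0.04])
        T = MC.maxcal_transition_matrix(pi, chain_adjacency(3), 0.05)
        assert MC.residence_time(T, [0]) > MC.residence_time(T, [1])


class TestCalibrateLag:
    def test_alternating_labels_clamped(self):
        seq = np.array([0, 1] * 50)
        with pytest.warns(UserWarning, match="clamping"):
            cal = MC.calibrate_lag([seq], 1, 0.1)
        assert cal["mean_jump_rate"] == pytest.approx(1 - 1e-6)
        assert cal["lag_time"] == pytest.approx(0.1)

    def test_frozen_trajectory_is_error(self):
        with pytest.raises(MC.CalibrationError, match="no transitions"):
            MC.calibrate_lag([np.zeros(100, dtype=int)], 1, 0.1)

    def test_rate_reproducible_and_in_range(self):
        rng = stream(1, 2)
        seq = rng.integers(0, 3, 5000)
        c1 = MC.calibrate_lag([seq], 2, 0.05)
        c2 = MC.calibrate_lag([seq], 2, 0.05)
        assert c1 == c2
        assert 0 < c1["mean_jump_rate"] < 1

    def test_weights_shift_the_rate(self):
        seq = np.array([0, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        flat = MC.calibrate_lag([seq], 1, 1.0)["mean_jump_rate"]
        w = [np.where(seq == 1, 5.0, 1.0)]
        up = MC.calibrate_lag([seq], 1, 1.0, weights=w)["mean_jump_rate"]
        assert up > flat


def tiny_decomposition():
    fp = np.array([[0, 1, 0], [1, 0, 1], [3, 0, 2]])
    return StateDecomposition(
        microstate_label=np.array([]), n_microstates=3, fingerprints=fp,
        macrostate_of=["pocket", "intermediate", "outside"],
    )


def synthetic_kinetics_inputs(seed=0, n=4000, p_stay=0.9):
    """Markov-chain-generated labels + uniform weights for bootstrap tests."""
    from pocketswitch.metad import WeightedFrames

    rng = stream(seed, 3)
    labels = [0]
    for _ in range(n - 1):
        s = labels[-1]
        if rng.random() < p_stay:
            labels.append(s)
        else:
            labels.append(int(np.clip(s + rng.choice([-1, 1]), 0, 2)))
    labels = np.array(labels)
    dec = tiny_decomposition()
    dec.microstate_label = labels
    w = WeightedFrames(traj_index=np.zeros(n, int), frame_index=np.arange(n),
                       cv=labels.astype(float), weights=np.ones(n) / n)
    return dec, w, [labels]


class TestBootstrapKinetics:
    def test_deterministic_given_seed(self):
        dec, w, lab = synthetic_kinetics_inputs()
        adj = chain_adjacency(3)
        kwargs = dict(n_resamples=20, block_frames=200, seed=5)
        k1 = MC.bootstrap_kinetics(dec, w, lab, 0.1, 1, adj, **kwargs)
        k2 = MC.bootstrap_kinetics(dec, w, lab, 0.1, 1, adj, **kwargs)
        for key in k1.residence_time:
            assert k1.residence_time[key]["mean"] == k2.residence_time[key]["mean"]
            assert k1.residence_time[key]["sd"] == k2.residence_time[key]["sd"]

    def test_degenerate_blocks_give_zero_sd(self):
        # strictly alternating two-state labels: every circular block
        # resample has identical composition and every pair is a jump, so
        # each resample rebuilds the same matrix and the bootstrap SD is 0
        from pocketswitch.metad import WeightedFrames

        labels = np.tile([0, 1], 500)
        dec = StateDecomposition(
            microstate_label=labels, n_microstates=2,
            fingerprints=np.array([[0, 1, 0], [3, 0, 5]]),
            macrostate_of=["pocket", "outside"],
        )
        n = labels.size
        w = WeightedFrames(traj_index=np.zeros(n, int), frame_index=np.arange(n),
                           cv=labels.astype(float), weights=np.ones(n) / n)
        with pytest.warns(UserWarning, match="clamping"):
            k = MC.bootstrap_kinetics(dec, w, [labels], 0.1, 1, chain_adjacency(2),
                                      n_resamples=4, block_frames=1000, seed=1)
        for key in k.residence_time:
            assert k.residence_time[key]["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_longer_trajectories_shrink_uncertainty(self):
        adj = chain_adjacency(3)
        sds = []
        for n in (2000, 16000):
            dec, w, lab = synthetic_kinetics_inputs(seed=9, n=n)
            k = MC.bootstrap_kinetics(dec, w, lab, 0.1, 1, adj,
                                      n_resamples=60, block_frames=100, seed=2)
            sds.append(k.residence_time["pocket"]["sd"]
                       / k.residence_time["pocket"]["mean"])
        assert sds[1] < sds[0]

    def test_committor_attached_for_pocket_outside(self):
        dec, w, lab = synthetic_kinetics_inputs()
        k = MC.bootstrap_kinetics(dec, w, lab, 0.1, 1, chain_adjacency(3),
                                  n_resamples=4, block_frames=200, seed=0)
        assert k.committor is not None
        assert k.committor_pair == ("pocket", "outside")
        assert np.all((0 <= k.committor) & (k.committor <= 1))


class TestCompareConditions:
    def _result(self, res_pocket, res_inter, n_samples=50, jitter=0.05, seed=0):
        rng = stream(seed, 44)

        def pack(mean):
            s = mean * (1 + jitter * rng.standard_normal(n_samples))
            return {"mean": mean, "sd": float(s.std(ddof=1)), "samples": s}

        return MC.KineticsResult(
            mfpt={}, residence_time={"pocket": pack(res_pocket),
                                     "intermediate": pack(res_inter),
                                     "outside": pack(res_inter / 4)},
            committor=None, committor_pair=None,
            macrostates=["intermediate", "outside", "pocket"], lag_time=0.1,
        )

    def test_infinite_switching_rate_limit(self):
        rep = MC.compare_conditions(self._result(1000, 10), self._result(500, 10),
                                    switching_rate=math.inf)
        for cond in rep["conditions"].values():
            assert cond["p_in_pocket"]["mean"] == 1.0
        assert rep["verdict"] == "in-pocket"

    def test_balance_point_is_half(self):
        res = self._result(1000.0, 10.0, jitter=0.0)
        rep = MC.compare_conditions(res, res, switching_rate=1.0 / 1000.0)
        assert rep["conditions"]["tethered"]["p_in_pocket"]["mean"] == pytest.approx(0.5)
        assert rep["verdict"] == "undetermined"

    def test_ratios_reported(self):
        rep = MC.compare_conditions(self._result(2000, 10, seed=1),
                                    self._result(800, 10, seed=2),
                                    switching_rate=1.0)
        ratio, sd = rep["residence_ratio_tethered_over_free"]
        assert ratio == pytest.approx(2.5, rel=1e-9)
        assert sd > 0

    def test_mismatched_macrostates_rejected(self):
        good = self._result(1000, 10)
        bad = self._result(1000, 10)
        bad.macrostates = ["pocket", "intermediate"]
        bad.residence_time.pop("outside")
        with pytest.raises(MC.ComparisonError, match="macrostate sets differ"):
            MC.compare_conditions(good, bad, 1.0)
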