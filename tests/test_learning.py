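import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import threetlr as t
from threetlr.learning import _presentation_fields


@pytest.fixture(scope="module")
def small_params():
    W = t.initialize_weights(200, seed=31)
    params = t.NetworkParams.standard(200, mean_w=W.mean_w, std_w=W.std_w)
    return W, params


class TestLearningThresholds:
    def test_dense_regime_values(self):
        params = t.NetworkParams.standard(1001)
        th0, th1 = t.learning_thresholds(params, eps=0.0)
        assert th0 == pytest.approx(350 - 3 * np.sqrt(1001), abs=1e-9)   # ~255.08
        assert th1 == pytest.approx(350 + 3 * np.sqrt(1001), abs=1e-9)   # ~444.92

    def test_degenerate_thresholds_at_zero_gamma_eps(self):
        params = t.NetworkParams.standard(401, gamma=0.0)
        th0, th1 = t.learning_thresholds(params, eps=0.0)
        assert th0 == th1 == params.theta

    def test_symmetric_about_theta_in_dense_regime(self):
        params = t.NetworkParams.standard(643, gamma=4.2)
        th0, th1 = t.learning_thresholds(params, eps=0.7)
        assert (th0 + th1) / 2 == pytest.approx(params.theta, rel=1e-12)

    def test_sparse_potentiation_threshold_tracks_on_shift(self):
        # at f != 0.5 the ON-population stimulus shift is (1-f) gamma sqrt(N)
        W = t.initialize_weights(401, seed=1)
        params = t.NetworkParams.standard(401, f=0.2, gamma=10.0,
                                          mean_w=W.mean_w, std_w=W.std_w)
        th0, th1 = t.learning_thresholds(params, eps=1.0)
        rootN = np.sqrt(401)
        assert th0 == pytest.approx(params.theta - (10 + 1) * 0.2 * rootN)
        assert th1 == pytest.approx(params.theta + (0.8 * 10 + 0.2 * 1) * rootN)


class TestThreeThresholdUpdate:
    def _setup(self):
        N = 5
        W = np.ones((N, N)); np.fill_diagonal(W, 0.0)
        cfg = t.LearningConfig(eta=0.1, eps=0.0, gamma=1.0, theta0=-1.0, theta1=1.0)
        s = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        return N, W, cfg, s

    def test_no_plasticity_outside_windows(self):
        N, W, cfg, s = self._setup()
        fields = np.array([-5.0, 5.0, -1.0, 1.0, 0.0])  # all outside (th0,th1) or on a boundary
        out = t.three_threshold_update(W.copy(), s, fields, cfg, theta=0.0)
        expected = np.ones((N, N)); np.fill_diagonal(expected, 0.0)
        assert np.array_equal(out, expected)

    def test_potentiation_adds_eta_times_presyn(self):
        N, W, cfg, s = self._setup()
        fields = np.array([0.5, -5.0, -5.0, -5.0, -5.0])  # row 0 in (theta, theta1)
        out = t.three_threshold_update(W.copy(), s, fields, cfg, theta=0.0)
        assert out[0, 2] == pytest.approx(1.1)   # presyn active
        assert out[0, 1] == pytest.approx(1.0)   # presyn silent: unchanged
        assert np.array_equal(out[1:], W[1:])

    def test_depression_clips_at_zero(self):
        N, W, cfg, s = self._setup()
        W0 = W.copy(); W0[1, 2] = 0.0
        fields = np.array([-5.0, -0.5, -5.0, -5.0, -5.0])  # row 1 in (theta0, theta)
        out = t.three_threshold_update(W0, s, fields, cfg, theta=0.0)
        assert out[1, 2] == 0.0            # was 0, stays 0 after clipping
        assert out[1, 0] == pytest.approx(0.9)
        assert out[1, 3] == pytest.approx(1.0)  # presyn silent

    def test_diagonal_stays_zero(self):
        N, W, cfg, s = self._setup()
        fields = np.full(N, 0.5)
        out = t.three_threshold_update(W.copy(), np.ones(N), fields, cfg, theta=0.0)
        assert np.diagonal(out).sum() == 0


class TestPresentAndLearn:
    def test_strong_field_clamps_state_to_pattern(self):
        # gamma = 6 at f = 0.5: one update pins the state to the pattern
        N = 1001
        W = t.initialize_weights(N, seed=41)
        params = t.NetworkParams.standard(N, mean_w=W.mean_w, std_w=W.std_w)
        xi = t.generate_patterns(N, 1, 0.5, seed=42).patterns[0].astype(float)
        rng = np.random.default_rng(43)
        s0 = (rng.random(N) < 0.5).astype(float)
        cfg = t.LearningConfig.for_params(params, eps=1.0)
        _, s1 = t.present_and_learn(W.W.copy(), xi, params, cfg, state=s0)
        assert np.array_equal(s1, xi)

    def test_zero_learning_rate_leaves_weights(self, small_params):
        W, params = small_params
        xi = t.generate_patterns(200, 1, 0.5, seed=44).patterns[0].astype(float)
        th0, th1 = t.learning_thresholds(params, 0.5)
        cfg = t.LearningConfig(eta=0.0, eps=0.5, gamma=params.gamma,
                               theta0=th0, theta1=th1)
        Wout, _ = t.present_and_learn(W.W.copy(), xi, params, cfg)
        assert np.array_equal(Wout, W.W)

    def test_repeated_presentation_becomes_noop(self, small_params):
        # once the pattern's fields leave (theta0, theta1), the plasticity
        # windows are depleted and further presentations change nothing
        W, params = small_params
        xi = t.generate_patterns(200, 1, 0.5, seed=45).patterns[0].astype(float)
        cfg = t.LearningConfig.for_params(params, eps=1.0)
        Warr = W.W.copy()
        for _ in range(200):
            before = Warr.copy()
            Warr, _ = t.present_and_learn(Warr, xi, params, cfg)
            if np.array_equal(Warr, before):
                break
        after, _ = t.present_and_learn(Warr.copy(), xi, params, cfg)
        assert np.array_equal(after, Warr)


class TestTrain3TLR:
    def test_empty_pattern_set_converges_immediately(self, small_params):
        W, params = small_params
        cfg = t.LearningConfig.for_params(params, eps=0.5)
        r = t.train_3tlr(W, np.zeros((0, 200), dtype=np.uint8), params, cfg, seed=1)
        assert r.converged and r.sweeps_used == 0
        assert np.array_equal(r.weights.W, W.W)

    def test_below_capacity_reaches_fixed_points_with_margin_gap(self, dense_trained):
        # after training, ON and OFF field populations are separated by at
        # least the robustness gap 2 f eps sqrt(N) within every pattern
        res = dense_trained["result"]
        params = dense_trained["params"]
        pats = dense_trained["patterns"]
        eps = dense_trained["eps"]
        assert res.converged or res.quiescent
        Xi = pats.patterns.T.astype(float)
        V = res.weights.W @ Xi - (
            params.H0 + params.lam * (Xi.sum(axis=0) - params.f * params.N)
        )[None, :]
        on = Xi > 0.5
        gap = (np.where(on, V, np.inf).min(axis=0)
               - np.where(~on, V, -np.inf).max(axis=0))
        assert gap.min() >= 2 * params.f * eps * np.sqrt(params.N) * (1 - 1e-12)

    def test_far_above_capacity_does_not_converge(self):
        N = 120
        W = t.initialize_weights(N, seed=51)
        params = t.NetworkParams.standard(N, mean_w=W.mean_w, std_w=W.std_w)
        pats = t.generate_patterns(N, int(3.0 * N), 0.5, seed=52)
        cfg = t.LearningConfig.for_params(params, eps=0.3, max_sweeps=40)
        r = t.train_3tlr(W, pats, params, cfg, seed=53)
        assert not r.converged

    def test_weights_stay_valid_during_training(self, dense_trained):
        Wt = dense_trained["result"].weights
        assert Wt.W.min() >= 0
        assert np.diagonal(Wt.W).sum() == 0


class TestPerceptronRuleBaseline:
    def test_exact_equivalence_at_strong_drive(self):
        # gamma = 12, f = 0.5, eps = 3: identical weights to machine precision
        N = 200
        W0 = t.initialize_weights(N, seed=61)
        params = t.NetworkParams.standard(N, gamma=12.0, mean_w=W0.mean_w, std_w=W0.std_w)
        pats = t.generate_patterns(N, 24, 0.5, seed=62)
        cfg = t.LearningConfig.for_params(params, eps=3.0, max_sweeps=300)
        r3 = t.train_3tlr(W0, pats, params, cfg, seed=63)
        rp = t.train_plr(W0, pats, params, cfg, seed=63)
        assert np.array_equal(r3.weights.W, rp.weights.W)

    def test_small_separable_problem_reaches_stability(self):
        # comfortably below capacity: every pattern becomes a fixed point
        N, p = 60, 5
        W0 = t.initialize_weights(N, seed=64)
        params = t.NetworkParams.standard(N, mean_w=W0.mean_w, std_w=W0.std_w)
        pats = t.generate_patterns(N, p, 0.5, seed=65)
        cfg = t.LearningConfig.for_params(params, eps=2.0)
        r = t.train_plr(W0, pats, params, cfg, seed=66)
        assert r.converged or r.quiescent
        for mu in range(p):
            s, _, conv = t.run_dynamics(r.weights, pats.patterns[mu].astype(float), r.params)
            assert conv and np.array_equal(s, pats.patterns[mu].astype(float))


class TestHopfieldBaseline:
    def test_symmetric_by_construction(self):
        pats = t.generate_patterns(80, 8, 0.5, seed=71)
        W = t.train_hopfield(pats)
        assert np.array_equal(W, W.T)
        assert np.diagonal(W).sum() == 0

    def test_single_pattern_and_complement_are_fixed_points(self):
        pats = t.generate_patterns(100, 1, 0.5, seed=72)
        W = t.train_hopfield(pats)
        xi = 2.0 * pats.patterns[0] - 1.0
        assert np.array_equal(t.hopfield_dynamics(W, xi, max_steps=2), xi)
        assert np.array_equal(t.hopfield_dynamics(W, -xi, max_steps=2), -xi)

    def test_retrieval_below_transition(self):
        # alpha = 0.10 < 0.138: stored patterns retrieved with overlap > 0.95
        N = 500
        pats = t.generate_patterns(N, 50, 0.5, seed=73)
        W = t.train_hopfield(pats)
        S0 = (2.0 * pats.patterns - 1.0).T
        S = t.hopfield_dynamics(W, S0)
        overlaps = np.abs((S * S0).mean(axis=0))
        assert overlaps.mean() > 0.95


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 2**16), eps=st.floats(0.0, 2.0))
def test_update_preserves_weight_invariants(seed, eps):
    # any single presentation keeps weights non-negative with zero diagonal
    rng = np.random.default_rng(seed)
    N = 40
    W = t.initialize_weights(N, seed)
    params = t.NetworkParams.standard(N, mean_w=W.mean_w, std_w=W.std_w)
    cfg = t.LearningConfig.for_params(params, eps)
    xi = (rng.random(N) < 0.5).astype(float)
    Wout, _ = t.present_and_learn(W.W.copy(), xi, params, cfg)
    assert Wout.min() >= 0
    assert np.diagonal(Wout).sum() == 0
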