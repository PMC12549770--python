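import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import norm

from rlwmlba import model, task


class TestValueUpdates:
    def test_rl_update_zero_prediction_error(self):
        assert model.rl_update(0.5, 0.5, alpha=0.3, bias=0.2) == 0.5

    def test_rl_update_zero_learning_rate(self):
        assert model.rl_update(0.7, 1, alpha=0.0, bias=0.5) == 0.7

    def test_rl_update_positive_delta(self):
        # q + alpha * (r - q) with the full rate on positive errors
        assert model.rl_update(1 / 3, 1, alpha=0.25, bias=0.9) == pytest.approx(0.5)

    def test_rl_update_negative_delta_uses_reduced_rate(self):
        assert model.rl_update(0.5, 0, alpha=0.2, bias=0.5) == pytest.approx(0.45)

    def test_wm_update_perfect_on_reward(self):
        assert model.wm_update(0.1, 1, bias=0.7) == 1.0

    def test_wm_update_full_neglect(self):
        assert model.wm_update(0.5, 0, bias=1.0) == 0.5

    def test_wm_update_partial_neglect(self):
        assert model.wm_update(0.5, 0, bias=0.4) == pytest.approx(0.2)

    def test_wm_decay_extremes(self):
        q = np.array([[0.0, 0.5, 1.0]])
        assert np.allclose(model.wm_decay(q, 0.0), q)
        assert np.allclose(model.wm_decay(q, 1.0), 1 / 3)

    def test_wm_decay_pulls_toward_init(self):
        out = model.wm_decay(np.array([1.0]), 0.1)
        assert out[0] == pytest.approx(1.0 + 0.1 * (1 / 3 - 1.0))

    @given(
        q=st.floats(0, 1), r=st.integers(0, 1),
        alpha=st.floats(0, 1), bias=st.floats(0, 1),
    )
    def test_updates_stay_in_unit_interval(self, q, r, alpha, bias):
        assert 0.0 <= model.rl_update(q, r, alpha, bias) <= 1.0
        assert 0.0 <= model.wm_update(q, r, bias) <= 1.0


class TestPolicies:
    def test_softmax_uniform(self):
        p = model.softmax_policy(np.array([0.4, 0.4, 0.4]))
        assert np.allclose(p, 1 / 3)

    def test_softmax_known_value(self):
        p = model.softmax_policy(np.array([1 / 3 + 0.1, 1 / 3, 1 / 3]), beta=50)
        expected = np.exp(5) / (np.exp(5) + 2)
        assert p[0] == pytest.approx(expected, abs=1e-9)

    def test_softmax_stability_at_large_gaps(self):
        p = model.softmax_policy(np.array([2.0, 1.0, 1.0]), beta=50)
        assert np.isfinite(p).all()
        assert p[1] < 1e-20 and p[2] < 1e-20  # winner carries all but <1e-20

    def test_mixing_weight(self):
        assert model.mixing_weight(0.0, 3.0, 4) == 0.0
        assert model.mixing_weight(0.7, 4.5, 3) == pytest.approx(0.7)
        assert model.mixing_weight(0.8, 2.5, 5) == pytest.approx(0.4)

    def test_mixed_policy_extremes(self):
        p_wm = np.array([1.0, 0.0, 0.0])
        p_rl = np.array([1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(model.mixed_policy(p_wm, p_rl, 1.0), p_wm)
        assert np.allclose(model.mixed_policy(p_wm, p_rl, 0.0), p_rl)
        assert np.allclose(
            model.mixed_policy(p_wm, p_rl, 0.5), [2 / 3, 1 / 6, 1 / 6]
        )

    def test_average_policy(self):
        rows = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        assert np.allclose(model.average_policy(rows), [0.5, 0.5, 0.0])
        same = np.tile([0.2, 0.3, 0.5], (4, 1))
        assert np.allclose(model.average_policy(same), [0.2, 0.3, 0.5])

    def test_prior_entropy(self):
        assert model.prior_entropy([1 / 3, 1 / 3, 1 / 3]) == pytest.approx(np.log2(3))
        assert model.prior_entropy([1.0, 0.0, 0.0]) == 0.0
        assert model.prior_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5)

    def test_drift_rates(self):
        assert np.allclose(model.drift_rates([0.2, 0.3, 0.5], 1.0, eta=0.0), 0.0)
        v = model.drift_rates([1 / 3] * 3, np.log2(3), eta=5.0)
        assert np.allclose(v, 5.0 / (3 * np.log2(3)))
        v1 = model.drift_rates([0.5, 0.3, 0.2], 1.0, eta=2.0)
        v2 = model.drift_rates([0.5, 0.3, 0.2], 0.5, eta=2.0)
        assert np.allclose(v2, 2 * v1)

    def test_drift_rates_floor_divisor(self):
        v = model.drift_rates([1.0, 0.0, 0.0], 0.0, eta=1.0, h_floor=0.01)
        assert v[0] == pytest.approx(100.0)

    @given(
        st.lists(st.floats(0, 1), min_size=3, max_size=3),
        st.floats(0.01, 1), st.floats(2.01, 4.99), st.integers(2, 5),
    )
    @settings(max_examples=50)
    def test_policy_simplex_invariant(self, q, rho, C, set_size):
        p_rl = model.softmax_policy(np.array(q))
        p_wm = model.softmax_policy(np.array(q[::-1]))
        w = model.mixing_weight(rho, C, set_size)
        p = model.mixed_policy(p_wm, p_rl, w)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()


class TestLBA:
    def test_logpdf_invalid_rt_returns_floor(self):
        v = np.array([1.0, 0.5, 0.5])
        assert model.lba_logpdf(0, 0.1, v, A=1.2, k=1.0) == model.LOG_LIK_FLOOR
        assert not model.is_valid_rt(0.1)
        assert model.is_valid_rt(0.2)

    def test_density_integrates_to_termination_mass(self):
        v = np.array([1.0, 0.5, 0.5])
        total = 0.0
        for c in range(3):
            mass, _ = integrate.quad(
                lambda t: model.lba_defective_density(c, t + model.FIXED_TAU, v, 1.2, 1.0),
                0, np.inf, limit=200,
            )
            total += mass
        expected = model.lba_termination_probability(v)
        assert total == pytest.approx(expected, abs=1e-3)

    def test_sampler_dominant_drift(self):
        rng = np.random.default_rng(1)
        v = np.array([1e6, 0.1, 0.1])
        choices = [model.lba_sample(v, 1.2, 1.0, rng=rng)[0] for _ in range(1000)]
        assert np.mean(np.array(choices) == 0) > 0.999

    def test_sampler_deterministic_under_seed(self):
        v = np.array([1.0, 0.8, 0.2])
        a = [model.lba_sample(v, 1.2, 1.0, seed=5)]
        b = [model.lba_sample(v, 1.2, 1.0, seed=5)]
        assert a == b

    def test_sampler_matches_density_win_fractions(self):
        # scaled-down version of the acceptance oracle
        v = np.array([1.0, 0.5, 0.5])
        choices, _ = model.lba_sample_many(v, 1.2, 1.0, n=200_000, seed=3)
        p_sim = np.mean(choices == 0)
        p_int, _ = integrate.quad(
            lambda t: model.lba_defective_density(0, t + model.FIXED_TAU, v, 1.2, 1.0),
            0, np.inf, limit=200,
        )
        # normalize by the termination mass (the sampler resamples stuck races)
        p_int /= model.lba_termination_probability(v)
        assert p_sim == pytest.approx(p_int, abs=0.01)

    def test_rt_always_above_tau(self):
        _, rts = model.lba_sample_many(np.array([2.0, 1.0, 0.5]), 0.8, 0.6, n=1000, seed=9)
        assert (rts > model.FIXED_TAU).all()


class TestSubjectParameters:
    def test_threshold_is_sum(self, default_params):
        assert default_params.b == pytest.approx(default_params.A + default_params.k)

    def test_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            model.SubjectParameters(1.5, 0.5, 0.5, 0.5, 3.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="C"):
            model.SubjectParameters(0.5, 0.5, 0.5, 0.5, 5.5, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="eta"):
            model.SubjectParameters(0.5, 0.5, 0.5, 0.5, 3.0, -1.0, 1.0, 1.0)

    def test_array_round_trip(self, default_params):
        arr = default_params.to_array()
        again = model.SubjectParameters.from_array(arr)
        assert again == default_params


class TestSimulation:
    def test_learner_state_initialization(self):
        state = model.LearnerState.fresh(4)
        assert state.Q_RL.shape == (4, 3)
        assert np.all(state.Q_RL == 1 / 3)
        assert np.all(state.Q_WM == 1 / 3)

    def test_chance_level_without_learning(self, session_design):
        params = model.SubjectParameters(
            alpha=1e-6, bias=0.5, phi=0.5, rho=1e-6, C=3.5, eta=5.0, A=1.2, k=1.0
        )
        df = model.simulate_agent(session_design, params, seed=21)
        acc = df["reward"].mean()
        se = np.sqrt(acc * (1 - acc) / len(df))
        assert abs(acc - 1 / 3) < 3 * max(se, 0.02)

    def test_perfect_wm_after_first_iteration(self, session_design):
        params = model.SubjectParameters(
            alpha=0.01, bias=1e-6, phi=1e-6, rho=1 - 1e-9, C=4.99, eta=5.0,
            A=0.5, k=1.5,
        )
        df = model.simulate_agent(session_design, params, seed=22)
        later = df[df["iteration"] >= 2]
        assert later["reward"].mean() > 0.95

    def test_set_size_effect_on_early_accuracy(self, default_params):
        accs = {}
        frames = []
        for seed in range(8):
            sess = task.generate_session(seed=seed + 100)
            frames.append(model.simulate_agent(sess, default_params, seed=seed))
        df = pd.concat(frames)
        early = df[df["iteration"] <= 4]
        accs = early.groupby("set_size")["reward"].mean()
        assert accs[2] > accs[5]

    def test_simulation_deterministic(self, session_design, default_params):
        a = model.simulate_agent(session_design, default_params, seed=7)
        b = model.simulate_agent(session_design, default_params, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rt_within_response_window(self, simulated_trials):
        rts = simulated_trials["rt"].dropna()
        assert (rts > model.FIXED_TAU).all()
        assert (rts <= model.RESPONSE_WINDOW).all()


class TestSessionLoglik:
    def test_empty_trials(self, default_params):
        empty = task.trials_to_frame([])
        assert model.session_loglik(empty, default_params) == 0.0

    def test_stateless_replay(self, simulated_trials, default_params):
        a = model.session_loglik(simulated_trials, default_params)
        b = model.session_loglik(simulated_trials, default_params)
        assert a == b

    def test_fast_path_matches_reference(self, simulated_trials, default_params):
        slow = model.session_loglik(simulated_trials, default_params)
        fast = model.session_loglik(simulated_trials, default_params, fast=True)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_fast_path_matches_reference_other_params(self, simulated_trials):
        params = model.SubjectParameters(
            alpha=0.3, bias=0.1, phi=0.6, rho=0.4, C=2.3, eta=2.0, A=0.4, k=2.0
        )
        slow = model.session_loglik(simulated_trials, params)
        fast = model.session_loglik(simulated_trials, params, fast=True)
        assert fast == pytest.approx(slow, rel=1e-9, abs=1e-5)

    def test_raises_on_missing_choice(self, simulated_trials, default_params):
        broken = simulated_trials.copy()
        broken.loc[3, "action"] = pd.NA
        with pytest.raises(ValueError, match="missing choice or rt"):
            model.session_loglik(broken, default_params)

    def test_generating_params_beat_perturbed(self, default_params):
        # average over a handful of subjects: truth should outscore a
        # one-SD perturbation of the drift scaling
        worse = model.SubjectParameters(
            alpha=0.05, bias=0.5, phi=0.2, rho=0.8, C=3.5,
            eta=5.0 * np.exp(0.5), A=1.2, k=1.0,
        )
        diffs = []
        for seed in range(5):
            sess = task.generate_session(seed=seed + 300)
            df = model.simulate_agent(sess, default_params, seed=seed)
            diffs.append(
                model.session_loglik(df, default_params, fast=True)
                - model.session_loglik(df, worse, fast=True)
            )
        assert np.mean(diffs) > 0

    def test_action_label_permutation_invariance(self, default_params):
        # permuting action labels consistently leaves the likelihood unchanged
        sess = task.generate_session(seed=41)
        df = model.simulate_agent(sess, default_params, seed=41)
        perm = {0: 1, 1: 2, 2: 0}
        permuted = df.copy()
        permuted["action"] = permuted["action"].map(perm).astype("Int64")
        permuted["correct_action"] = permuted["correct_action"].map(perm)
        a = model.session_loglik(df, default_params, fast=True)
        b = model.session_loglik(permuted, default_params, fast=True)
        assert b == pytest.approx(a, abs=1e-8)
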