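import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baldwinsim.learning import (
    Action,
    ExplorationPolicy,
    QNetwork,
    greedy_forager_network,
    q_values,
    select_action,
    skill_update,
    td_update,
)


def random_net(rng, n_features=6, alpha=0.1, gamma=0.9):
    return QNetwork(
        rng.normal(size=(5, n_features)), rng.normal(size=5), alpha, gamma
    )


def td_oracle(net, i_prev, a_prev, reward, i_now, h=1e-6):
    """Independent oracle: numerical gradient of the squared TD error
    0.5 * (target - Q_theta(i_prev, a_prev))**2 with the bootstrapped
    target held fixed, stepped with learning rate alpha."""
    target = reward + net.gamma * np.max(net.W @ np.asarray(i_now) + net.b)

    def loss(W, b):
        pred = W[a_prev] @ np.asarray(i_prev) + b[a_prev]
        return 0.5 * (target - pred) ** 2

    gW = np.zeros_like(net.W)
    gb = np.zeros_like(net.b)
    for idx in np.ndindex(net.W.shape):
        Wp, Wm = net.W.copy(), net.W.copy()
        Wp[idx] += h
        Wm[idx] -= h
        gW[idx] = (loss(Wp, net.b) - loss(Wm, net.b)) / (2 * h)
    for i in range(5):
        bp, bm = net.b.copy(), net.b.copy()
        bp[i] += h
        bm[i] -= h
        gb[i] = (loss(net.W, bp) - loss(net.W, bm)) / (2 * h)
    return net.W - net.alpha * gW, net.b - net.alpha * gb


class TestQValues:
    def test_zero_network_gives_zero_values(self):
        net = QNetwork.zeros(18)
        assert np.array_equal(q_values(net, np.zeros(18)), np.zeros(5))

    def test_bias_passes_through_at_zero_features(self, rng):
        net = random_net(rng)
        assert np.allclose(q_values(net, np.zeros(6)), net.b)

    def test_linear_in_features(self, rng):
        net = random_net(rng)
        feats = rng.random(6)
        assert np.allclose(q_values(net, feats), net.W @ feats + net.b)

    def test_dimension_mismatch_is_an_error(self, rng):
        net = random_net(rng, n_features=6)
        with pytest.raises(ValueError):
            q_values(net, np.zeros(18))


class TestSelectAction:
    def test_unique_argmax_is_deterministic(self, rng):
        qvals = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        policy = ExplorationPolicy(epsilon=0.0)
        assert all(select_action(qvals, policy, rng) == Action.EAT for _ in range(20))

    def test_exact_ties_break_uniformly(self, rng):
        qvals = np.ones(5)
        policy = ExplorationPolicy(epsilon=0.0)
        draws = np.array([select_action(qvals, policy, rng) for _ in range(5000)])
        freqs = np.bincount(draws, minlength=5) / 5000
        assert np.all(np.abs(freqs - 0.2) < 4 * np.sqrt(0.2 * 0.8 / 5000))

    def test_full_exploration_ignores_q_values(self, rng):
        qvals = np.array([10.0, 0.0, 0.0, 0.0, 0.0])
        policy = ExplorationPolicy(epsilon=1.0)
        draws = np.array([select_action(qvals, policy, rng) for _ in range(5000)])
        freqs = np.bincount(draws, minlength=5) / 5000
        assert np.all(np.abs(freqs - 0.2) < 4 * np.sqrt(0.2 * 0.8 / 5000))


class TestTDUpdate:
    def test_zero_net_zero_reward_is_a_fixed_point(self):
        net = QNetwork.zeros(4, alpha=0.5, gamma=0.9)
        td_update(net, np.zeros(4), 2, 0.0, np.zeros(4))
        assert not net.W.any() and not net.b.any()

    def test_reward_with_zero_features_moves_only_the_bias(self):
        net = QNetwork.zeros(4, alpha=0.5, gamma=0.0)
        td_update(net, np.zeros(4), 1, 1.0, np.zeros(4))
        assert not net.W.any()
        assert np.allclose(net.b, [0, 0.5, 0, 0, 0])

    def test_consistent_target_leaves_network_unchanged(self, rng):
        net = random_net(rng, gamma=0.5)
        i_prev, i_now = rng.random(6), rng.random(6)
        # choose the reward that makes the bootstrapped target equal the prediction
        a = 3
        pred = net.W[a] @ i_prev + net.b[a]
        reward = pred - net.gamma * np.max(net.W @ i_now + net.b)
        W0, b0 = net.W.copy(), net.b.copy()
        td_update(net, i_prev, a, reward, i_now)
        assert np.allclose(net.W, W0) and np.allclose(net.b, b0)

    def test_matches_numerical_gradient_oracle(self, rng):
        for _ in range(30):
            net = random_net(rng, n_features=4, alpha=float(rng.uniform(0.05, 1.0)))
            i_prev = rng.random(4)
            i_now = rng.random(4)
            a = int(rng.integers(5))
            reward = float(rng.normal())
            expected_W, expected_b = td_oracle(net, i_prev, a, reward, i_now)
            td_update(net, i_prev, a, reward, i_now)
            assert np.allclose(net.W, expected_W, atol=1e-8)
            assert np.allclose(net.b, expected_b, atol=1e-8)

    def test_repeated_updates_converge_geometrically(self, rng):
        # gamma = 0 makes the target a constant; the TD error must shrink
        net = random_net(rng, gamma=0.0, alpha=0.3)
        i_prev = rng.random(6)
        a, reward = 1, 2.0
        errors = []
        for _ in range(40):
            pred = net.W[a] @ i_prev + net.b[a]
            errors.append(abs(reward - pred))
            td_update(net, i_prev, a, reward, np.zeros(6))
        errors = np.array(errors)
        assert np.all(np.diff(errors) <= 1e-12)
        assert errors[-1] < 1e-6


class TestSkillUpdate:
    @pytest.mark.parametrize(
        "s,rtype,ds,expected",
        [
            (0.5, 0, 0.05, 0.55),
            (0.98, 0, 0.05, 1.0),  # clamp at the specialist boundary
            (0.5, 1, 0.05, 0.45),  # raising the type-1 skill lowers s
            (0.02, 1, 0.05, 0.0),
        ],
    )
    def test_increment_toward_successful_type(self, s, rtype, ds, expected):
        assert skill_update(s, rtype, ds) == pytest.approx(expected)

    @given(s=st.floats(0, 1), ds=st.floats(0, 0.5), rtype=st.integers(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_result_stays_in_unit_interval(self, s, ds, rtype):
        assert 0.0 <= skill_update(s, rtype, ds) <= 1.0

    @given(s=st.floats(0.2, 0.8), ds=st.floats(0, 0.2))
    @settings(max_examples=60, deadline=None)
    def test_opposite_successes_cancel_away_from_clamps(self, s, ds):
        assert skill_update(skill_update(s, 0, ds), 1, ds) == pytest.approx(s)


class TestGreedyForager:
    def test_eats_when_standing_on_food(self, rng):
        W, b = greedy_forager_network(18)
        feat = np.zeros(18)
        feat[8] = 1  # type-0 food on own cell
        net = QNetwork(W, b)
        assert select_action(q_values(net, feat), ExplorationPolicy(0.0), rng) == Action.EAT

    def test_moves_toward_visible_food(self, rng):
        W, b = greedy_forager_network(18)
        feat = np.zeros(18)
        feat[2 * 1 + 0] = 1  # food due north (cell 1)
        net = QNetwork(W, b)
        assert select_action(q_values(net, feat), ExplorationPolicy(0.0), rng) == Action.NORTH
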