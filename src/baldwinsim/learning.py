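"""Action selection and reinforcement learning.

Agents choose among five actions (four moves and "eat") with a linear
action-value function ("perceptron Q-network"): ``Q(I) = W @ I + beta`` over
the binary perception features ``I``.  The network is trained online by the
one-step temporal-difference rule

    dQ = reward + gamma * max_a Q(I_now, a) - Q(I_prev, a_prev)
    Q(I_prev, a_prev) <- Q(I_prev, a_prev) + alpha_rl * dQ

which, for a linear network, is a gradient-descent step of size ``alpha_rl``
on the squared TD error: only the weight row and bias of the taken action
move, each by ``alpha_rl * dQ * feature`` (bias feature = 1).

Skill is a second, scalar plastic trait: each successful forage of type 0
raises the skill by ``delta_s`` (clamped to [0, 1]); success on type 1
lowers it by ``delta_s``, which by the complementarity ``s_1 = 1 - s``
raises the type-1 skill by the same amount.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Action",
    "N_ACTIONS",
    "ExplorationPolicy",
    "QNetwork",
    "q_values",
    "select_action",
    "td_update",
    "skill_update",
    "q_values_batch",
    "select_actions_batch",
    "td_update_batch",
    "greedy_forager_network",
]


class Action(IntEnum):
    NORTH = 0
    SOUTH = 1
    EAST = 2
    WEST = 3
    EAT = 4


N_ACTIONS = 5


@dataclass(frozen=True)
class ExplorationPolicy:
    """Epsilon-greedy action selection; ties among maximal Q-values are
    broken uniformly at random.  ``epsilon = 0`` recovers pure argmax."""

    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"exploration epsilon must be in [0, 1], got {self.epsilon}")


@dataclass
class QNetwork:
    """Linear action-value function with its learning constants.

    ``W`` has shape (5 actions, n_features); ``b`` has one bias per action.
    """

    W: np.ndarray
    b: np.ndarray
    alpha: float = 0.1
    gamma: float = 0.9

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[0] != N_ACTIONS:
            raise ValueError(f"W must have shape ({N_ACTIONS}, n_features), got {self.W.shape}")
        if self.b.shape != (N_ACTIONS,):
            raise ValueError(f"b must have shape ({N_ACTIONS},), got {self.b.shape}")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b).all()):
            raise ValueError("network parameters must be finite")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"learning rate must be in (0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"discount factor must be in [0, 1), got {self.gamma}")

    @classmethod
    def zeros(cls, n_features: int, alpha: float = 0.1, gamma: float = 0.9) -> "QNetwork":
        return cls(np.zeros((N_ACTIONS, n_features)), np.zeros(N_ACTIONS), alpha, gamma)

    def copy(self) -> "QNetwork":
        return QNetwork(self.W.copy(), self.b.copy(), self.alpha, self.gamma)


def q_values(net: QNetwork, features: np.ndarray) -> np.ndarray:
    """``W @ I + b``: one action value per action."""
    features = np.asarray(features, dtype=np.float64)
    if features.shape != (net.W.shape[1],):
        raise ValueError(
            f"feature vector of length {features.shape} does not match "
            f"network input size {net.W.shape[1]}"
        )
    return net.W @ features + net.b


def select_action(
    qvals: np.ndarray, policy: ExplorationPolicy, rng: np.random.Generator
) -> int:
    """Epsilon-greedy selection with uniform random tie-breaking."""
    if policy.epsilon > 0 and rng.random() < policy.epsilon:
        return int(rng.integers(N_ACTIONS))
    qvals = np.asarray(qvals, dtype=np.float64)
    best = np.flatnonzero(qvals == qvals.max())
    if best.size == 1:
        return int(best[0])
    return int(rng.choice(best))


def td_update(
    net: QNetwork,
    i_prev: np.ndarray,
    a_prev: int,
    reward: float,
    i_now: np.ndarray,
) -> QNetwork:
    """One online TD(0) step on the transition (I_prev, a_prev, reward, I_now).

    Updates ``net`` in place (and returns it): the taken action's weight row
    moves by ``alpha * dQ * I_prev`` and its bias by ``alpha * dQ``; other
    rows are untouched.  The bootstrapped target uses the *current* network
    for both the prediction and the next-state maximum.
    """
    i_prev = np.asarray(i_prev, dtype=np.float64)
    target = reward + net.gamma * np.max(q_values(net, i_now))
    pred = net.W[a_prev] @ i_prev + net.b[a_prev]
    dq = target - pred
    net.W[a_prev] += net.alpha * dq * i_prev
    net.b[a_prev] += net.alpha * dq
    return net


def skill_update(s: float, foraged_type: int, delta_s: float) -> float:
    """Shift skill by ``delta_s`` toward the successfully foraged type.

    Type 0 raises ``s``; type 1 lowers it (equivalently raises ``1 - s``).
    The result is clamped to [0, 1].
    """
    if foraged_type == 0:
        return min(1.0, s + delta_s)
    return max(0.0, s - delta_s)


# -- batched versions used by the simulation engine ------------------------


def q_values_batch(W: np.ndarray, b: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Per-agent Q-values: ``(n, 5, f) x (n, f) -> (n, 5)``."""
    return np.einsum("naf,nf->na", W, features) + b


def select_actions_batch(
    qvals: np.ndarray, epsilon: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized epsilon-greedy with uniform tie-breaking, one row per agent."""
    n = qvals.shape[0]
    is_max = qvals == qvals.max(axis=1, keepdims=True)
    # random score on maximal entries only -> argmax picks uniformly among ties
    scores = rng.random(qvals.shape) * is_max
    actions = scores.argmax(axis=1).astype(np.int8)
    if epsilon > 0:
        explore = rng.random(n) < epsilon
        n_explore = int(explore.sum())
        if n_explore:
            actions[explore] = rng.integers(N_ACTIONS, size=n_explore, dtype=np.int8)
    return actions


def td_update_batch(
    W: np.ndarray,
    b: np.ndarray,
    idx: np.ndarray,
    i_prev: np.ndarray,
    a_prev: np.ndarray,
    reward: np.ndarray,
    i_now: np.ndarray,
    alpha: float,
    gamma: float,
) -> None:
    """In-place TD(0) update for the agents listed in ``idx``.

    ``W``/``b`` are the full population parameter arrays; ``i_prev``,
    ``a_prev``, ``reward`` and ``i_now`` are aligned with ``idx``.
    """
    if idx.size == 0:
        return
    q_next = q_values_batch(W[idx], b[idx], i_now).max(axis=1)
    pred = np.einsum("nf,nf->n", W[idx, a_prev], i_prev) + b[idx, a_prev]
    dq = reward + gamma * q_next - pred
    W[idx, a_prev] += alpha * dq[:, None] * i_prev
    b[idx, a_prev] += alpha * dq


def greedy_forager_network(n_features: int = 18) -> tuple[np.ndarray, np.ndarray]:
    """Hand-crafted competent policy: eat when standing on food, otherwise
    move toward visible food (straight cells preferred over diagonals),
    otherwise a uniform random move.

    Used for the behavior-evaluation baseline populations, whose published
    description fixes only their aptitude values: with this shared policy,
    differences in foraging behavior are attributable to aptitude alone.
    Works for both the 18-feature and the 9-feature (type-blind) perception.
    """
    channels = 2 if n_features == 18 else 1
    if n_features not in (18, 9):
        raise ValueError(f"unsupported perception size {n_features}")
    W = np.zeros((N_ACTIONS, n_features))
    b = np.zeros(N_ACTIONS)

    def cell_slice(cell: int) -> slice:
        return slice(channels * cell, channels * (cell + 1))

    # window cells: 0 NW, 1 N, 2 NE, 3 W, 4 center, 5 E, 6 SW, 7 S, 8 SE
    for action, (straight, diagonals) in {
        Action.NORTH: (1, (0, 2)),
        Action.SOUTH: (7, (6, 8)),
        Action.EAST: (5, (2, 8)),
        Action.WEST: (3, (0, 6)),
    }.items():
        W[action, cell_slice(straight)] = 1.0
        for d in diagonals:
            W[action, cell_slice(d)] += 0.5
    W[Action.EAT, cell_slice(4)] = 2.0
    b[Action.EAT] = -0.05  # with nothing visible, prefer moving over eating
    return W, b
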