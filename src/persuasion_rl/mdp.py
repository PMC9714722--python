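"""Tabular MDP model estimation and value iteration.

The decision process has 8 abstract states (three binary COM-B-derived
features) and 5 actions (persuasion types). Reward and transition tables are
estimated from logged transitions ``(s, a, r, s')`` by (optionally weighted)
averaging; Q-values come from synchronous value iteration.

Person-specific weighting (the similarity-based level-4 policy) enters only
through the per-sample weights: the estimators themselves are weight-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actions import N_ACTIONS, N_STATES

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ModelEstimate:
    """Weighted tabular estimates of the reward and transition functions.

    Attributes
    ----------
    reward : ndarray, shape (8, 5, 8)
        R(s, a, s'): weighted mean reward of transitions matching the cell.
        Cells with no weight mass hold the neutral default 0 (the reward of
        a mean-effort response).
    transition : ndarray, shape (8, 5, 8)
        T(s, a, .): weighted relative frequency of next states; rows with no
        observations default to the uniform distribution.
    support : ndarray, shape (8, 5, 8)
        Total weight mass per (s, a, s') cell.
    """

    reward: np.ndarray
    transition: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        row_sums = self.transition.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=_ROW_SUM_TOL, rtol=0):
            raise ValueError("transition rows must each sum to 1")
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be nonnegative")
        # estimated cell means of rewards in [-1, 1] cannot escape the range
        assert np.all(np.abs(self.reward) <= 1 + 1e-12)


def _validate_transitions(states, actions, next_states):
    for name, arr, high in (
        ("states", states, N_STATES),
        ("actions", actions, N_ACTIONS),
        ("next_states", next_states, N_STATES),
    ):
        if np.any((arr < 0) | (arr >= high)):
            raise ValueError(f"{name} must be integers in [0, {high})")


def estimate_models(
    states,
    actions,
    rewards,
    next_states,
    sample_weight=None,
) -> ModelEstimate:
    """Estimate reward and transition tables from logged transitions.

    Parameters
    ----------
    states, actions, next_states : array-like of int
        State indices in [0, 8), action codes in [0, 5).
    rewards : array-like of float
        Rewards in [-1, 1], one per transition.
    sample_weight : array-like of float, optional
        Positive per-sample weights (similarity weights for the personalized
        level-4 policy). ``None`` means uniform weighting. Scaling all
        weights by a positive constant leaves the estimate unchanged.
    """
    states = np.asarray(states, dtype=np.intp)
    actions = np.asarray(actions, dtype=np.intp)
    rewards = np.asarray(rewards, dtype=float)
    next_states = np.asarray(next_states, dtype=np.intp)
    n = states.shape[0]
    if not (actions.shape[0] == rewards.shape[0] == next_states.shape[0] == n):
        raise ValueError("states, actions, rewards, next_states must align")
    if n == 0:
        raise ValueError("cannot estimate models from zero transitions")
    _validate_transitions(states, actions, next_states)
    if np.any(np.abs(rewards) > 1 + 1e-12):
        raise ValueError("rewards must lie in [-1, 1]")

    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape[0] != n:
            raise ValueError("sample_weight must align with samples")
        if np.any(w <= 0):
            raise ValueError("sample weights must be strictly positive")

    support = np.zeros((N_STATES, N_ACTIONS, N_STATES))
    wr_sum = np.zeros_like(support)
    np.add.at(support, (states, actions, next_states), w)
    np.add.at(wr_sum, (states, actions, next_states), w * rewards)

    reward = np.divide(
        wr_sum, support, out=np.zeros_like(wr_sum), where=support > 0
    )

    row_mass = support.sum(axis=2, keepdims=True)
    uniform = np.full_like(support, 1.0 / N_STATES)
    transition = np.divide(
        support, row_mass, out=uniform, where=row_mass > 0
    )
    return ModelEstimate(reward=reward, transition=transition, support=support)


def expected_reward(model: ModelEstimate) -> np.ndarray:
    """R(s, a) = sum_s' T(s, a, s') R(s, a, s'), shape (8, 5)."""
    return np.einsum("sap,sap->sa", model.transition, model.reward)


def value_iteration(
    model: ModelEstimate,
    gamma: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Solve for Q* by synchronous value iteration.

    Iterates ``Q(s,a) = sum_s' T(s,a,s') [R(s,a,s') + gamma max_a' Q(s',a')]``
    from Q=0. The contraction argument bounds the distance to the fixed
    point by ``gamma/(1-gamma)`` times the last sup-norm change, so the
    stopping threshold is scaled to guarantee the returned table is within
    ``tol`` of the true fixed point. Deterministic for fixed inputs.

    Returns
    -------
    ndarray, shape (8, 5)
        The Q-value table.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must lie in [0, 1), got {gamma!r}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    er = expected_reward(model)
    if gamma == 0.0:
        return er
    stop = tol * (1.0 - gamma) / gamma
    q = np.zeros((N_STATES, N_ACTIONS))
    for _ in range(max_iter):
        v = q.max(axis=1)
        q_new = er + gamma * model.transition.dot(v).reshape(q.shape)
        if np.max(np.abs(q_new - q)) < stop:
            return q_new
        q = q_new
    raise RuntimeError("value iteration failed to converge")  # pragma: no cover


def finite_horizon_q(
    model: ModelEstimate, gamma: float, horizon: int
) -> np.ndarray:
    """Finite-horizon Q by backward induction (independent check oracle).

    Q_0 = 0; Q_{t+1}(s,a) = sum_s' T [R + gamma max_a' Q_t(s',a')]. After
    ``horizon`` backups the result is within ``gamma**horizon / (1-gamma)``
    of the infinite-horizon fixed point (rewards bounded by 1).
    """
    er = expected_reward(model)
    q = np.zeros((N_STATES, N_ACTIONS))
    for _ in range(horizon):
        q = er + gamma * model.transition.dot(q.max(axis=1)).reshape(q.shape)
    return q
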