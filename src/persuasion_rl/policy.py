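"""Greedy persuasion policies at the four complexity levels.

The four nested levels choose, for a user in state ``s``:

1. the action with the overall highest average reward (state-blind);
2. the action with the highest average reward in ``s``;
3. the action with the highest Q-value in ``s`` (value iteration);
4. the action with the highest similarity-weighted Q-value in ``s``,
   where each logged sample is weighted by how similar its contributor is
   to the target user.

`PolicyLearner` is the scikit-learn-style front end: ``fit`` consumes a
transition log, ``predict`` maps state indices to recommended actions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

from .actions import ACTIONS, N_ACTIONS, N_STATES, Action
from .mdp import ModelEstimate, estimate_models, expected_reward, value_iteration

#: Action values closer than this are treated as tied.
TIE_ATOL = 1e-12

SAMPLE_COLUMNS = ("state", "action", "reward", "next_state")


@dataclass(frozen=True)
class Policy:
    """A greedy policy over the 8 abstract states.

    ``mapping[s]`` is the chosen action code; ``argmax_sets[s]`` lists every
    maximizing action (ties included); ``action_values[s, a]`` holds the
    criterion the level maximizes (mean reward or Q-value).
    """

    level: int
    mapping: np.ndarray
    argmax_sets: tuple[tuple[int, ...], ...]
    action_values: np.ndarray

    def __post_init__(self):
        for s in range(N_STATES):
            if self.mapping[s] not in self.argmax_sets[s]:
                raise ValueError("mapping must select a maximizing action")

    def actions(self) -> list[Action]:
        return [ACTIONS[a] for a in self.mapping]


def _argmax_sets(values: np.ndarray) -> tuple[tuple[int, ...], ...]:
    sets = []
    for row in values:
        top = row.max()
        sets.append(tuple(np.flatnonzero(np.isclose(row, top, rtol=0, atol=TIE_ATOL))))
    return tuple(sets)


def _resolve_ties(argmax_sets, tie_break: str, rng) -> np.ndarray:
    mapping = np.empty(N_STATES, dtype=np.intp)
    for s, candidates in enumerate(argmax_sets):
        if tie_break == "canonical":
            mapping[s] = candidates[0]
        elif tie_break == "random":
            mapping[s] = rng.choice(candidates)
        else:
            raise ValueError(f"unknown tie_break {tie_break!r}")
    return mapping


def action_values_for_level(
    level: int,
    model: ModelEstimate,
    gamma: float = 0.85,
    tol: float = 1e-9,
) -> np.ndarray:
    """The (8, 5) criterion table each complexity level maximizes."""
    if level == 1:
        mass = model.support.sum(axis=(0, 2))
        if not np.any(mass > 0):
            raise ValueError("level 1 requires at least one sample")
        total = (model.support * model.reward).sum(axis=(0, 2))
        overall = np.divide(total, mass, out=np.zeros(N_ACTIONS), where=mass > 0)
        return np.tile(overall, (N_STATES, 1))
    if level == 2:
        return expected_reward(model)
    if level in (3, 4):
        return value_iteration(model, gamma=gamma, tol=tol)
    raise ValueError(f"complexity level must be 1-4, got {level!r}")


def policy_for_level(
    level: int,
    states,
    actions,
    rewards,
    next_states,
    gamma: float = 0.85,
    sample_weight=None,
    tie_break: str = "canonical",
    rng=None,
    tol: float = 1e-9,
) -> Policy:
    """Fit the greedy policy of a complexity level from a transition log.

    Levels 1-3 use uniform weighting; level 4 requires per-sample similarity
    weights. ``tie_break`` is ``"canonical"`` (lowest action code, the
    reproducible default) or ``"random"`` (uniform among maximizers, the
    convention of the resampled policy-agreement analysis; needs ``rng``).
    """
    if level == 4 and sample_weight is None:
        raise ValueError("level 4 requires similarity-based sample weights")
    model = estimate_models(states, actions, rewards, next_states, sample_weight)
    values = action_values_for_level(level, model, gamma=gamma, tol=tol)
    argmax_sets = _argmax_sets(values)
    rng = check_random_state(rng) if tie_break == "random" else None
    mapping = _resolve_ties(argmax_sets, tie_break, rng)
    return Policy(level=level, mapping=mapping, argmax_sets=argmax_sets,
                  action_values=values)


def _extract_columns(X):
    if isinstance(X, pd.DataFrame):
        missing = [c for c in SAMPLE_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"transition log is missing columns {missing}")
        return tuple(X[c].to_numpy() for c in SAMPLE_COLUMNS)
    if isinstance(X, dict):
        return tuple(np.asarray(X[c]) for c in SAMPLE_COLUMNS)
    raise TypeError(
        "X must be a DataFrame or mapping with columns "
        f"{SAMPLE_COLUMNS}"
    )


class PolicyLearner(BaseEstimator):
    """Batch policy learner for persuasive-message selection.

    Estimates tabular reward/transition models from a log of persuasive
    attempts and derives the greedy policy of the requested complexity level.

    Parameters
    ----------
    level : int, default=3
        Complexity level 1-4 (see module docstring).
    gamma : float, default=0.85
        Discount factor for the Q-value levels (3 and 4); favors rewards
        in the near future.
    tol : float, default=1e-9
        Sup-norm convergence tolerance of value iteration.
    tie_break : {"canonical", "random"}, default="canonical"
        How ``predict`` resolves tied action values.
    random_state : int, RandomState or None
        Randomness source for ``tie_break="random"``.

    Attributes
    ----------
    model_ : ModelEstimate
        Estimated reward/transition/support tables.
    action_values_ : ndarray of shape (8, 5)
        The criterion table the level maximizes.
    policy_ : Policy
        Greedy policy with tie information.

    Examples
    --------
    >>> import pandas as pd
    >>> log = pd.DataFrame({"state": [0, 0], "action": [0, 1],
    ...                     "reward": [0.5, -0.5], "next_state": [1, 0]})
    >>> PolicyLearner(level=2).fit(log).predict([0])
    array([0])
    """

    def __init__(self, level: int = 3, gamma: float = 0.85, tol: float = 1e-9,
                 tie_break: str = "canonical", random_state=None):
        self.level = level
        self.gamma = gamma
        self.tol = tol
        self.tie_break = tie_break
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None):
        """Fit from a transition log.

        Parameters
        ----------
        X : DataFrame or mapping
            Must provide columns ``state``, ``action``, ``reward``,
            ``next_state`` (integer state indices 0-7, action codes 0-4,
            rewards in [-1, 1]).
        y : ignored
        sample_weight : array-like, optional
            Positive similarity weights; required for ``level=4``.
        """
        states, actions, rewards, next_states = _extract_columns(X)
        rng = check_random_state(self.random_state)
        policy = policy_for_level(
            self.level, states, actions, rewards, next_states,
            gamma=self.gamma, sample_weight=sample_weight,
            tie_break=self.tie_break, rng=rng, tol=self.tol,
        )
        self.model_ = estimate_models(states, actions, rewards, next_states,
                                      sample_weight)
        self.action_values_ = policy.action_values
        self.policy_ = policy
        self.n_features_in_ = len(SAMPLE_COLUMNS)
        return self

    def predict(self, states) -> np.ndarray:
        """Recommended action codes for an array of state indices."""
        check_is_fitted(self, "policy_")
        states = np.asarray(states, dtype=np.intp)
        if np.any((states < 0) | (states >= N_STATES)):
            raise ValueError("state indices must lie in [0, 8)")
        return self.policy_.mapping[states]


def render_policy(policy: Policy, feature_labels) -> str:
    """Human-readable policy table.

    One row per selected state feature (most significant bit first) showing
    its bit value in each of the 8 states, then the chosen action
    abbreviation per state.
    """
    if len(feature_labels) != 3:
        raise ValueError("expected the 3 selected feature labels")
    width = max(len(str(l)) for l in feature_labels)
    header = f"{'State feature':<{width}}  " + "  ".join(
        f"{s + 1:>4}" for s in range(N_STATES)
    )
    lines = [f"Complexity level {policy.level}", header]
    for bit_pos, label in enumerate(feature_labels):
        bits = [(s >> (2 - bit_pos)) & 1 for s in range(N_STATES)]
        lines.append(
            f"{str(label):<{width}}  " + "  ".join(f"{b:>4}" for b in bits)
        )
    abbrevs = [ACTIONS[a].abbreviation for a in policy.mapping]
    lines.append(
        f"{'Action':<{width}}  " + "  ".join(f"{a:>4}" for a in abbrevs)
    )
    return "\n".join(lines)
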