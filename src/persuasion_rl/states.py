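"""State abstraction: binarization and 3-feature selection.

Users answer ten 5-point questionnaire items per session (seven COM-B
self-evaluation items, self-efficacy, smoker identity, physical-activity
identity). To keep the state space learnable from a small training batch the
ten raw features are (a) binarized at their training-batch means (value >=
mean -> 1) and (b) reduced to the three most action-value-relevant bits,
giving 2^3 = 8 abstract states.

Feature selection scores each candidate bit by how much the action values of
the two-state MDP induced by that bit alone differ between its two sides:
``score(f) = sum_a |V(f=1, a) - V(f=0, a)|``, where V is the per-side mean
reward (level 2) or the single-bit Q-value at the configured discount
(levels 3-4). This captures the G-algorithm's test of whether a bit changes
action values, without growing its recursive tree.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .actions import N_ACTIONS, N_RAW_FEATURES, N_SELECTED_FEATURES

#: Labels for the ten raw state features. Five have established wording;
#: the rest are study configuration and default to generic placeholders.
DEFAULT_FEATURE_LABELS = (
    "Knowing why it is important to do an activity (F1)",
    "State feature F2",
    "State feature F3",
    "Feeling like being part of a group that is doing these kinds of "
    "activities (F4)",
    "Feeling like wanting to do an activity (F5)",
    "State feature F6",
    "Thinking that it would be a good thing to do an activity (F7)",
    "Thinking they can do an activity (F8)",
    "State feature F9 (smoker identity)",
    "State feature F10 (physical activity identity)",
)


def fit_thresholds(raw_vectors) -> np.ndarray:
    """Per-feature arithmetic means of the training batch (split points)."""
    X = np.asarray(raw_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a nonempty 2-D array of raw state vectors")
    if X.shape[1] != N_RAW_FEATURES:
        raise ValueError(f"expected {N_RAW_FEATURES} raw features")
    return X.mean(axis=0)


def binarize(raw_vectors, thresholds) -> np.ndarray:
    """1 where a raw answer is >= its feature threshold, else 0."""
    X = np.atleast_2d(np.asarray(raw_vectors, dtype=float))
    thresholds = np.asarray(thresholds, dtype=float)
    if X.shape[1] != thresholds.shape[0]:
        raise ValueError("raw vectors and thresholds must have equal width")
    return (X >= thresholds).astype(np.int8)


class StateBinarizer(TransformerMixin, BaseEstimator):
    """Binarize raw questionnaire answers at their training-batch means.

    Thresholds are fit once on the training batch and frozen, mirroring how
    the mean-effort reward anchor is handled.

    Attributes
    ----------
    thresholds_ : ndarray of shape (10,)
        Per-feature means of the training batch.
    """

    def fit(self, X, y=None):
        self.thresholds_ = fit_thresholds(X)
        self.n_features_in_ = self.thresholds_.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return binarize(X, self.thresholds_)


def _two_state_values(bits_f, actions, rewards, next_bits_f, level, gamma, tol):
    """Action-value table (2, n_actions) of the MDP induced by one bit."""
    support = np.zeros((2, N_ACTIONS, 2))
    wr = np.zeros_like(support)
    np.add.at(support, (bits_f, actions, next_bits_f), 1.0)
    np.add.at(wr, (bits_f, actions, next_bits_f), rewards)
    reward = np.divide(wr, support, out=np.zeros_like(wr), where=support > 0)
    mass = support.sum(axis=2, keepdims=True)
    transition = np.divide(
        support, mass, out=np.full_like(support, 0.5), where=mass > 0
    )
    er = np.einsum("sap,sap->sa", transition, reward)
    if level == 2 or gamma == 0.0:
        return er
    q = np.zeros((2, N_ACTIONS))
    while True:
        q_new = er + gamma * transition.dot(q.max(axis=1))
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new


def feature_scores(
    bits, actions, rewards, next_bits, level: int = 3,
    gamma: float = 0.85, tol: float = 1e-9,
) -> np.ndarray:
    """Selection score per raw feature.

    Constant features score exactly 0 (a bit that never varies cannot change
    action values).
    """
    bits = np.asarray(bits, dtype=np.intp)
    actions = np.asarray(actions, dtype=np.intp)
    rewards = np.asarray(rewards, dtype=float)
    next_bits = np.asarray(next_bits, dtype=np.intp)
    if level not in (2, 3, 4):
        raise ValueError("feature selection applies to levels 2-4")
    n_features = bits.shape[1]
    scores = np.zeros(n_features)
    for f in range(n_features):
        col = bits[:, f]
        if col.min() == col.max():
            continue
        values = _two_state_values(
            col, actions, rewards, next_bits[:, f], level, gamma, tol
        )
        scores[f] = np.abs(values[1] - values[0]).sum()
    return scores


def select_features(
    bits, actions, rewards, next_bits, level: int = 3,
    gamma: float = 0.85, tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the three highest-scoring features.

    Returns ``(chosen, scores)`` with ``chosen`` ordered by score descending
    (the first chosen feature becomes the most significant state bit); score
    ties break toward the lowest feature index.
    """
    scores = feature_scores(bits, actions, rewards, next_bits, level, gamma, tol)
    if scores.shape[0] < N_SELECTED_FEATURES:
        raise ValueError("need at least 3 candidate features")
    # stable sort on (-score, index)
    order = np.lexsort((np.arange(scores.shape[0]), -scores))
    return order[:N_SELECTED_FEATURES], scores


def encode_state(bits3) -> np.ndarray:
    """Binary-encode bit triples to state indices 0-7 (first bit = MSB)."""
    b = np.atleast_2d(np.asarray(bits3, dtype=np.intp))
    if b.shape[1] != N_SELECTED_FEATURES:
        raise ValueError("expected bit triples")
    if np.any((b < 0) | (b > 1)):
        raise ValueError("bits must be 0 or 1")
    return 4 * b[:, 0] + 2 * b[:, 1] + b[:, 2]


def decode_state(index) -> np.ndarray:
    """Inverse of `encode_state`."""
    s = np.atleast_1d(np.asarray(index, dtype=np.intp))
    if np.any((s < 0) | (s > 7)):
        raise ValueError("state indices must lie in [0, 8)")
    return np.stack([(s >> 2) & 1, (s >> 1) & 1, s & 1], axis=1)


class FeatureSelector(TransformerMixin, BaseEstimator):
    """Select the 3 state bits with the largest action-value separation.

    Parameters
    ----------
    level : int, default=3
        Complexity level whose criterion scores features: mean rewards for
        level 2, single-bit Q-values for levels 3-4.
    gamma : float, default=0.85
        Discount used for the Q-value criterion.

    Attributes
    ----------
    chosen_ : ndarray of shape (3,)
        Selected feature indices, bit-significance order.
    scores_ : ndarray of shape (10,)
        Selection score of every candidate feature.
    """

    def __init__(self, level: int = 3, gamma: float = 0.85, tol: float = 1e-9):
        self.level = level
        self.gamma = gamma
        self.tol = tol

    def fit(self, X, y=None, *, actions=None, rewards=None, next_bits=None):
        """Fit on binarized training vectors plus their transitions.

        ``X`` is the (n, 10) bit matrix; ``actions``, ``rewards`` and
        ``next_bits`` align with its rows.
        """
        if actions is None or rewards is None or next_bits is None:
            raise ValueError("actions, rewards and next_bits are required")
        self.chosen_, self.scores_ = select_features(
            X, actions, rewards, next_bits, self.level, self.gamma, self.tol
        )
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Map (n, 10) bit matrices to abstract state indices 0-7."""
        check_is_fitted(self, "chosen_")
        bits = np.atleast_2d(np.asarray(X, dtype=np.intp))
        return encode_state(bits[:, self.chosen_])

    def labels(self, feature_labels=DEFAULT_FEATURE_LABELS) -> list[str]:
        check_is_fitted(self, "chosen_")
        return [feature_labels[f] for f in self.chosen_]
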