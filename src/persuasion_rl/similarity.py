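"""Person similarity and sample weighting for the personalized policy.

Each person is described by a six-dimensional trait vector: the five Big-Five
personality dimensions and the transtheoretical-model (TTM) stage of change
for physical activity, each min-max scaled to [0, 1]. Similarity between two
people maps the Euclidean distance between their trait vectors linearly so
that the smallest observed distance becomes similarity 1 and the largest
similarity 0. A sample contributed by person j receives, for target person i,
the weight

    w_ij = max(s_ij / sum_k s_ik, 0.0001)

where the floor guarantees no sample is ever ignored entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

WEIGHT_FLOOR = 1e-4

#: Instrument bounds: personality items on a 1-7 scale, TTM stage 1-5.
PERSONALITY_BOUNDS = (1.0, 7.0)
TTM_BOUNDS = (1.0, 5.0)

TRAIT_COLUMNS = (
    "extraversion", "agreeableness", "conscientiousness",
    "emotional_stability", "openness", "ttm_stage",
)


def scale_traits(
    raw_personality,
    raw_ttm,
    personality_bounds=PERSONALITY_BOUNDS,
    ttm_bounds=TTM_BOUNDS,
) -> np.ndarray:
    """Min-max scale raw traits to the six-dimensional [0, 1] vector.

    Scaling uses the instrument bounds, not observed sample extremes, so a
    person's scaled vector does not change as the cohort grows.
    """
    p = np.atleast_2d(np.asarray(raw_personality, dtype=float))
    t = np.atleast_1d(np.asarray(raw_ttm, dtype=float))
    if p.shape[1] != 5:
        raise ValueError("expected five personality dimensions")
    if p.shape[0] != t.shape[0]:
        raise ValueError("personality and TTM inputs must align")
    p_lo, p_hi = personality_bounds
    t_lo, t_hi = ttm_bounds
    if np.any((p < p_lo) | (p > p_hi)) or np.any((t < t_lo) | (t > t_hi)):
        raise ValueError("trait values outside instrument bounds")
    scaled = np.column_stack([
        (p - p_lo) / (p_hi - p_lo),
        (t - t_lo) / (t_hi - t_lo),
    ])
    if np.ndim(raw_ttm) == 0:
        return scaled[0]
    return scaled


def pairwise_similarity(target, others) -> np.ndarray:
    """Similarities of ``target`` to each row of ``others``.

    Euclidean distances are mapped linearly: the smallest distance becomes
    similarity 1, the largest 0. If all distances coincide (including the
    single-other case) there is no information to discriminate and every
    similarity is 1, which makes the personalized level reduce to the
    unweighted one.
    """
    target = np.asarray(target, dtype=float)
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.shape[0] == 0:
        raise ValueError("need at least one other person")
    if others.shape[1] != target.shape[0]:
        raise ValueError("trait vectors must share dimensionality")
    d = np.linalg.norm(others - target, axis=1)
    d_min, d_max = d.min(), d.max()
    if d_max == d_min:
        return np.ones_like(d)
    return (d_max - d) / (d_max - d_min)


def sample_weights(similarities) -> np.ndarray:
    """Normalized, floored per-contributor weights (w = max(s/Σs, 0.0001))."""
    s = np.asarray(similarities, dtype=float)
    if np.any(s < 0):
        raise ValueError("similarities must be nonnegative")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero similarities: weight normalizer undefined")
    return np.maximum(s / total, WEIGHT_FLOOR)


class TraitSimilarity(BaseEstimator):
    """Similarity-weight provider over a cohort trait table.

    ``fit`` ingests a per-person trait table; ``sample_weight_for`` returns
    Eq-style weights aligned with an arbitrary sequence of contributor
    person ids (one logged sample per entry). A target person present in the
    table contributes at distance 0, i.e. with maximal similarity.

    Parameters
    ----------
    personality_bounds, ttm_bounds : (low, high)
        Instrument bounds used for min-max scaling.
    """

    def __init__(self, personality_bounds=PERSONALITY_BOUNDS,
                 ttm_bounds=TTM_BOUNDS):
        self.personality_bounds = personality_bounds
        self.ttm_bounds = ttm_bounds

    def fit(self, X, y=None):
        """Fit on a trait table.

        ``X`` is a DataFrame with a ``person_id`` column plus the six trait
        columns (five personality dimensions on the personality scale and
        ``ttm_stage``).
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a trait-table DataFrame")
        missing = [c for c in ("person_id", *TRAIT_COLUMNS) if c not in X.columns]
        if missing:
            raise ValueError(f"trait table is missing columns {missing}")
        scaled = scale_traits(
            X[list(TRAIT_COLUMNS[:5])].to_numpy(),
            X["ttm_stage"].to_numpy(),
            self.personality_bounds, self.ttm_bounds,
        )
        self.person_ids_ = X["person_id"].to_numpy()
        self.traits_ = scaled
        self._row_of = {pid: i for i, pid in enumerate(self.person_ids_)}
        return self

    def trait_vector(self, person_id) -> np.ndarray:
        check_is_fitted(self, "traits_")
        return self.traits_[self._row_of[person_id]]

    def median_traits(self) -> np.ndarray:
        """Component-wise median trait vector of the cohort."""
        check_is_fitted(self, "traits_")
        return np.median(self.traits_, axis=0)

    def similarities_to(self, target) -> np.ndarray:
        """Per-person similarities of a target trait vector to the cohort."""
        check_is_fitted(self, "traits_")
        return pairwise_similarity(np.asarray(target, dtype=float), self.traits_)

    def sample_weight_for(self, target, sample_person_ids) -> np.ndarray:
        """Per-sample weights for a target person or trait vector.

        Parameters
        ----------
        target : person id or array-like of shape (6,)
            A person id present in the fitted table, or a scaled trait
            vector.
        sample_person_ids : sequence
            Contributor person id of each logged sample; the returned array
            aligns with it.
        """
        check_is_fitted(self, "traits_")
        if np.ndim(target) == 0 and target in self._row_of:
            target = self.trait_vector(target)
        sims = self.similarities_to(target)
        per_person = sample_weights(sims)
        rows = np.array([self._row_of[p] for p in np.asarray(sample_person_ids)])
        return per_person[rows]
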