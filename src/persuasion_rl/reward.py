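"""Reward signal derived from self-reported effort.

Effort is reported on a 0-10 scale. Rewards are anchored at the mean effort
``mean_effort`` of the training batch: an effort equal to the mean maps to 0,
efforts below it are spaced linearly down to -1 at effort 0, efforts above it
linearly up to +1 at effort 10::

    r = -1 + e / mean_effort            if e < mean_effort
    r = 1 - (10 - e) / (10 - mean_effort)   if e > mean_effort
    r = 0                               otherwise

``mean_effort`` is computed once on the training batch and frozen; all later
rewards use the frozen value.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

MAX_EFFORT = 10.0


def compute_mean_effort(efforts: Iterable[float]) -> float:
    """Arithmetic mean effort of a training batch.

    Raises
    ------
    ValueError
        If ``efforts`` is empty or contains values outside [0, 10].
    """
    arr = np.asarray(list(efforts), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute mean effort of an empty sample list")
    if np.any((arr < 0) | (arr > MAX_EFFORT)) or np.any(np.isnan(arr)):
        raise ValueError("efforts must lie in [0, 10]")
    return float(arr.mean())


def compute_reward(effort, mean_effort: float):
    """Map effort ratings to rewards in [-1, 1], anchored at ``mean_effort``.

    Parameters
    ----------
    effort : float or array-like
        Effort rating(s) in [0, 10].
    mean_effort : float
        Frozen training-batch mean effort; must lie strictly inside (0, 10),
        otherwise one of the two linear branches degenerates.

    Returns
    -------
    float or ndarray
        Reward(s) in [-1, 1]; scalar input gives a scalar.
    """
    if not 0.0 < mean_effort < MAX_EFFORT:
        raise ValueError(
            f"mean_effort must lie in (0, 10), got {mean_effort!r}"
        )
    e = np.asarray(effort, dtype=float)
    if np.any((e < 0) | (e > MAX_EFFORT)):
        raise ValueError("effort must lie in [0, 10]")
    below = -1.0 + e / mean_effort
    above = 1.0 - (MAX_EFFORT - e) / (MAX_EFFORT - mean_effort)
    r = np.where(e < mean_effort, below, np.where(e > mean_effort, above, 0.0))
    if np.ndim(effort) == 0:
        return float(r)
    return r
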