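"""Policy-agreement analysis across activity types.

Tests whether the optimal persuasion policy transfers between activity
domains (smoking cessation vs. physical activity): repeatedly subsample
equal numbers of logged transitions per activity type, compute the optimal
policy of a complexity level on each draw (ties resolved uniformly at
random), concatenate the per-state action choices over repetitions into one
label list per data type, and compare lists with Cohen's kappa, interpreted
on the Landis-Koch bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from sklearn.utils.validation import check_random_state

from .actions import ACTIVITY_TYPES, N_STATES
from .policy import policy_for_level

BOTH = "BOTH"

LANDIS_KOCH_BANDS = (
    (0.00, "poor"),
    (0.21, "slight"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (1.01, "almost perfect"),
)


@dataclass(frozen=True)
class PolicyList:
    """Concatenated optimal policies: ``reps`` blocks of 8 state actions."""

    labels: np.ndarray
    source: str
    level: int

    def __post_init__(self):
        if self.labels.shape[0] % N_STATES != 0:
            raise ValueError("label list length must be a multiple of 8")


def resample_policies(
    samples: pd.DataFrame,
    source: str,
    level: int,
    n_per_type: int = 1000,
    reps: int = 100,
    rng=None,
    gamma: float = 0.85,
    similarity=None,
    reference_traits=None,
    replace: bool = False,
) -> PolicyList:
    """Optimal policies over repeated subsamples of one data type.

    Parameters
    ----------
    samples : DataFrame
        Transition frame with ``state``, ``action``, ``reward``,
        ``next_state``, ``activity_type`` (and ``person_id`` for level 4).
    source : {"SMOKING", "PHYSICAL_ACTIVITY", "BOTH"}
        Which activity type(s) to draw from. ``BOTH`` draws ``n_per_type``
        transitions from each type (2 x n_per_type total).
    level : {2, 3, 4}
        Complexity level whose optimal policy is computed per draw.
    n_per_type, reps : int
        Draw size per type (without replacement unless ``replace``) and
        number of repetitions.
    similarity : fitted TraitSimilarity, required for level 4
        Supplies per-sample weights for the reference person.
    reference_traits : array-like of shape (6,), optional
        Scaled trait vector the level-4 policy is computed for; defaults to
        the cohort's component-wise median.
    """
    if level not in (2, 3, 4):
        raise ValueError("agreement analysis applies to levels 2-4")
    if source not in (*ACTIVITY_TYPES, BOTH):
        raise ValueError(f"unknown data type {source!r}")
    if level == 4 and similarity is None:
        raise ValueError("level 4 requires a fitted TraitSimilarity")
    rng = check_random_state(rng)
    types = ACTIVITY_TYPES if source == BOTH else (source,)
    pools = []
    for t in types:
        idx = np.flatnonzero(samples["activity_type"].to_numpy() == t)
        if not replace and idx.shape[0] < n_per_type:
            raise ValueError(
                f"only {idx.shape[0]} samples of type {t}, need {n_per_type}")
        pools.append(idx)
    if level == 4 and reference_traits is None:
        reference_traits = similarity.median_traits()

    labels = np.empty(reps * N_STATES, dtype=np.intp)
    for rep in range(reps):
        take = np.concatenate([
            rng.choice(pool, size=n_per_type, replace=replace)
            for pool in pools
        ])
        sub = samples.iloc[take]
        weights = None
        if level == 4:
            weights = similarity.sample_weight_for(
                reference_traits, sub["person_id"].to_numpy())
        pol = policy_for_level(
            level, sub["state"], sub["action"], sub["reward"],
            sub["next_state"], gamma=gamma, sample_weight=weights,
            tie_break="random", rng=rng,
        )
        labels[rep * N_STATES:(rep + 1) * N_STATES] = pol.mapping
    return PolicyList(labels=labels, source=source, level=level)


def cohens_kappa(a, b) -> float:
    """Chance-corrected agreement between two action-label lists.

    Expected agreement uses the two lists' marginal label frequencies. Two
    identical constant lists (expected agreement 1) are defined to agree
    perfectly (kappa 1).
    """
    a = np.asarray(a.labels if isinstance(a, PolicyList) else a)
    b = np.asarray(b.labels if isinstance(b, PolicyList) else b)
    if a.shape != b.shape:
        raise ValueError("policy lists must have equal length")
    if a.shape[0] == 0:
        raise ValueError("policy lists must be nonempty")
    # degenerate case: both lists constant
    if np.all(a == a[0]) and np.all(b == b[0]):
        return 1.0 if a[0] == b[0] else 0.0
    return float(cohen_kappa_score(a, b))


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa < 0:
        return "poor"
    for upper, label in LANDIS_KOCH_BANDS:
        if kappa < upper:
            return label
    return "almost perfect"  # pragma: no cover


def agreement_report(
    samples: pd.DataFrame,
    levels=(2, 3, 4),
    n_per_type: int = 1000,
    reps: int = 100,
    rng=None,
    gamma: float = 0.85,
    similarity=None,
) -> pd.DataFrame:
    """Main and reference kappa analyses for each complexity level.

    Main rows compare each single activity type against the pooled data;
    reference rows compare two independent resamples of the same data type
    (an upper bound on attainable agreement).
    """
    rng = check_random_state(rng)
    pairs = [(t, BOTH) for t in ACTIVITY_TYPES]
    pairs += [(s, s) for s in (BOTH, *ACTIVITY_TYPES)]
    rows = []
    for level in levels:
        for left, right in pairs:
            kw = dict(n_per_type=n_per_type, reps=reps, gamma=gamma,
                      similarity=similarity)
            la = resample_policies(samples, left, level, rng=rng, **kw)
            lb = resample_policies(samples, right, level, rng=rng, **kw)
            k = cohens_kappa(la, lb)
            rows.append({
                "analysis": "reference" if left == right else "main",
                "data_type_a": left, "data_type_b": right, "level": level,
                "kappa": round(k, 4), "interpretation": interpret_kappa(k),
            })
    return pd.DataFrame(rows)
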