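"""Synthetic longitudinal cohorts in the published persuasion-log schema.

Generates per-person session records (raw questionnaire answers, assigned
activity, persuasion type, reported effort) from a configurable ground truth:
per-(state, action) mean effort, state-transition kernel, Gaussian effort
noise, and optionally trait-cluster-specific action effectiveness. Every
other module is testable against these cohorts without any download.

The generator mirrors the study protocol: five sessions; a random persuasion
type in sessions 1-2 (training data) and a supplied policy afterwards; one
smoking-cessation and one physical-activity activity in sessions 1-2 and
again in 3-4, the fifth session's type chosen at random; no activity (nor a
member of its declared similarity group) ever repeated for a person.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actions import ACTIVITY_TYPES, N_ACTIONS, N_RAW_FEATURES, N_STATES, ACTIONS
from .states import decode_state

RAW_ANSWER_COLUMNS = tuple(f"answer_{i + 1}" for i in range(N_RAW_FEATURES))

COHORT_COLUMNS = (
    "person_id", "session", *RAW_ANSWER_COLUMNS,
    "activity_id", "activity_type", "action", "effort",
)


@dataclass(frozen=True)
class ActivityPool:
    """24 preparatory activities, 12 per activity type.

    ``similarity_group`` declares which activities are near-duplicates across
    types (e.g. the same rule-setting exercise phrased for smoking and for
    physical activity); once any member of a group is assigned, the rest are
    ineligible for that person.
    """

    ids: tuple[str, ...]
    types: tuple[str, ...]
    similarity_group: tuple[int, ...]

    @classmethod
    def default(cls) -> "ActivityPool":
        ids, types, groups = [], [], []
        for g in range(12):
            ids += [f"S{g + 1:02d}", f"P{g + 1:02d}"]
            types += [ACTIVITY_TYPES[0], ACTIVITY_TYPES[1]]
            groups += [g, g]
        return cls(tuple(ids), tuple(types), tuple(groups))

    def __post_init__(self):
        if len(self.ids) != len(self.types) or len(self.ids) != len(self.similarity_group):
            raise ValueError("ids, types and similarity_group must align")
        for t in ACTIVITY_TYPES:
            if sum(x == t for x in self.types) != 12:
                raise ValueError("activity pool must hold 12 activities per type")

    def type_of(self, activity_id: str) -> str:
        return self.types[self.ids.index(activity_id)]


@dataclass(frozen=True)
class TraitEffect:
    """Cluster-specific action effectiveness.

    People whose scaled trait ``dim`` is >= ``cutoff`` form cluster 1, the
    rest cluster 0; each cluster has its own (8, 5) mean-effort table. Used
    to plant populations whose best actions differ, the situation the
    similarity-weighted policy level exists for.
    """

    effort_means: tuple
    dim: int = 5
    cutoff: float = 0.5

    def cluster_of(self, scaled_traits: np.ndarray) -> int:
        return int(scaled_traits[self.dim] >= self.cutoff)


@dataclass(frozen=True)
class GroundTruth:
    """Data-generating process of a synthetic cohort.

    Parameters
    ----------
    effort_mean : ndarray (8, 5)
        True mean effort (0-10 scale) per (state, action).
    transition : ndarray (8, 5, 8)
        True next-state kernel; rows sum to 1.
    noise_sd : float
        SD of the Gaussian noise added to effort before rounding/clipping.
        Defaults to 2.5, the order of the effort SDs observed in studies on
        this 0-10 scale.
    person_sd : float
        SD of a persistent per-person effort offset (individual reporting
        tendency); 0 disables it.
    trait_effect : TraitEffect or None
        Optional cluster-specific effort tables overriding ``effort_mean``.
    signal_features : tuple of 3 ints
        Which of the ten raw questionnaire features carry the three state
        bits (most significant first). The remaining features are answered
        as pure noise.
    """

    effort_mean: np.ndarray
    transition: np.ndarray
    noise_sd: float = 2.5
    person_sd: float = 0.0
    trait_effect: TraitEffect | None = None
    signal_features: tuple[int, int, int] = (4, 3, 7)

    def __post_init__(self):
        em = np.asarray(self.effort_mean, dtype=float)
        tr = np.asarray(self.transition, dtype=float)
        if em.shape != (N_STATES, N_ACTIONS):
            raise ValueError("effort_mean must have shape (8, 5)")
        if np.any((em < 0) | (em > 10)):
            raise ValueError("effort means must lie in [0, 10]")
        if tr.shape != (N_STATES, N_ACTIONS, N_STATES):
            raise ValueError("transition must have shape (8, 5, 8)")
        if not np.allclose(tr.sum(axis=2), 1.0, atol=1e-9) or np.any(tr < 0):
            raise ValueError("transition rows must be distributions")
        if self.noise_sd < 0 or self.person_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if len(set(self.signal_features)) != 3:
            raise ValueError("signal_features must name 3 distinct features")
        object.__setattr__(self, "effort_mean", em)
        object.__setattr__(self, "transition", tr)

    @classmethod
    def random(cls, rng, noise_sd: float = 2.5, **kwargs) -> "GroundTruth":
        """A random dense ground truth (Dirichlet transitions)."""
        rng = np.random.default_rng(rng)
        em = rng.uniform(2.0, 8.0, size=(N_STATES, N_ACTIONS))
        tr = rng.dirichlet(np.ones(N_STATES), size=(N_STATES, N_ACTIONS))
        return cls(effort_mean=em, transition=tr, noise_sd=noise_sd, **kwargs)

    @classmethod
    def planted(cls, best_actions, base: float = 4.0, margin: float = 2.0,
                rng=None, noise_sd: float = 1.0, **kwargs) -> "GroundTruth":
        """Ground truth with a unique best action planted in every state."""
        best = np.asarray(best_actions, dtype=np.intp)
        if best.shape != (N_STATES,):
            raise ValueError("need one planted action per state")
        em = np.full((N_STATES, N_ACTIONS), base)
        em[np.arange(N_STATES), best] = base + margin
        rng = np.random.default_rng(rng)
        tr = rng.dirichlet(np.ones(N_STATES), size=(N_STATES, N_ACTIONS))
        return cls(effort_mean=em, transition=tr, noise_sd=noise_sd, **kwargs)


@dataclass(frozen=True)
class CohortConfig:
    """Study-shaped cohort: 516 people (the trained batch) over 5 sessions."""

    n_people: int = 516
    n_sessions: int = 5
    seed: int = 0
    dropout_rate: float = 0.0
    pool: ActivityPool = field(default_factory=ActivityPool.default)

    def __post_init__(self):
        if self.n_people <= 0:
            raise ValueError("n_people must be positive")
        if not 1 <= self.n_sessions <= 5:
            raise ValueError("n_sessions must lie in 1-5")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def assign_activity(history, session: int, rng, pool: ActivityPool | None = None):
    """Pick the next activity for a person, honoring the protocol rules.

    Sessions 1-2 cover both activity types in random order, sessions 3-4
    likewise; the fifth session's type is uniform random. The activity is
    uniform over pool members of the required type whose id and similarity
    group are still unused.

    Parameters
    ----------
    history : sequence of str
        Activity ids already assigned to this person, session order.
    session : int
        1-based session number (1-5).
    rng : numpy Generator

    Returns
    -------
    (activity_id, activity_type)
    """
    pool = pool or ActivityPool.default()
    rng = np.random.default_rng(rng)
    if not 1 <= session <= 5:
        raise ValueError("session must lie in 1-5")
    if len(history) != session - 1:
        raise ValueError("history must hold one activity per prior session")
    if session in (2, 4):
        prev_type = pool.type_of(history[session - 2])
        activity_type = next(t for t in ACTIVITY_TYPES if t != prev_type)
    else:
        activity_type = ACTIVITY_TYPES[rng.integers(2)]
    used_groups = {pool.similarity_group[pool.ids.index(a)] for a in history}
    eligible = [
        i for i, (aid, atype, grp) in enumerate(
            zip(pool.ids, pool.types, pool.similarity_group))
        if atype == activity_type and aid not in history
        and grp not in used_groups
    ]
    if not eligible:
        raise RuntimeError("activity pool exhausted for this person")
    idx = eligible[rng.integers(len(eligible))]
    return pool.ids[idx], pool.types[idx]


def _raw_answers(state_bits: np.ndarray, signal_features, rng) -> np.ndarray:
    """Raw 1-5 answers whose binarized signal features encode the state."""
    answers = rng.integers(1, 6, size=N_RAW_FEATURES)
    for bit, feat in zip(state_bits, signal_features):
        answers[feat] = rng.integers(4, 6) if bit else rng.integers(1, 3)
    return answers


def generate_cohort(
    config: CohortConfig,
    truth: GroundTruth,
    policy=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (session records, trait table).

    The ``effort`` on a session's row is the effort the person later reports
    for that session's activity; it is missing (NaN) when no follow-up
    session observed it (the final session, or dropout).

    ``policy``, if given, is a callable ``(state_index, scaled_traits) ->
    action code`` applied from session 3 on; sessions 1-2 always use a
    uniformly random persuasion type, mirroring the training protocol.
    """
    rng = np.random.default_rng(config.seed)
    records: list[dict] = []
    traits_rows: list[dict] = []
    from .similarity import TRAIT_COLUMNS, scale_traits

    for p in range(config.n_people):
        pid = f"p{p:05d}"
        personality = rng.uniform(1.0, 7.0, size=5)
        ttm = int(rng.integers(1, 6))
        scaled = scale_traits(personality, ttm)
        traits_rows.append({
            "person_id": pid,
            **dict(zip(TRAIT_COLUMNS[:5], np.round(personality, 3))),
            "ttm_stage": ttm,
        })
        if truth.trait_effect is not None:
            effort_mean = np.asarray(
                truth.trait_effect.effort_means[
                    truth.trait_effect.cluster_of(scaled)
                ], dtype=float)
        else:
            effort_mean = truth.effort_mean
        offset = rng.normal(0.0, truth.person_sd) if truth.person_sd else 0.0

        state = int(rng.integers(N_STATES))
        history: list[str] = []
        person_records: list[dict] = []
        for session in range(1, config.n_sessions + 1):
            if session > 1 and rng.random() < config.dropout_rate:
                break
            activity_id, activity_type = assign_activity(
                history, session, rng, config.pool)
            history.append(activity_id)
            if session <= 2 or policy is None:
                action = int(rng.integers(N_ACTIONS))
            else:
                action = int(policy(state, scaled))
            bits = decode_state(state)[0]
            answers = _raw_answers(bits, truth.signal_features, rng)
            effort = float(np.clip(
                np.round(effort_mean[state, action]
                         + offset + rng.normal(0.0, truth.noise_sd)),
                0, 10))
            person_records.append({
                "person_id": pid, "session": session,
                **dict(zip(RAW_ANSWER_COLUMNS, answers.tolist())),
                "activity_id": activity_id, "activity_type": activity_type,
                "action": ACTIONS[action].name, "effort": effort,
            })
            state = int(rng.choice(N_STATES, p=truth.transition[state, action]))
        # the final observed session's effort is never reported back
        if person_records:
            person_records[-1]["effort"] = np.nan
        records.extend(person_records)

    records_df = pd.DataFrame(records, columns=list(COHORT_COLUMNS))
    traits_df = pd.DataFrame(traits_rows)
    return records_df, traits_df
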