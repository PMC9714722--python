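"""End-to-end preparation of a persuasion log for policy learning.

Ties the pieces together: fit binarization thresholds and the mean-effort
reward anchor on a training batch, select the three state features, and turn
consecutive session pairs into MDP transitions ``(s, a, r, s')``. All fitted
anchors (thresholds, chosen features, mean effort) are frozen with the
training batch and reused verbatim afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .actions import Action
from .cohort import RAW_ANSWER_COLUMNS
from .reward import compute_mean_effort, compute_reward
from .states import (
    DEFAULT_FEATURE_LABELS,
    binarize,
    encode_state,
    fit_thresholds,
    select_features,
)


@dataclass(frozen=True)
class Preprocessor:
    """Frozen training-batch anchors for turning logs into transitions."""

    thresholds: np.ndarray
    chosen: np.ndarray
    scores: np.ndarray
    mean_effort: float
    level: int
    gamma: float

    def feature_labels(self, labels=DEFAULT_FEATURE_LABELS) -> list[str]:
        return [labels[f] for f in self.chosen]

    def encode(self, raw_answers) -> np.ndarray:
        bits = binarize(raw_answers, self.thresholds)
        return encode_state(bits[:, self.chosen])


def _transition_rows(records: pd.DataFrame) -> pd.DataFrame:
    """Pair consecutive sessions per person into transition rows.

    A session row becomes a transition when the next session exists (it
    carries the next state's answers and the reported effort for this
    session's activity).
    """
    req = {"person_id", "session", "action", "effort", *RAW_ANSWER_COLUMNS}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"cohort log is missing columns {sorted(missing)}")
    df = records.sort_values(["person_id", "session"], kind="stable")
    nxt = df.groupby("person_id", sort=False).shift(-1)
    has_next = nxt["session"].notna() & (nxt["session"] == df["session"] + 1)
    usable = has_next & df["effort"].notna()
    out = df.loc[usable, ["person_id", "session", "action", "effort"]].copy()
    if "activity_type" in df.columns:
        out["activity_type"] = df.loc[usable, "activity_type"]
    for c in RAW_ANSWER_COLUMNS:
        out[c] = df.loc[usable, c]
        out[f"next_{c}"] = nxt.loc[usable, c]
    return out.reset_index(drop=True)


def fit_preprocessor(
    records: pd.DataFrame, level: int = 3, gamma: float = 0.85
) -> Preprocessor:
    """Fit thresholds, feature selection and the reward anchor on a batch.

    Binarization thresholds are the per-feature means over all session state
    vectors in the batch; the mean effort is taken over every reported
    effort; feature selection scores use the level's criterion (mean rewards
    for level 2, Q-values for levels 3-4).
    """
    trans = _transition_rows(records)
    if trans.empty:
        raise ValueError("no usable transitions in the training batch")
    raw_all = records[list(RAW_ANSWER_COLUMNS)].to_numpy(dtype=float)
    thresholds = fit_thresholds(raw_all)
    mean_effort = compute_mean_effort(trans["effort"].to_numpy())
    bits = binarize(trans[list(RAW_ANSWER_COLUMNS)].to_numpy(dtype=float),
                    thresholds)
    next_cols = [f"next_{c}" for c in RAW_ANSWER_COLUMNS]
    next_bits = binarize(trans[next_cols].to_numpy(dtype=float), thresholds)
    actions = np.array([Action.from_name(a) for a in trans["action"]],
                       dtype=np.intp)
    rewards = compute_reward(trans["effort"].to_numpy(), mean_effort)
    sel_level = level if level in (2, 3, 4) else 3
    chosen, scores = select_features(
        bits, actions, rewards, next_bits, level=sel_level, gamma=gamma)
    return Preprocessor(thresholds=thresholds, chosen=chosen, scores=scores,
                        mean_effort=mean_effort, level=level, gamma=gamma)


def transform_records(
    records: pd.DataFrame, prep: Preprocessor
) -> pd.DataFrame:
    """Turn a cohort log into the transition frame `PolicyLearner` consumes.

    Columns: ``person_id``, ``session``, ``activity_type`` (when present),
    ``state``, ``action``, ``effort``, ``reward``, ``next_state``.
    """
    trans = _transition_rows(records)
    out = pd.DataFrame({
        "person_id": trans["person_id"],
        "session": trans["session"].astype(int),
        "state": prep.encode(
            trans[list(RAW_ANSWER_COLUMNS)].to_numpy(dtype=float)),
        "action": [int(Action.from_name(a)) for a in trans["action"]],
        "effort": trans["effort"].astype(float),
        "reward": compute_reward(trans["effort"].to_numpy(),
                                 prep.mean_effort),
        "next_state": prep.encode(
            trans[[f"next_{c}" for c in RAW_ANSWER_COLUMNS]]
            .to_numpy(dtype=float)),
    })
    if "activity_type" in trans.columns:
        out["activity_type"] = trans["activity_type"]
    return out


def prepare_training_frame(
    records: pd.DataFrame, level: int = 3, gamma: float = 0.85
) -> tuple[pd.DataFrame, Preprocessor]:
    """Fit the preprocessor on a log and transform the same log."""
    prep = fit_preprocessor(records, level=level, gamma=gamma)
    return transform_records(records, prep), prep
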