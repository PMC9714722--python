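"""Cleaning rules for raw submission logs.

Raw logs hold one row per submission of a study component (a session or
questionnaire) per person, with an attention-check pass count and a
submission order. Cleaning applies the study's rules:

1. drop a component submission when the person passed none of its attention
   checks;
2. when a person submitted the same component more than once, keep only the
   first recorded submission;
3. flag people without a (surviving) session-2 submission — they were never
   assigned to a condition and are excluded from condition-level analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("person_id", "component", "submission_order",
                    "attention_checks_passed")


@dataclass
class PreprocessResult:
    clean: pd.DataFrame
    excluded_persons: list = field(default_factory=list)
    n_dropped_attention: int = 0
    n_dropped_duplicates: int = 0
    n_malformed: int = 0


def preprocess_submission_log(
    log: pd.DataFrame,
    session2_component: str = "session_2",
    drop_unassigned: bool = True,
) -> PreprocessResult:
    """Apply the attention-check, first-submission and session-2 rules.

    Parameters
    ----------
    log : DataFrame
        Columns ``person_id``, ``component``, ``submission_order`` (strict
        order within a (person, component) key), ``attention_checks_passed``
        plus arbitrary payload columns.
    session2_component : str
        Component name whose absence marks a person as never assigned.
    drop_unassigned : bool
        Whether to drop flagged persons from the returned frame (they are
        always listed in ``excluded_persons``).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"submission log is missing columns {missing}")

    malformed = (log["person_id"].isna() | log["component"].isna()
                 | log["attention_checks_passed"].isna())
    if malformed.any():
        for _, row in log[malformed].iterrows():
            logger.warning("excluding malformed submission record: %s",
                           row.to_dict())
    df = log[~malformed]

    passed = df["attention_checks_passed"].astype(float) > 0
    n_attention = int((~passed).sum())
    df = df[passed]

    df = df.sort_values(["person_id", "component", "submission_order"],
                        kind="stable")
    kept = df.drop_duplicates(subset=["person_id", "component"], keep="first")
    n_dupes = len(df) - len(kept)

    have_s2 = set(kept.loc[kept["component"] == session2_component,
                           "person_id"])
    excluded = sorted(set(kept["person_id"]) - have_s2)
    if excluded:
        logger.info("persons without %s excluded from condition-level "
                    "analyses: %s", session2_component, excluded)
    clean = kept
    if drop_unassigned and excluded:
        clean = kept[kept["person_id"].isin(have_s2)]
    return PreprocessResult(
        clean=clean.reset_index(drop=True),
        excluded_persons=excluded,
        n_dropped_attention=n_attention,
        n_dropped_duplicates=n_dupes,
        n_malformed=int(malformed.sum()),
    )
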