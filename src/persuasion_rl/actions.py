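"""Action space of the persuasion MDP.

Five persuasive message types: three Cialdini strategies (commitment,
consensus, authority), action planning, and a no-persuasion control.
The listed order is canonical: it is used for deterministic tie-breaking
and for serialization, and action codes are indices into it.
"""

from __future__ import annotations

from enum import IntEnum


class Action(IntEnum):
    """Persuasion type sent together with a preparatory activity."""

    COMMITMENT = 0
    CONSENSUS = 1
    AUTHORITY = 2
    ACTION_PLANNING = 3
    NO_PERSUASION = 4

    @property
    def abbreviation(self) -> str:
        return _ABBREVIATIONS[self]

    @classmethod
    def from_name(cls, name: str) -> "Action":
        key = name.strip().upper().replace(" ", "_").replace("-", "_")
        try:
            return cls[key]
        except KeyError:
            abbrev = {v: k for k, v in _ABBREVIATIONS.items()}
            stripped = name.strip()
            if stripped in abbrev:
                return abbrev[stripped]
            raise ValueError(f"unknown action {name!r}") from None


_ABBREVIATIONS = {
    Action.COMMITMENT: "Com.",
    Action.CONSENSUS: "Con.",
    Action.AUTHORITY: "Au.",
    Action.ACTION_PLANNING: "AP",
    Action.NO_PERSUASION: "NP",
}

#: Canonical action order (tie-break / serialization order).
ACTIONS: tuple[Action, ...] = tuple(Action)

N_ACTIONS: int = len(ACTIONS)

#: Number of abstract states after binarization + 3-feature selection (2^3).
N_STATES: int = 8

#: Number of raw questionnaire state features.
N_RAW_FEATURES: int = 10

#: Number of binary features defining the abstract state.
N_SELECTED_FEATURES: int = 3

#: Activity types the coach alternates between.
ACTIVITY_TYPES: tuple[str, str] = ("SMOKING", "PHYSICAL_ACTIVITY")
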