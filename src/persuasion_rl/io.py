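"""Versioned CSV readers/writers and the run configuration.

All tabular artifacts are plain CSV with a one-line versioned header comment
so files are self-describing and the round trip is exact on records.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

SCHEMA_VERSION = 1


def _header(kind: str) -> str:
    return f"# persuasion-rl {kind} v{SCHEMA_VERSION}\n"


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_header(kind))
        df.to_csv(fh, index=False)


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# persuasion-rl"):
            raise ValueError(f"{path}: missing versioned header")
        if kind is not None and f" {kind} " not in first:
            raise ValueError(f"{path}: expected a {kind} table, got {first!r}")
        return pd.read_csv(_io.StringIO(fh.read()))


def write_cohort(records: pd.DataFrame, path) -> None:
    write_table(records, path, "cohort")


def read_cohort(path) -> pd.DataFrame:
    return read_table(path, "cohort")


def write_traits(traits: pd.DataFrame, path) -> None:
    write_table(traits, path, "traits")


def read_traits(path) -> pd.DataFrame:
    return read_table(path, "traits")


def write_samples(samples: pd.DataFrame, path) -> None:
    write_table(samples, path, "samples")


def read_samples(path) -> pd.DataFrame:
    return read_table(path, "samples")


@dataclass
class RunConfig:
    """Run parameters shared by the CLI subcommands.

    The frozen training-batch anchors (``mean_effort``, ``thresholds``,
    ``chosen_features``) are populated by ``train`` and carried along so any
    later recommendation is auditable.
    """

    gamma: float = 0.85
    tol: float = 1e-9
    tie_break: str = "canonical"
    seed: int = 0
    personality_bounds: tuple = (1.0, 7.0)
    ttm_bounds: tuple = (1.0, 5.0)
    mean_effort: float | None = None
    thresholds: list = field(default_factory=list)
    chosen_features: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["personality_bounds"] = list(d["personality_bounds"])
        d["ttm_bounds"] = list(d["ttm_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("personality_bounds", "ttm_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_preprocessor(self, prep) -> "RunConfig":
        return dataclasses.replace(
            self,
            mean_effort=float(prep.mean_effort),
            thresholds=[float(t) for t in prep.thresholds],
            chosen_features=[int(f) for f in prep.chosen],
            gamma=prep.gamma,
        )
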