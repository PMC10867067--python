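"""Trial-log domain types, CSV reading/writing, and validation.

A *trial* is one visit to a display ("patch") in a non-exhaustive foraging
task: the observer taps targets in some order and may abandon the patch at
will, so the number of picks varies freely across trials and participants.
The on-disk format is a long CSV with one row per pick.

Coordinates are screen pixels, origin at the top-left corner, y increasing
downward (touch-screen convention).  All downstream organization metrics use
only distances, segment crossings, and correlations up to sign, so they are
invariant to this choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CONDITIONS = ("feature", "conjunction")

#: canonical CSV column order
COLUMNS = (
    "participant", "age", "condition", "set_size", "trial",
    "order", "x", "y", "t", "item_class", "is_target",
)


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class ValidationError(ValueError):
    """Row-level or trial-level contract violation in a trial log."""


@dataclass
class Pick:
    """One collected item: rank within the trial plus pick-time state."""

    order: int
    x: float
    y: float
    t: float | None = None
    item_class: str = ""
    is_target: bool = True


@dataclass
class TrialRecord:
    """One patch visit: metadata plus the ordered pick sequence.

    Distractor picks (``is_target=False``) are retained in the log but are
    excluded from organization scoring and from the choice-model likelihood;
    the metrics are defined over collected targets only.
    """

    participant_id: str
    age_years: float
    condition: str
    set_size: int
    trial_index: int
    picks: list[Pick] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        self.picks = sorted(self.picks, key=lambda p: p.order)
        orders = [p.order for p in self.picks]
        if orders != list(range(1, len(orders) + 1)):
            raise ValidationError(
                f"pick orders must be consecutive 1..n, got {orders} "
                f"(participant {self.participant_id}, trial {self.trial_index})")

    @property
    def target_picks(self) -> list[Pick]:
        return [p for p in self.picks if p.is_target]

    @property
    def n_distractor_picks(self) -> int:
        return sum(not p.is_target for p in self.picks)


@dataclass
class OrgScores:
    """The four organization indicators for one pick sequence (trial or bin).

    A score whose precondition fails (too few picks, degenerate geometry) is
    ``None`` and carries a reason code in :attr:`reasons` — never silently 0.
    """

    best_r: float | None
    mean_itd: float | None
    pao: float | None
    intersection_rate: float | None
    n_picks: int
    bin_label: str = "whole"
    reasons: dict[str, str] = field(default_factory=dict)


@dataclass
class AnalysisConfig:
    """Pipeline-wide knobs, serialisable to YAML alongside every output."""

    display_width: float = 1400.0
    display_height: float = 1050.0
    min_picks_per_bin: int = 4
    tsp_exact_threshold: int = 10
    seed: int = 0
    direction_offset: float = -1.5707963267948966  # lateral bias angle, rad

    def __post_init__(self) -> None:
        if self.display_width <= 0 or self.display_height <= 0:
            raise ValueError("display bounds must be positive")
        if self.min_picks_per_bin <= 0 or self.tsp_exact_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def display_diagonal(self) -> float:
        return float((self.display_width ** 2 + self.display_height ** 2) ** 0.5)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


DEFAULT_SCHEMA: Mapping[str, str] = {c: c for c in COLUMNS}

_REQUIRED = ("participant", "age", "condition", "set_size", "trial", "order", "x", "y")


def read_trials(path: str | Path,
                schema: Mapping[str, str] | None = None) -> list[TrialRecord]:
    """Read a long-format trial-log CSV into :class:`TrialRecord` objects.

    Parameters
    ----------
    path
        CSV file with one row per pick (comma-separated, UTF-8, header row,
        ``.`` decimal mark).
    schema
        Optional mapping from canonical column names to the file's column
        names, for logs with non-default headers.

    Returns
    -------
    Trials grouped by (participant, condition, trial), picks sorted by order.

    Raises
    ------
    SchemaError
        if a required column is absent under the mapping.
    ValidationError
        on duplicate or non-consecutive pick orders, or non-numeric
        coordinates (reported with the offending CSV line number).
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, dtype={schema["participant"]: str})
    for canon in _REQUIRED:
        if schema[canon] not in df.columns:
            raise SchemaError(f"missing required column {schema[canon]!r} "
                              f"(maps to {canon!r})")
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)

    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValidationError(f"non-numeric {col!r} value at line {line}")
        df[col] = pd.to_numeric(df[col])

    if "t" not in df.columns:
        df["t"] = pd.NA
    if "item_class" not in df.columns:
        df["item_class"] = ""
    if "is_target" not in df.columns:
        df["is_target"] = True

    trials: list[TrialRecord] = []
    for (pid, cond, tidx), grp in df.groupby(
            ["participant", "condition", "trial"], sort=True):
        orders = grp["order"].to_numpy()
        if len(set(orders)) != len(orders):
            dup = grp["order"][grp["order"].duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate (trial, order) pair: trial {tidx}, order {dup}")
        picks = [
            Pick(order=int(r.order), x=float(r.x), y=float(r.y),
                 t=None if pd.isna(r.t) else float(r.t),
                 item_class="" if pd.isna(r.item_class) else str(r.item_class),
                 is_target=bool(r.is_target))
            for r in grp.itertuples()
        ]
        trials.append(TrialRecord(
            participant_id=str(pid),
            age_years=float(grp["age"].iloc[0]),
            condition=str(cond),
            set_size=int(grp["set_size"].iloc[0]),
            trial_index=int(tidx),
            picks=picks,
        ))
    return trials


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        for p in tr.picks:
            rows.append({
                "participant": tr.participant_id, "age": tr.age_years,
                "condition": tr.condition, "set_size": tr.set_size,
                "trial": tr.trial_index, "order": p.order,
                "x": p.x, "y": p.y, "t": p.t,
                "item_class": p.item_class, "is_target": p.is_target,
            })
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write trials to CSV such that ``read_trials`` round-trips them."""
    trials_to_frame(trials).to_csv(path, index=False)


def write_display_snapshots(snapshots: Mapping, path: str | Path) -> None:
    """Write per-pick remaining-target snapshots to a long CSV.

    ``snapshots`` maps a trial key (participant, condition, trial) to a
    list of ``(coords, classes, chosen_index)`` triples, one per pick.
    One CSV row per remaining target per step; the selected target is
    marked ``chosen=1``.  This is the display history the choice-model
    likelihood conditions on when items move between picks.
    """
    rows = []
    for (pid, cond, tidx), steps in snapshots.items():
        for step, (coords, classes, j) in enumerate(steps):
            coords = np.asarray(coords, dtype=float)
            for m in range(len(coords)):
                rows.append((pid, cond, tidx, step, coords[m, 0],
                             coords[m, 1], classes[m], int(m == j)))
    pd.DataFrame(rows, columns=["participant", "condition", "trial",
                                "step", "x", "y", "item_class",
                                "chosen"]).to_csv(path, index=False)


def read_display_snapshots(path: str | Path) -> dict:
    """Inverse of :func:`write_display_snapshots`."""
    df = pd.read_csv(path, dtype={"participant": str})
    out: dict = {}
    for (pid, cond, tidx), trial_grp in df.groupby(
            ["participant", "condition", "trial"], sort=True):
        steps = []
        for _, grp in trial_grp.groupby("step", sort=True):
            coords = grp[["x", "y"]].to_numpy(dtype=float)
            classes = grp["item_class"].to_numpy(dtype=str)
            chosen = int(np.flatnonzero(grp["chosen"].to_numpy())[0])
            steps.append((coords, classes, chosen))
        out[(str(pid), str(cond), int(tidx))] = steps
    return out
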