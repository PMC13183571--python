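"""Reading, validating and writing step-level walkway data.

The on-disk schema is an open, comma-separated stand-in for proprietary
pressure-walkway exports: one row per foot contact with the side, the
contact (heel-strike) and lift (toe-off) timestamps in seconds, and the
heel position in cm.  Two recorded trials are pooled into one analyzable
:class:`Walk`; stride formation downstream never crosses the trial
boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class Condition(str, enum.Enum):
    """Walking condition: preferred speed, slow speed, eyes closed."""

    PWS = "PWS"
    SWS = "SWS"
    EC = "EC"


class Foot(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


#: Columns of the footfall table, in canonical order.
FOOTFALL_COLUMNS = (
    "subject_id",
    "condition",
    "trial_index",
    "foot",
    "contact_time",
    "lift_time",
    "heel_x",
    "heel_y",
)

#: Columns of the one-row-per-subject clinical anchor table.
ANCHOR_COLUMNS = ("subject_id", "fga", "fes_i", "pcs12", "mcs12")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a footfall or anchor invariant."""


@dataclass(frozen=True)
class FootfallEvent:
    """One foot contact on the walkway."""

    subject_id: str
    condition: Condition
    trial_index: int
    foot: Foot
    contact_time: float  # s, heel strike
    lift_time: float  # s, toe off
    heel_x: float  # cm, nominal progression direction
    heel_y: float  # cm, lateral

    def __post_init__(self) -> None:
        if not self.lift_time > self.contact_time:
            raise ValidationError(
                f"lift_time ({self.lift_time}) must exceed contact_time "
                f"({self.contact_time}) for subject {self.subject_id}, "
                f"trial {self.trial_index}"
            )
        if self.trial_index < 1:
            raise ValidationError(f"trial_index must be >= 1, got {self.trial_index}")


@dataclass
class Walk:
    """Step data of two pooled walkway trials for one subject x condition.

    The unit on which gait metrics are computed.  Events keep their
    within-trial recording order; ``trial_pair`` records which two trials
    were pooled.
    """

    subject_id: str
    condition: Condition
    trial_pair: tuple[int, int]
    events: list[FootfallEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        trials = {e.trial_index for e in self.events}
        if trials and trials != set(self.trial_pair):
            raise ValidationError(
                f"walk events must come from trials {self.trial_pair}, found {sorted(trials)}"
            )

    @property
    def n_cycles(self) -> int:
        """Number of complete same-foot gait cycles (both feet, both trials)."""
        n = 0
        for trial in self.trial_pair:
            for foot in Foot:
                k = sum(1 for e in self.events if e.trial_index == trial and e.foot == foot)
                n += max(k - 1, 0)
        return n

    def events_of(self, trial: int, foot: Foot) -> list[FootfallEvent]:
        return [e for e in self.events if e.trial_index == trial and e.foot == foot]


@dataclass(frozen=True)
class AnchorRecord:
    """Clinical anchor scores for one subject.

    FGA: functional gait assessment, 0-30, higher is better.
    FES-I: falls efficacy scale international, 16-64, higher is worse.
    PCS-12 / MCS-12: SF-12 physical / mental component summaries
    (MCS-12 is carried but unused by the MCID analysis).
    """

    subject_id: str
    fga: int
    fes_i: int
    pcs12: float
    mcs12: float

    def __post_init__(self) -> None:
        if not 0 <= self.fga <= 30:
            raise ValidationError(f"FGA must be in [0, 30], got {self.fga}")
        if not 16 <= self.fes_i <= 64:
            raise ValidationError(f"FES-I must be in [16, 64], got {self.fes_i}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_footfalls(path: str | Path) -> list[FootfallEvent]:
    """Read and validate a footfall event table.

    Raises :class:`SchemaError` when a column is missing and
    :class:`ValidationError` (citing the offending row index) when a row
    violates an event invariant or same-foot events are not strictly
    ordered by contact time within a trial.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, FOOTFALL_COLUMNS, path)
    events: list[FootfallEvent] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(
                FootfallEvent(
                    subject_id=str(row.subject_id),
                    condition=Condition(row.condition),
                    trial_index=int(row.trial_index),
                    foot=Foot(row.foot),
                    contact_time=float(row.contact_time),
                    lift_time=float(row.lift_time),
                    heel_x=float(row.heel_x),
                    heel_y=float(row.heel_y),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {idx}: {exc}") from exc
    _check_same_foot_order(events)
    return events


def _check_same_foot_order(events: Iterable[FootfallEvent]) -> None:
    last: dict[tuple[str, Condition, int, Foot], float] = {}
    for i, e in enumerate(events):
        key = (e.subject_id, e.condition, e.trial_index, e.foot)
        if key in last and e.contact_time <= last[key]:
            raise ValidationError(
                f"row {i}: same-foot events must be strictly ordered by "
                f"contact_time within a trial (subject {e.subject_id}, "
                f"trial {e.trial_index}, {e.foot.value})"
            )
        last[key] = e.contact_time


def footfalls_to_frame(events: Sequence[FootfallEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in events],
            "condition": [e.condition.value for e in events],
            "trial_index": [e.trial_index for e in events],
            "foot": [e.foot.value for e in events],
            "contact_time": [e.contact_time for e in events],
            "lift_time": [e.lift_time for e in events],
            "heel_x": [e.heel_x for e in events],
            "heel_y": [e.heel_y for e in events],
        }
    )


def write_footfalls(events: Sequence[FootfallEvent], path: str | Path) -> None:
    footfalls_to_frame(events).to_csv(path, index=False)


def pool_trials(
    events: Sequence[FootfallEvent], trial_pair: tuple[int, int]
) -> Walk:
    """Pool the events of two trials into one analyzable :class:`Walk`.

    All events must belong to a single subject x condition.  Event order
    within each trial is preserved; strides are never formed across the
    trial boundary downstream.
    """
    if trial_pair[0] == trial_pair[1]:
        raise ValueError("trial_pair must name two distinct trials")
    if not events:
        raise ValueError("no events supplied")
    subjects = {e.subject_id for e in events}
    conditions = {e.condition for e in events}
    if len(subjects) != 1 or len(conditions) != 1:
        raise ValueError(
            f"pool_trials expects one subject x condition, got subjects={sorted(subjects)}, "
            f"conditions={sorted(c.value for c in conditions)}"
        )
    selected = [e for e in events if e.trial_index in trial_pair]
    present = {e.trial_index for e in selected}
    missing = set(trial_pair) - present
    if missing:
        raise ValueError(
            f"subject {next(iter(subjects))}, condition "
            f"{next(iter(conditions)).value}: trial(s) {sorted(missing)} not present"
        )
    return Walk(
        subject_id=next(iter(subjects)),
        condition=next(iter(conditions)),
        trial_pair=trial_pair,
        events=selected,
    )


def group_walks(
    events: Sequence[FootfallEvent],
    trial_pairs: Sequence[tuple[int, int]] = ((1, 2), (3, 4)),
) -> list[Walk]:
    """Split a cohort event stream into walks, one per subject x condition x trial pair.

    Walks are formed from consecutive trial pairs in recording order.
    Subjects missing a full trial pair for a condition are skipped for
    that pair.
    """
    keyed: dict[tuple[str, Condition], list[FootfallEvent]] = {}
    for e in events:
        keyed.setdefault((e.subject_id, e.condition), []).append(e)
    walks: list[Walk] = []
    for (_subject, _condition), evs in keyed.items():
        trials = {e.trial_index for e in evs}
        for pair in trial_pairs:
            if set(pair) <= trials:
                walks.append(pool_trials(evs, pair))
    return walks


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format metric table (one row per subject x condition x walk x metric)."""
    required = ("subject_id", "condition", "walk", "metric", "value")
    for col in required:
        if col not in table.columns:
            raise SchemaError(f"metric table: missing required column '{col}'")
    table.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("subject_id", "condition", "walk", "metric", "value"), path)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_anchors(path: str | Path) -> list[AnchorRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ANCHOR_COLUMNS, path)
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                AnchorRecord(
                    subject_id=str(row.subject_id),
                    fga=int(row.fga),
                    fes_i=int(row.fes_i),
                    pcs12=float(row.pcs12),
                    mcs12=float(row.mcs12),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {idx}: {exc}") from exc
    return records


def anchors_to_frame(records: Sequence[AnchorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "fga": [r.fga for r in records],
            "fes_i": [r.fes_i for r in records],
            "pcs12": [r.pcs12 for r in records],
            "mcs12": [r.mcs12 for r in records],
        }
    )


def write_anchors(records: Sequence[AnchorRecord], path: str | Path) -> None:
    anchors_to_frame(records).to_csv(path, index=False)
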