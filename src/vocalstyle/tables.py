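"""Observational data model and CSV I/O.

Every downstream stage consumes the record types defined here: directed
aggression bouts, feeding-proximity scans, focal observation sessions,
vocal events, group metadata and per-species vocal repertoire counts.

Files are plain CSV with a header row, UTF-8, ``.`` decimal separator and
flags encoded 0/1.  Times are numeric seconds from an arbitrary per-study
epoch; only differences are ever used.  Validation is total: a file either
loads fully or raises :class:`ValidationError` naming the first offending
row (1-based, counting data rows).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd


class ValidationError(ValueError):
    """A record violated its schema or an invariant."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggressionBout:
    """One directed agonistic interaction.

    ``decided`` marks bouts with a clear winner (victim fled or submitted);
    ``winner_id`` is present iff decided and must be one of the two
    participants.  ``contact`` flags physical contact by the aggressor,
    ``counter`` flags retaliation by the victim within the bout.
    """

    group_id: str
    bout_id: str
    time: float
    aggressor_id: str
    victim_id: str
    contact: bool
    counter: bool
    decided: bool
    winner_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.aggressor_id == self.victim_id:
            raise ValidationError(
                f"bout {self.bout_id}: aggressor_id == victim_id ({self.aggressor_id})")
        if self.time < 0:
            raise ValidationError(f"bout {self.bout_id}: negative time {self.time}")
        if self.decided:
            if self.winner_id not in (self.aggressor_id, self.victim_id):
                raise ValidationError(
                    f"bout {self.bout_id}: decided bout needs winner_id in "
                    f"{{{self.aggressor_id}, {self.victim_id}}}, got {self.winner_id!r}")
        elif self.winner_id not in (None, ""):
            raise ValidationError(
                f"bout {self.bout_id}: winner_id set on undecided bout")


@dataclass(frozen=True)
class ProximityScan:
    """Instantaneous point sample of a focal individual.

    ``feeding`` — focal was in a feeding context; ``neighbor_within_1m`` —
    nearest neighbour was an independent individual within 1 m.
    """

    group_id: str
    focal_id: str
    time: float
    feeding: bool
    neighbor_within_1m: bool


@dataclass(frozen=True)
class FocalSession:
    """A continuous focal observation period (duration in hours)."""

    group_id: str
    focal_id: str
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError(
                f"session for {self.focal_id}: duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration * 3600.0


@dataclass(frozen=True)
class VocalEvent:
    """Onset of one vocalization during a focal session."""

    group_id: str
    focal_id: str
    time: float


@dataclass(frozen=True)
class GroupMeta:
    group_id: str
    species_id: str
    group_size: int

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValidationError(
                f"group {self.group_id}: group_size must be >= 2, got {self.group_size}")


@dataclass(frozen=True)
class RepertoireRecord:
    """Curated per-species vocal repertoire counts.

    ``hierarchy_calls`` (calls described as occurring in an appeasement or
    dominance context) is a subset of ``total_calls``.
    """

    species_id: str
    total_calls: int
    hierarchy_calls: int

    def __post_init__(self) -> None:
        if not (0 <= self.hierarchy_calls <= self.total_calls):
            raise ValidationError(
                f"repertoire {self.species_id}: need 0 <= hierarchy_calls "
                f"({self.hierarchy_calls}) <= total_calls ({self.total_calls})")


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_BOOL = {"0": False, "1": True, 0: False, 1: True, False: False, True: True,
         "0.0": False, "1.0": True}

BOUT_COLUMNS = ["group_id", "bout_id", "time", "aggressor_id", "victim_id",
                "contact", "counter", "decided", "winner_id"]
SCAN_COLUMNS = ["group_id", "focal_id", "time", "feeding", "neighbor_within_1m"]
SESSION_COLUMNS = ["group_id", "focal_id", "start", "duration"]
EVENT_COLUMNS = ["group_id", "focal_id", "time"]
GROUP_COLUMNS = ["group_id", "species_id", "group_size"]
REPERTOIRE_COLUMNS = ["species_id", "total_calls", "hierarchy_calls"]


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _flag(value: str, row: int, field: str) -> bool:
    try:
        return _BOOL[value]
    except KeyError:
        raise ValidationError(f"row {row}: field {field!r} must be 0/1, got {value!r}")


def _num(value: str, row: int, field: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"row {row}: field {field!r} is not numeric: {value!r}")


def _intval(value: str, row: int, field: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"row {row}: field {field!r} is not an integer: {value!r}")


def _wrap_row(row_number: int, exc: ValidationError) -> ValidationError:
    return ValidationError(f"row {row_number}: {exc}")


def read_bouts(path: str | Path) -> list[AggressionBout]:
    """Read and validate an aggression-bout table. Row order is preserved."""
    df = _read_csv(path, BOUT_COLUMNS)
    out: list[AggressionBout] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        winner = rec["winner_id"] or None
        try:
            out.append(AggressionBout(
                group_id=rec["group_id"], bout_id=rec["bout_id"],
                time=_num(rec["time"], i, "time"),
                aggressor_id=rec["aggressor_id"], victim_id=rec["victim_id"],
                contact=_flag(rec["contact"], i, "contact"),
                counter=_flag(rec["counter"], i, "counter"),
                decided=_flag(rec["decided"], i, "decided"),
                winner_id=winner))
        except ValidationError as exc:
            raise _wrap_row(i, exc) from None
    return out


def read_scans(path: str | Path) -> list[ProximityScan]:
    df = _read_csv(path, SCAN_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            out.append(ProximityScan(
                group_id=rec["group_id"], focal_id=rec["focal_id"],
                time=_num(rec["time"], i, "time"),
                feeding=_flag(rec["feeding"], i, "feeding"),
                neighbor_within_1m=_flag(rec["neighbor_within_1m"], i,
                                         "neighbor_within_1m")))
        except ValidationError as exc:
            raise _wrap_row(i, exc) from None
    return out


def read_sessions(path: str | Path) -> list[FocalSession]:
    """Read focal sessions; sessions of one focal may not overlap."""
    df = _read_csv(path, SESSION_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            out.append(FocalSession(
                group_id=rec["group_id"], focal_id=rec["focal_id"],
                start=_num(rec["start"], i, "start"),
                duration=_num(rec["duration"], i, "duration")))
        except ValidationError as exc:
            raise _wrap_row(i, exc) from None
    _check_no_overlap(out)
    return out


def _check_no_overlap(sessions: Sequence[FocalSession]) -> None:
    by_focal: dict[str, list[FocalSession]] = {}
    for s in sessions:
        by_focal.setdefault(s.focal_id, []).append(s)
    for focal, ss in by_focal.items():
        ss = sorted(ss, key=lambda s: s.start)
        for a, b in zip(ss, ss[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"focal {focal}: sessions overlap at t={b.start}")


def read_vocal_events(path: str | Path,
                      sessions: Optional[Sequence[FocalSession]] = None,
                      ) -> list[VocalEvent]:
    """Read vocal events; if ``sessions`` is given, every event must fall
    inside one of its focal's sessions."""
    df = _read_csv(path, EVENT_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        out.append(VocalEvent(group_id=rec["group_id"], focal_id=rec["focal_id"],
                              time=_num(rec["time"], i, "time")))
    if sessions is not None:
        check_events_in_sessions(out, sessions)
    return out


def check_events_in_sessions(events: Sequence[VocalEvent],
                             sessions: Sequence[FocalSession]) -> None:
    by_focal: dict[str, list[FocalSession]] = {}
    for s in sessions:
        by_focal.setdefault(s.focal_id, []).append(s)
    for ev in events:
        ss = by_focal.get(ev.focal_id, [])
        if not any(s.start <= ev.time <= s.end for s in ss):
            raise ValidationError(
                f"vocal event for focal {ev.focal_id} at t={ev.time} "
                f"falls outside every focal session")


def read_group_meta(path: str | Path) -> list[GroupMeta]:
    df = _read_csv(path, GROUP_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            out.append(GroupMeta(group_id=rec["group_id"],
                                 species_id=rec["species_id"],
                                 group_size=_intval(rec["group_size"], i, "group_size")))
        except ValidationError as exc:
            raise _wrap_row(i, exc) from None
    return out


def read_repertoires(path: str | Path) -> list[RepertoireRecord]:
    df = _read_csv(path, REPERTOIRE_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            out.append(RepertoireRecord(
                species_id=rec["species_id"],
                total_calls=_intval(rec["total_calls"], i, "total_calls"),
                hierarchy_calls=_intval(rec["hierarchy_calls"], i, "hierarchy_calls")))
        except ValidationError as exc:
            raise _wrap_row(i, exc) from None
    return out


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def _records_frame(records: Sequence, columns: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {}
        for f in dc_fields(r):
            v = getattr(r, f.name)
            if isinstance(v, bool):
                v = int(v)
            elif v is None:
                v = ""
            row[f.name] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=list(columns))


def write_bouts(records: Sequence[AggressionBout], path: str | Path) -> None:
    _records_frame(records, BOUT_COLUMNS).to_csv(path, index=False)


def write_scans(records: Sequence[ProximityScan], path: str | Path) -> None:
    _records_frame(records, SCAN_COLUMNS).to_csv(path, index=False)


def write_sessions(records: Sequence[FocalSession], path: str | Path) -> None:
    _records_frame(records, SESSION_COLUMNS).to_csv(path, index=False)


def write_vocal_events(records: Sequence[VocalEvent], path: str | Path) -> None:
    _records_frame(records, EVENT_COLUMNS).to_csv(path, index=False)


def write_group_meta(records: Sequence[GroupMeta], path: str | Path) -> None:
    _records_frame(records, GROUP_COLUMNS).to_csv(path, index=False)


def write_repertoires(records: Sequence[RepertoireRecord], path: str | Path) -> None:
    _records_frame(records, REPERTOIRE_COLUMNS).to_csv(path, index=False)
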