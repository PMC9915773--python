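"""CSV interchange for event logs, visit tables, and analysis outputs.

The event-log dialect is one row per behavioral event (UTF-8, header row,
"." decimal, LF line endings): subject_id, sex, session_index, cod_s,
event_type in {patch_entry, reward, leave, cod_start, cod_end, session_end},
time_s (3 decimals, matching the apparatus's millisecond resolution),
patch_id, volume_ul (only on reward rows, written at full precision).
Writing then reading a simulated cohort reproduces the session records
field-for-field.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import TaskConfig
from .task_model import (
    TIME_CAP,
    VOLUME_CAP,
    PatchVisit,
    SessionRecord,
    scheduled_volume,
)

EVENT_COLUMNS = (
    "subject_id",
    "sex",
    "session_index",
    "cod_s",
    "event_type",
    "time_s",
    "patch_id",
    "volume_ul",
)

EVENT_TYPES = frozenset(
    {"patch_entry", "reward", "leave", "cod_start", "cod_end", "session_end"}
)


class ParseError(ValueError):
    """Malformed event log; the message names the offending line."""


def _fmt_num(x: float) -> str:
    return f"{x:g}" if x == int(x) else repr(x)


def iter_events(record: SessionRecord) -> Iterable[tuple[str, float, str, float | None]]:
    """Flatten a session into (event_type, time_s, patch_id, volume) tuples.

    Changeover rows are emitted only for CODs > 0 (a 0-s changeover is
    instantaneous). If the session ends during a COD, cod_start appears
    without a matching cod_end.
    """
    for i, visit in enumerate(record.visits):
        yield "patch_entry", visit.entry_time, visit.patch_id, None
        for t, vol in zip(visit.reward_times, visit.reward_volumes):
            yield "reward", t, visit.patch_id, vol
        if visit.exit_time is not None:
            yield "leave", visit.exit_time, visit.patch_id, None
            if record.cod_s > 0:
                yield "cod_start", visit.exit_time, "", None
                cod_end = visit.exit_time + record.cod_s
                if cod_end <= record.total_time:
                    yield "cod_end", cod_end, "", None
    yield "session_end", record.total_time, "", None


def write_event_log(records: Sequence[SessionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(EVENT_COLUMNS)
        for rec in records:
            for etype, t, patch, vol in iter_events(rec):
                w.writerow(
                    [
                        rec.subject_id,
                        rec.sex,
                        rec.session_index,
                        _fmt_num(rec.cod_s),
                        etype,
                        f"{t:.3f}",
                        patch,
                        "" if vol is None else repr(vol),
                    ]
                )


def read_event_log(
    path: str | Path, config: TaskConfig | None = None
) -> list[SessionRecord]:
    """Reconstruct session records from an event-log CSV.

    The termination reason is not a CSV column; it is inferred by comparing
    the session's total volume with the configured volume cap (default task
    constants if no config is given). Raises :class:`ParseError`, naming the
    line number, on a malformed header, an unknown event type, or
    non-monotone timestamps within a session.
    """
    if config is None:
        config = TaskConfig()
    path = Path(path)
    records: list[SessionRecord] = []
    current_key: tuple[str, int] | None = None
    rec: SessionRecord | None = None
    last_t = -1.0

    def finalize() -> None:
        nonlocal rec
        if rec is not None and rec.termination == "":
            raise ParseError(
                f"{path}: session {current_key} ended without a session_end event"
            )
        rec = None

    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, missing header") from None
        if tuple(header) != EVENT_COLUMNS:
            raise ParseError(f"{path}: line 1: malformed header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(EVENT_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"{len(EVENT_COLUMNS)} fields, got {len(row)}")
            sid, sex, s_idx, cod_s, etype, time_s, patch, vol = row
            if etype not in EVENT_TYPES:
                raise ParseError(f"{path}: line {lineno}: unknown event_type {etype!r}")
            try:
                session_index = int(s_idx)
                cod = float(cod_s)
                t = float(time_s)
            except ValueError as e:
                raise ParseError(f"{path}: line {lineno}: {e}") from None
            key = (sid, session_index)
            if key != current_key:
                finalize()
                current_key = key
                last_t = -1.0
                rec = SessionRecord(
                    subject_id=sid,
                    sex=sex,
                    session_index=session_index,
                    cod_s=cod,
                    visits=[],
                    termination="",
                    total_volume=0.0,
                    total_time=0.0,
                )
                records.append(rec)
            if t < last_t:
                raise ParseError(
                    f"{path}: line {lineno}: timestamp {t} precedes {last_t} "
                    f"within session {key}"
                )
            last_t = t
            if etype == "patch_entry":
                rec.visits.append(
                    PatchVisit(
                        patch_id=patch,
                        entry_time=t,
                        preceded_by_cod=len(rec.visits) > 0,
                    )
                )
            elif etype == "reward":
                if not rec.visits:
                    raise ParseError(f"{path}: line {lineno}: reward before any patch_entry")
                rec.visits[-1].reward_volumes.append(float(vol))
                rec.visits[-1].reward_times.append(t)
                rec.total_volume += float(vol)
            elif etype == "leave":
                if not rec.visits:
                    raise ParseError(f"{path}: line {lineno}: leave before any patch_entry")
                rec.visits[-1].exit_time = t
            elif etype == "session_end":
                rec.total_time = t
                rec.termination = (
                    VOLUME_CAP
                    if rec.total_volume >= config.session_volume_cap * (1 - 1e-12)
                    else TIME_CAP
                )
        finalize()
    return records


def visit_table(records: Sequence[SessionRecord], config: TaskConfig) -> pd.DataFrame:
    """One row per patch visit, with the forgone next scheduled volume."""
    rows = []
    for rec in records:
        for i, v in enumerate(rec.visits):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "session_index": rec.session_index,
                    "cod_s": rec.cod_s,
                    "visit_index": i,
                    "patch_id": v.patch_id,
                    "entry_time_s": v.entry_time,
                    "exit_time_s": v.exit_time,
                    "n_rewards": v.n_rewards,
                    "last_volume_ul": v.reward_volumes[-1] if v.reward_volumes else None,
                    "next_scheduled_ul": scheduled_volume(v.n_rewards + 1, config),
                }
            )
    return pd.DataFrame(rows)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis table: UTF-8, LF endings, empty cells for missing."""
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
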