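"""Session-file reading and writing.

One comma-delimited, UTF-8, header-bearing file holds any number of
sessions, one row per trial, identified by (subject_id, group, med_state).
``outcome`` is empty on timeouts and ``rating`` is empty on unprompted or
unanswered trials.  An optional column dictionary maps foreign column
names onto this dialect when importing external exports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from sborg.records import SessionRecord, TRIAL_COLUMNS, GROUPS, MED_STATES

SESSION_COLUMNS = ["subject_id", "group", "med_state"] + TRIAL_COLUMNS


class SessionValidationError(ValueError):
    """Raised when a session file violates the trial-row invariants."""


def sessions_to_frame(sessions: list[SessionRecord]) -> pd.DataFrame:
    frames = []
    for s in sessions:
        t = s.trials.copy()
        t.insert(0, "subject_id", s.subject_id)
        t.insert(1, "group", s.group)
        t.insert(2, "med_state", s.med_state)
        frames.append(t[SESSION_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=SESSION_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_sessions(sessions: list[SessionRecord], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions(path, column_map: dict[str, str] | None = None,
                  rating_scale: str = "z") -> list[SessionRecord]:
    """Read and validate a session file.

    ``column_map`` renames foreign columns onto the native dialect
    (e.g. ``{"subj": "subject_id"}``).  Every invariant violation is
    reported with its 1-based data row number; a file with only a header
    yields an empty list.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise SessionValidationError(f"{path}: malformed file: {err}") from err
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = set(SESSION_COLUMNS) - set(frame.columns)
    if missing:
        raise SessionValidationError(
            f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        return []
    problems: list[str] = []
    for pos, row in enumerate(frame.itertuples(index=False), start=1):
        where = f"{path.name} row {pos}"
        if row.group not in GROUPS:
            problems.append(f"{where}: unknown group {row.group!r}")
        if row.med_state not in MED_STATES:
            problems.append(f"{where}: unknown med_state {row.med_state!r}")
        if row.choice not in ("certain", "gamble", "timeout"):
            problems.append(f"{where}: unknown choice {row.choice!r}")
            continue
        has_outcome = not pd.isna(row.outcome)
        if row.choice == "timeout" and has_outcome:
            problems.append(f"{where}: outcome present on a timeout")
        if row.choice != "timeout" and not has_outcome:
            problems.append(f"{where}: outcome missing on a responded trial")
        if row.choice == "certain" and has_outcome \
                and row.outcome != row.certain_value:
            problems.append(
                f"{where}: certain-choice outcome != certain_value")
        if row.choice == "gamble" and has_outcome \
                and row.outcome not in (row.gamble_low, row.gamble_high):
            problems.append(f"{where}: gamble outcome not a gamble value")
        if not pd.isna(row.rating) and not row.rating_prompt:
            problems.append(f"{where}: rating present without a prompt")
    if problems:
        shown = "\n".join(problems[:20])
        extra = len(problems) - min(len(problems), 20)
        if extra:
            shown += f"\n... and {extra} more"
        raise SessionValidationError(f"invalid session file:\n{shown}")
    sessions = []
    for (sid, grp, med), sub in frame.groupby(
            ["subject_id", "group", "med_state"], sort=False):
        trials = sub[TRIAL_COLUMNS].reset_index(drop=True)
        trials["rating_prompt"] = trials["rating_prompt"].astype(bool)
        sessions.append(SessionRecord(str(sid), grp, med, trials,
                                      rating_scale=rating_scale))
    return sessions
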