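"""Session records: one subject-visit's ordered trials with behavior."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("ICD", "non-ICD")
MED_STATES = ("on", "off")
CHOICES = ("certain", "gamble", "timeout")

#: column order of the session-file dialect (one row per trial)
TRIAL_COLUMNS = [
    "trial_index", "certain_value", "gamble_low", "gamble_high",
    "rating_prompt", "time_limit", "choice", "outcome", "rating",
]


@dataclass
class SessionRecord:
    """One subject-visit: ordered trials plus identifying labels.

    ``trials`` has one row per trial with columns ``TRIAL_COLUMNS``.
    ``outcome`` is NaN on timeouts; ``rating`` is NaN unless the trial was
    prompted and responded to.  ``rating_scale`` records whether ratings
    are already standardized ("z") or raw slider integers ("slider").
    """

    subject_id: str
    group: str
    med_state: str
    trials: pd.DataFrame = field(repr=False)
    rating_scale: str = "z"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.med_state not in MED_STATES:
            raise ValueError(f"med_state must be one of {MED_STATES}")
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials table missing columns: {sorted(missing)}")
        self.trials = self.trials.reset_index(drop=True)

    @property
    def cell(self) -> str:
        """Condition-cell label, e.g. ``"ICD-off"``."""
        return f"{self.group}-{self.med_state}"

    @property
    def responded(self) -> pd.DataFrame:
        """Non-timeout trials, original order preserved."""
        return self.trials[self.trials["choice"] != "timeout"]

    @property
    def n_rated(self) -> int:
        return int(self.trials["rating"].notna().sum())

    def ratings(self) -> pd.Series:
        """Emitted ratings indexed by trial row position."""
        return self.trials["rating"].dropna()

    def validate(self) -> list[str]:
        """Return a list of per-row invariant violations (empty if clean)."""
        problems: list[str] = []
        t = self.trials
        for i, row in enumerate(t.itertuples(index=False)):
            where = f"{self.subject_id}/{self.cell} trial row {i}"
            if row.choice not in CHOICES:
                problems.append(f"{where}: unknown choice {row.choice!r}")
                continue
            has_outcome = not pd.isna(row.outcome)
            if row.choice == "timeout":
                if has_outcome:
                    problems.append(f"{where}: outcome present on a timeout")
                if not pd.isna(row.rating):
                    problems.append(f"{where}: rating present on a timeout")
            else:
                if not has_outcome:
                    problems.append(f"{where}: outcome missing on a responded trial")
                elif row.choice == "certain" and row.outcome != row.certain_value:
                    problems.append(
                        f"{where}: certain-choice outcome {row.outcome} != "
                        f"certain_value {row.certain_value}")
                elif row.choice == "gamble" and row.outcome not in (
                        row.gamble_low, row.gamble_high):
                    problems.append(
                        f"{where}: gamble outcome {row.outcome} not one of "
                        f"{{{row.gamble_low}, {row.gamble_high}}}")
            if not pd.isna(row.rating) and not row.rating_prompt:
                problems.append(f"{where}: rating present without a prompt")
        return problems


def group_by_cell(sessions: list[SessionRecord]) -> dict[str, list[SessionRecord]]:
    """Partition sessions into the four condition cells."""
    cells: dict[str, list[SessionRecord]] = {}
    for s in sessions:
        cells.setdefault(s.cell, []).append(s)
    return cells
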