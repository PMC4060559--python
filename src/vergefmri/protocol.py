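"""Vergence-training schedule arithmetic.

The training protocol combines home sessions (two 10-minute sessions per day,
three days per week) with laboratory sessions (one hour, twice per week) over
six weeks, for 6 h at home plus 12 h in the laboratory: 18 h total.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TrainingSchedule:
    """Weekly structure of the vergence-training protocol."""

    home_session_min: float = 10.0
    home_sessions_per_day: int = 2
    home_days_per_week: int = 3
    lab_session_hours: float = 1.0
    lab_sessions_per_week: int = 2
    weeks: int = 6

    def __post_init__(self) -> None:
        if self.weeks <= 0:
            raise ValueError("weeks must be positive")
        if min(self.home_session_min, self.lab_session_hours) < 0:
            raise ValueError("session durations must be >= 0")

    @property
    def home_hours(self) -> float:
        return (
            self.home_session_min / 60.0
            * self.home_sessions_per_day
            * self.home_days_per_week
            * self.weeks
        )

    @property
    def lab_hours(self) -> float:
        return self.lab_session_hours * self.lab_sessions_per_week * self.weeks

    @property
    def total_hours(self) -> float:
        return self.home_hours + self.lab_hours
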