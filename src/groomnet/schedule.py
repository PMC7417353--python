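"""Observation calendar for weekly behavioural sampling.

The study protocol observes the herd 5 consecutive days per week, in two
daily blocks (morning 09:00-12:00, afternoon 18:00-21:00), each block being
four 30-min continuous observation periods separated by 20-min breaks
(4 h of observation per day).  Weeks are calendar-defined from a configured
study start; every behavioural event must fall inside one of the declared
observation periods of its week.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterator

#: (block start hour, number of periods); each period is 30 min, gaps 20 min.
BLOCK_STARTS = (time(9, 0), time(18, 0))
PERIODS_PER_BLOCK = 4
PERIOD_MINUTES = 30
GAP_MINUTES = 20


@dataclass(frozen=True)
class ObservationSchedule:
    """Calendar of observation periods.

    Parameters
    ----------
    study_start : date
        First observation day (start of week 1).
    n_weeks : int
        Number of observation weeks.
    days_per_week : int
        Consecutive observation days per week (default 5).
    """

    study_start: date = field(default_factory=lambda: date(2019, 2, 4))
    n_weeks: int = 6
    days_per_week: int = 5

    def week_of(self, ts: datetime) -> int:
        """1-based week index of a timestamp (by calendar day)."""
        return (ts.date() - self.study_start).days // 7 + 1

    def observation_days(self, week: int) -> list[date]:
        first = self.study_start + timedelta(weeks=week - 1)
        return [first + timedelta(days=d) for d in range(self.days_per_week)]

    def periods(self, week: int) -> Iterator[tuple[datetime, datetime]]:
        """Yield (start, end) of every observation period in a week."""
        for day in self.observation_days(week):
            for block in BLOCK_STARTS:
                block_start = datetime.combine(day, block)
                for p in range(PERIODS_PER_BLOCK):
                    start = block_start + timedelta(
                        minutes=p * (PERIOD_MINUTES + GAP_MINUTES)
                    )
                    yield start, start + timedelta(minutes=PERIOD_MINUTES)

    def contains(self, ts: datetime) -> bool:
        """True if ``ts`` lies inside a declared observation period."""
        week = self.week_of(ts)
        if not 1 <= week <= self.n_weeks:
            return False
        return any(start <= ts <= end for start, end in self.periods(week))

    def total_period_starts(self, week: int) -> list[datetime]:
        return [start for start, _ in self.periods(week)]
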