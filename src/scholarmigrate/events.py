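"""Detect migration events as year-over-year changes in inferred residence.

With residence resolved at annual granularity, a change of residence between
consecutive years is, by construction, a change lasting at least one year --
the standard long-term migrant criterion. The event year is the first year
of residence in the destination; the mover is counted in the origin's
outflow for that year. Moves in consecutive years are all retained: the
annual residence resolution already encodes the one-year criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .residence import ResidenceTimeline

__all__ = ["MigrationEvent", "detect_events", "detect_events_all", "EVENT_COLUMNS"]

EVENT_COLUMNS = ["scholar_id", "origin", "destination", "year"]


@dataclass(frozen=True)
class MigrationEvent:
    scholar_id: str
    origin: str
    destination: str
    year: int  # first year of residence in the destination

    def __post_init__(self):
        if self.origin == self.destination:
            raise ValueError("origin and destination must differ")


def detect_events(timeline: ResidenceTimeline) -> list[MigrationEvent]:
    """One event per consecutive-year pair with differing residence, by year."""
    events = []
    for i in range(1, len(timeline.countries)):
        o, d = timeline.countries[i - 1], timeline.countries[i]
        if o != d:
            events.append(
                MigrationEvent(timeline.scholar_id, o, d, timeline.first_year + i)
            )
    return events


def detect_events_all(timelines: Iterable[ResidenceTimeline]) -> pd.DataFrame:
    """Event table over all scholars, ordered by (scholar_id, year)."""
    rows = [
        (e.scholar_id, e.origin, e.destination, e.year)
        for tl in timelines
        for e in detect_events(tl)
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(df) == 0:
        return df.astype({"scholar_id": str, "origin": str, "destination": str, "year": int})
    return df.sort_values(["scholar_id", "year"], kind="mergesort", ignore_index=True)
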