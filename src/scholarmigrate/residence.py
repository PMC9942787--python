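"""Infer each scholar's country of residence per year from publications.

A scholar's residence in a year is the country of primary affiliation with
the largest number of publications in that year (the modal rule). Years
without publications inside the active window (first to last publication
year) are filled by carrying the most recent observed residence forward and
flagged as imputed: absence of publications is not treated as evidence of
relocation, and no migration event can be dated to an imputed year.

Ties are broken in favour of residence continuity: if the previous year's
residence is among the tied countries it is kept, otherwise the
lexicographically smallest country code wins. Both choices are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ResidenceTimeline", "assign_residence", "assign_residence_all"]


@dataclass(frozen=True)
class ResidenceTimeline:
    """Per-scholar residence by year over the active window.

    ``countries[i]`` is the residence in year ``first_year + i``;
    ``observed[i]`` is True when that year has publications and False when
    the residence was carried forward through a publication gap.
    """

    scholar_id: str
    first_year: int
    last_year: int
    countries: tuple[str, ...]
    observed: tuple[bool, ...]

    def __post_init__(self):
        n = self.last_year - self.first_year + 1
        if len(self.countries) != n or len(self.observed) != n:
            raise ValueError(
                f"timeline for {self.scholar_id!r} must cover exactly "
                f"[{self.first_year}, {self.last_year}]"
            )
        if any(c is None for c in self.countries):
            raise ValueError(f"timeline for {self.scholar_id!r} has unfilled gaps")

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    def residence(self, year: int) -> str:
        if not self.first_year <= year <= self.last_year:
            raise KeyError(f"year {year} outside active window of {self.scholar_id!r}")
        return self.countries[year - self.first_year]


def _modal_sequence(years: np.ndarray, countries: np.ndarray) -> tuple[int, int, list, list]:
    """Core modal-rule pass over one scholar's (year, country) record pairs."""
    counts: dict[int, dict[str, int]] = {}
    for y, c in zip(years.tolist(), countries.tolist()):
        counts.setdefault(y, {}).setdefault(c, 0)
        counts[y][c] += 1
    first, last = min(counts), max(counts)
    out: list[str] = []
    observed: list[bool] = []
    prev: str | None = None
    for y in range(first, last + 1):
        if y in counts:
            by_country = counts[y]
            top = max(by_country.values())
            tied = [c for c, n in by_country.items() if n == top]
            if len(tied) == 1:
                prev = tied[0]
            elif prev in tied:
                pass  # keep previous residence
            else:
                prev = min(tied)
            observed.append(True)
        else:
            observed.append(False)  # gap year: carry prev forward
        out.append(prev)
    return first, last, out, observed


def assign_residence(records: pd.DataFrame) -> ResidenceTimeline:
    """Build the residence timeline for a single scholar.

    ``records`` must contain at least one row and columns ``scholar_id``,
    ``year`` and ``country``, all for the same scholar.
    """
    if len(records) == 0:
        raise ValueError("cannot assign residence from an empty record set")
    ids = records["scholar_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"records span multiple scholars: {sorted(ids)[:5]}")
    first, last, seq, obs = _modal_sequence(
        records["year"].to_numpy(), records["country"].to_numpy()
    )
    return ResidenceTimeline(str(ids[0]), first, last, tuple(seq), tuple(obs))


def assign_residence_all(records: pd.DataFrame) -> list[ResidenceTimeline]:
    """One timeline per distinct scholar, sorted by scholar_id.

    The result is invariant under permutation of the input rows. Per-scholar
    failures are aggregated and reported together with the scholar ids.
    """
    if len(records) == 0:
        return []
    timelines: list[ResidenceTimeline] = []
    failures: list[str] = []
    sid = records["scholar_id"].to_numpy()
    order = np.argsort(sid, kind="mergesort")
    sid, yr, co = sid[order], records["year"].to_numpy()[order], records["country"].to_numpy()[order]
    bounds = np.concatenate([[0], np.nonzero(sid[1:] != sid[:-1])[0] + 1, [sid.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        try:
            first, last, seq, obs = _modal_sequence(yr[a:b], co[a:b])
            timelines.append(
                ResidenceTimeline(str(sid[a]), first, last, tuple(seq), tuple(obs))
            )
        except Exception as exc:
            failures.append(f"{sid[a]}: {exc}")
    if failures:
        raise ValueError("residence assignment failed for: " + "; ".join(failures[:20]))
    return timelines
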