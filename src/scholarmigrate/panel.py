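"""Country-year panel of exposures, migration flows, and emigration rates.

Exposure follows residence: a scholar resident in country c in year t
contributes one person-year to c's active-scholar count for t, including
imputed gap years. A scholar who relocates in year t is therefore in the
origin's exposure for t-1 and the destination's for t, while being counted
as the origin's emigrant for t. Emigration rates consequently use the
previous year's scholars as denominator -- the population actually at risk
of leaving -- which bounds every rate in [0, 1000] per 1,000 scholars and
leaves the first panel year per country without a rate.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .residence import ResidenceTimeline

__all__ = [
    "PanelError",
    "build_panel",
    "filter_countries",
    "mean_rate",
    "to_model_frame",
    "PANEL_COLUMNS",
]

logger = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "country",
    "year",
    "scholars",
    "emigrants",
    "immigrants",
    "rate_per_1000",
    "gdp_ppp_2017",
    "log_gdp",
    "population",
]


class PanelError(ValueError):
    pass


def build_panel(
    timelines: Iterable[ResidenceTimeline],
    events: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate timelines and events into the country-year panel.

    The panel covers the full grid of observed countries x years spanned by
    the timelines; covariates must cover every such (country, year) pair.
    """
    timelines = list(timelines)
    if not timelines:
        raise PanelError("no timelines to aggregate")
    years_arr = np.concatenate([np.arange(t.first_year, t.last_year + 1) for t in timelines])
    countries_arr = np.concatenate([np.asarray(t.countries, dtype=object) for t in timelines])
    exposure = (
        pd.DataFrame({"country": countries_arr, "year": years_arr})
        .groupby(["country", "year"])
        .size()
        .rename("scholars")
    )

    all_countries = sorted(
        set(exposure.index.get_level_values(0))
        | set(events["origin"])
        | set(events["destination"])
    )
    y0 = int(years_arr.min())
    y1 = int(years_arr.max())
    grid = pd.MultiIndex.from_product(
        [all_countries, range(y0, y1 + 1)], names=["country", "year"]
    )
    panel = exposure.reindex(grid, fill_value=0).reset_index()

    emi = events.groupby(["origin", "year"]).size()
    imm = events.groupby(["destination", "year"]).size()
    key = pd.MultiIndex.from_frame(panel[["country", "year"]])
    panel["emigrants"] = emi.reindex(key, fill_value=0).to_numpy()
    panel["immigrants"] = imm.reindex(key, fill_value=0).to_numpy()

    cov = covariates.set_index(["country", "year"])
    missing = key.difference(cov.index)
    if len(missing):
        pairs = ", ".join(f"({c}, {y})" for c, y in list(missing)[:20])
        raise PanelError(f"covariates missing for {len(missing)} (country, year) pairs: {pairs}")
    panel["gdp_ppp_2017"] = cov["gdp_ppp_2017"].reindex(key).to_numpy()
    panel["population"] = cov["population"].reindex(key).to_numpy()
    panel["log_gdp"] = np.log(panel["gdp_ppp_2017"].to_numpy())

    panel = panel.sort_values(["country", "year"], ignore_index=True)
    at_risk = panel.groupby("country")["scholars"].shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 1000.0 * panel["emigrants"] / at_risk
    panel["rate_per_1000"] = rate.where(at_risk > 0)
    return panel[PANEL_COLUMNS]


def filter_countries(
    panel: pd.DataFrame, top_n: int = 100, min_population: float = 500_000.0
) -> pd.DataFrame:
    """Keep large-population countries with the biggest scholar stocks.

    Countries whose mean population over the panel years is below
    ``min_population`` are dropped first; of the remainder the ``top_n`` by
    total active-scholar person-years (summed over all years) are kept, with
    all their years retained. Ties in total person-years break on country
    code for determinism.
    """
    by_country = panel.groupby("country").agg(
        total_scholars=("scholars", "sum"), mean_pop=("population", "mean")
    )
    eligible = by_country[by_country["mean_pop"] >= min_population]
    if top_n > len(eligible):
        logger.warning(
            "top_n=%d exceeds the %d eligible countries; keeping all", top_n, len(eligible)
        )
    keep = (
        eligible.sort_values(
            ["total_scholars", "country"], ascending=[False, True], kind="mergesort"
        )
        .head(top_n)
        .index
    )
    return panel[panel["country"].isin(keep)].reset_index(drop=True)


def mean_rate(panel: pd.DataFrame, year_from: int, year_to: int) -> pd.Series:
    """Per-country mean of yearly emigration rates over [year_from, year_to].

    Convenience for map-style summaries (e.g. a five-year average rate);
    years with undefined rates are skipped.
    """
    window = panel[(panel["year"] >= year_from) & (panel["year"] <= year_to)]
    return window.groupby("country")["rate_per_1000"].mean()


def to_model_frame(panel: pd.DataFrame) -> pd.DataFrame:
    """Model frame for the emigration-count GAMM.

    One row per (country, year) with a defined rate: the response is the
    emigrant count, the exposure is the previous year's scholars (population
    at risk, log of which becomes the model offset). Rows with zero or
    undefined exposure are dropped; the number dropped is logged.
    """
    panel = panel.sort_values(["country", "year"])
    at_risk = panel.groupby("country")["scholars"].shift(1)
    keep = (at_risk > 0).to_numpy()
    dropped = len(panel) - int(keep.sum())
    if dropped:
        logger.info("to_model_frame: dropped %d rows without at-risk exposure", dropped)
    out = panel.loc[keep, ["country", "year", "emigrants", "gdp_ppp_2017", "log_gdp"]].copy()
    out.insert(2, "exposure", at_risk[keep].astype(int).to_numpy())
    return out.reset_index(drop=True)
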