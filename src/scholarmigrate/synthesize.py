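"""Synthetic bibliometric corpora with known migration dynamics.

Real bibliometric microdata (publication records with disambiguated author
identities and affiliation countries) are proprietary, so every downstream
stage of the pipeline is exercised against corpora generated here, for which
the true relocation history of every scholar is known.

The generator emulates the statistical structure the analysis relies on:

* pre-disambiguated scholars with careers of random length inside the study
  window, publishing a Poisson number of papers per active year (zero counts
  produce gap years);
* country GDP-per-capita series following geometric Brownian drift, giving
  the within-country variation the random-slope term needs;
* an emigration hazard per scholar-year that is quadratic in the origin
  country's log GDP per capita, ``h(x) = exp(g0 + g1*x + g2*x**2)`` clamped
  to ``[0, h_max]`` -- the U-shaped ground truth the model should recover;
* destination choice proportional to current scholar stocks;
* multi-affiliation noise: some scholar-years carry publications attributed
  to a second country, creating the ties the modal residence rule must
  resolve.

All randomness derives from one root seed through named streams, so adding a
draw site to one stage does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from math import log
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "CorpusValidationError",
    "HazardSpec",
    "GdpModel",
    "SimConfig",
    "generate_corpus",
    "simulate_rate_panel",
    "write_corpus",
    "read_corpus",
    "validate_corpus",
]

PUBLICATIONS_COLUMNS = ["scholar_id", "pub_id", "year", "country"]
COVARIATES_COLUMNS = ["country", "year", "gdp_ppp_2017", "population"]
TRUTH_COLUMNS = ["scholar_id", "origin", "destination", "year"]


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


class CorpusValidationError(ValueError):
    """A corpus file or table violates its schema; message lists offending rows."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream derived from one root seed.

    The stream key is a CRC32 of the name, so streams are independent of the
    order in which draw sites appear in the code.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HazardSpec:
    """Per scholar-year emigration hazard, quadratic in origin log GDP.

    ``h(x) = clamp(exp(gamma0 + gamma1*x + gamma2*x**2), 0, h_max)`` with
    ``x`` the natural log of GDP per capita (2017 PPP dollars). The default
    has its interior minimum at ``x* = -gamma1 / (2*gamma2) = log(25000)``
    and a minimum hazard of about 1% per scholar-year.
    """

    gamma0: float = 21.0
    gamma1: float = -5.06332
    gamma2: float = 0.25
    h_max: float = 0.5

    def rate(self, log_gdp):
        x = np.asarray(log_gdp, dtype=float)
        h = np.exp(self.gamma0 + self.gamma1 * x + self.gamma2 * x * x)
        return np.clip(h, 0.0, self.h_max)

    @property
    def argmin_gdp(self) -> float:
        """GDP at the hazard's interior minimum (requires gamma2 > 0)."""
        return float(np.exp(-self.gamma1 / (2.0 * self.gamma2)))


@dataclass(frozen=True)
class GdpModel:
    """Per-country log GDP level and geometric-Brownian drift.

    Initial log GDP is uniform on ``[log(gdp_min), log(gdp_max)]``; each
    subsequent year adds ``Normal(drift, sigma)`` to the log level.
    """

    gdp_min: float = 1500.0
    gdp_max: float = 90000.0
    drift: float = 0.02
    sigma: float = 0.03


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one synthetic corpus.

    Career lengths are ``1 + Poisson(career_mean_years - 1)``, truncated at
    the end of the study window. Per-year publication counts are
    ``pubs_per_year_min + Poisson(pubs_per_year_mean - pubs_per_year_min)``;
    with the default minimum of 0, gap years arise naturally.
    ``multi_affil_prob`` is the probability that a scholar-year with at least
    two publications attributes a minority (possibly exactly half, creating a
    tie) of them to another country.
    """

    n_countries: int = 20
    n_scholars: int = 2000
    year_start: int = 1998
    year_end: int = 2017
    career_mean_years: float = 8.0
    pubs_per_year_mean: float = 2.0
    pubs_per_year_min: int = 0
    hazard: HazardSpec = field(default_factory=HazardSpec)
    gdp: GdpModel = field(default_factory=GdpModel)
    population_log_mean: float = 16.0
    population_log_sd: float = 1.5
    population_growth: float = 0.01
    multi_affil_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 2 or self.n_countries > 676:
            raise ConfigError(f"n_countries must be in [2, 676], got {self.n_countries}")
        if self.n_scholars < 1:
            raise ConfigError(f"n_scholars must be positive, got {self.n_scholars}")
        if self.year_end - self.year_start + 1 < 3:
            raise ConfigError(
                f"year range must span >= 3 years, got {self.year_start}..{self.year_end}"
            )
        if self.career_mean_years < 1:
            raise ConfigError(f"career_mean_years must be >= 1, got {self.career_mean_years}")
        if self.pubs_per_year_min < 0:
            raise ConfigError(f"pubs_per_year_min must be >= 0, got {self.pubs_per_year_min}")
        if self.pubs_per_year_mean < self.pubs_per_year_min:
            raise ConfigError(
                "pubs_per_year_mean must be >= pubs_per_year_min, got "
                f"{self.pubs_per_year_mean} < {self.pubs_per_year_min}"
            )
        if not 0.0 <= self.multi_affil_prob <= 1.0:
            raise ConfigError(f"multi_affil_prob must be in [0, 1], got {self.multi_affil_prob}")
        if not 0.0 <= self.hazard.h_max <= 1.0:
            raise ConfigError(f"hazard.h_max must be in [0, 1], got {self.hazard.h_max}")
        if self.gdp.gdp_min <= 0 or self.gdp.gdp_max <= self.gdp.gdp_min:
            raise ConfigError("gdp.gdp_min/gdp_max must satisfy 0 < gdp_min < gdp_max")
        if self.gdp.sigma < 0:
            raise ConfigError(f"gdp.sigma must be >= 0, got {self.gdp.sigma}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def country_codes(n: int) -> list[str]:
    """Deterministic two-letter codes AA, AB, ... for n synthetic countries."""
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return [alphabet[i // 26] + alphabet[i % 26] for i in range(n)]


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def generate_corpus(config: SimConfig):
    """Simulate a publication corpus with a known relocation history.

    Returns ``(publications, covariates, truth_events)`` as DataFrames with
    the schemas of ``publications.csv``, ``covariates.csv`` and
    ``truth_events.csv``. The truth log records every simulated relocation
    with its true year (the first year of residence in the destination);
    identical config and seed give byte-identical outputs.
    """
    config.validate()
    seed = config.seed
    nc, ns = config.n_countries, config.n_scholars
    years = np.arange(config.year_start, config.year_end + 1)
    ny = years.size
    codes = np.array(country_codes(nc))

    # country covariates
    rng_c = stream(seed, "countries")
    log_gdp = np.empty((nc, ny))
    log_gdp[:, 0] = rng_c.uniform(log(config.gdp.gdp_min), log(config.gdp.gdp_max), nc)
    if ny > 1:
        steps = rng_c.normal(config.gdp.drift, config.gdp.sigma, (nc, ny - 1))
        log_gdp[:, 1:] = log_gdp[:, [0]] + np.cumsum(steps, axis=1)
    pop0 = np.exp(rng_c.normal(config.population_log_mean, config.population_log_sd, nc))
    population = pop0[:, None] * (1.0 + config.population_growth) ** np.arange(ny)[None, :]

    # careers: home country sampled proportional to population size
    rng_k = stream(seed, "careers")
    home = rng_k.choice(nc, size=ns, p=pop0 / pop0.sum())
    entry = rng_k.integers(0, ny, size=ns)
    length = 1 + rng_k.poisson(max(config.career_mean_years - 1.0, 0.0), size=ns)
    exit_ = np.minimum(entry + length - 1, ny - 1)

    # residence paths: a relocation takes effect at the start of a year
    rng_m = stream(seed, "moves")
    res = np.full((ns, ny), -1, dtype=np.int64)
    res[np.arange(ns)[entry == 0], 0] = home[entry == 0]
    truth_rows: list[tuple[int, int, int, int]] = []
    for t in range(1, ny):
        res[entry == t, t] = home[entry == t]
        cont = (entry < t) & (exit_ >= t)
        idx = np.nonzero(cont)[0]
        if idx.size == 0:
            continue
        origin = res[idx, t - 1]
        res[idx, t] = origin
        # hazard evaluated at the origin's GDP in the at-risk year t-1
        h = config.hazard.rate(log_gdp[origin, t - 1])
        movers = idx[rng_m.random(idx.size) < h]
        if movers.size == 0:
            continue
        prev_active = (entry <= t - 1) & (exit_ >= t - 1)
        stock = np.bincount(res[prev_active, t - 1], minlength=nc).astype(float)
        for i in movers:
            o = res[i, t - 1]
            w = stock.copy()
            w[o] = 0.0
            if w.sum() <= 0:
                w[:] = 1.0
                w[o] = 0.0
            d = rng_m.choice(nc, p=w / w.sum())
            res[i, t] = d
            truth_rows.append((i, o, d, t))

    # publications
    rng_p = stream(seed, "pubs")
    npubs = config.pubs_per_year_min + rng_p.poisson(
        config.pubs_per_year_mean - config.pubs_per_year_min, size=(ns, ny)
    )
    npubs[res < 0] = 0
    # every scholar publishes at least once
    silent = np.nonzero(npubs.sum(axis=1) == 0)[0]
    for i in silent:
        active = np.nonzero(res[i] >= 0)[0]
        npubs[i, rng_p.choice(active)] = 1

    cell_s, cell_y = np.nonzero(npubs > 0)
    counts = npubs[cell_s, cell_y]
    rec_c = np.repeat(res[cell_s, cell_y], counts)

    # multi-affiliation noise: a minority (or exactly half) of a year's
    # publications are attributed to the previous residence when it differs,
    # otherwise to a random other country
    rng_n = stream(seed, "noise")
    if config.multi_affil_prob > 0:
        offsets = np.concatenate([[0], np.cumsum(counts)])
        # cell_s is scholar-major, so the first cell per scholar is their
        # first publication year; a tie there has no residence history to
        # resolve it, so only a strict minority may be misattributed
        is_first = np.zeros(cell_s.size, dtype=bool)
        is_first[np.unique(cell_s, return_index=True)[1]] = True
        noisy = np.nonzero(
            (rng_n.random(cell_s.size) < config.multi_affil_prob) & (counts >= 2)
        )[0]
        for j in noisy:
            s, y, n_j = cell_s[j], cell_y[j], counts[j]
            m_max = (n_j - 1) // 2 if is_first[j] else n_j // 2
            if m_max < 1:
                continue
            cur = res[s, y]
            prev = res[s, y - 1] if y > 0 else -1
            if prev >= 0 and prev != cur:
                alt = prev
            else:
                alt = (cur + 1 + rng_n.integers(0, nc - 1)) % nc
            m = rng_n.integers(1, m_max + 1)
            rec_c[offsets[j] : offsets[j] + m] = alt

    publications = pd.DataFrame(
        {
            "scholar_id": np.char.add("s", np.char.zfill(np.repeat(cell_s, counts).astype(str), 6)),
            "pub_id": np.char.add("p", np.char.zfill(np.arange(rec_c.size).astype(str), 8)),
            "year": years[np.repeat(cell_y, counts)],
            "country": codes[rec_c],
        }
    )

    covariates = pd.DataFrame(
        {
            "country": np.repeat(codes, ny),
            "year": np.tile(years, nc),
            "gdp_ppp_2017": np.exp(log_gdp).ravel(),
            "population": population.ravel(),
        }
    )

    if truth_rows:
        tr = np.array(truth_rows, dtype=np.int64)
        truth = pd.DataFrame(
            {
                "scholar_id": np.char.add("s", np.char.zfill(tr[:, 0].astype(str), 6)),
                "origin": codes[tr[:, 1]],
                "destination": codes[tr[:, 2]],
                "year": years[tr[:, 3]],
            }
        ).sort_values(["scholar_id", "year"], kind="mergesort", ignore_index=True)
    else:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS).astype(
            {"scholar_id": str, "origin": str, "destination": str, "year": np.int64}
        )
    return publications, covariates, truth


def simulate_rate_panel(
    n_countries: int = 100,
    n_years: int = 20,
    gdp_low: float = 1_000.0,
    gdp_high: float = 120_000.0,
    exposure_low: int = 200,
    exposure_high: int = 20_000,
    hazard: HazardSpec = HazardSpec(h_max=1.0),
    year_start: int = 1998,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a country-year model frame with Poisson emigration counts.

    This is the macro-level twin of :func:`generate_corpus`: instead of
    simulating individual careers it draws, per country-year, GDP per capita
    log-uniform on ``[gdp_low, gdp_high]``, an exposure (active scholars at
    risk) uniform on ``[exposure_low, exposure_high]``, and an emigrant count
    ``Y ~ Poisson(exposure * h(log gdp))`` with the quadratic hazard. The
    returned frame has columns ``country, year, emigrants, exposure,
    gdp_ppp_2017, log_gdp`` and feeds :func:`scholarmigrate.gamm.build_design`
    directly.
    """
    rng = stream(seed, "rate_panel")
    codes = country_codes(n_countries)
    n = n_countries * n_years
    gdp = np.exp(rng.uniform(np.log(gdp_low), np.log(gdp_high), n))
    exposure = rng.integers(exposure_low, exposure_high + 1, n)
    x = np.log(gdp)
    y = rng.poisson(exposure * hazard.rate(x))
    return pd.DataFrame(
        {
            "country": np.repeat(codes, n_years),
            "year": np.tile(np.arange(year_start, year_start + n_years), n_countries),
            "emigrants": y,
            "exposure": exposure,
            "gdp_ppp_2017": gdp,
            "log_gdp": x,
        }
    )


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise CorpusValidationError([f"{path.name}: cannot parse CSV ({exc})"]) from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CorpusValidationError([f"{path.name}: missing columns {missing}"])
    return df[columns]


def validate_corpus(publications: pd.DataFrame, covariates: pd.DataFrame) -> list[str]:
    """Schema/consistency checks; returns a list of human-readable errors.

    Row numbers are 1-based positions in the data section of each table
    (header excluded).
    """
    errors: list[str] = []
    cov = covariates
    for col in ("gdp_ppp_2017", "population"):
        bad = np.nonzero(~(cov[col].to_numpy(float) > 0))[0]
        for i in bad[:20]:
            errors.append(f"covariates row {i + 1}: {col} must be > 0, got {cov[col].iloc[i]}")
    dup = cov.duplicated(["country", "year"])
    for i in np.nonzero(dup.to_numpy())[0][:20]:
        errors.append(
            f"covariates row {i + 1}: duplicate (country, year) = "
            f"({cov['country'].iloc[i]}, {cov['year'].iloc[i]})"
        )
    known = set(cov["country"])
    years = cov["year"].to_numpy()
    year_lo, year_hi = (int(years.min()), int(years.max())) if len(cov) else (0, -1)
    pub = publications
    if pub["pub_id"].duplicated().any():
        errors.append("publications: duplicate pub_id values")
    unknown = ~pub["country"].isin(known).to_numpy()
    for i in np.nonzero(unknown)[0][:20]:
        errors.append(
            f"publications row {i + 1}: unknown country code {pub['country'].iloc[i]!r}"
        )
    yr = pub["year"].to_numpy()
    out = (yr < year_lo) | (yr > year_hi)
    for i in np.nonzero(out)[0][:20]:
        errors.append(
            f"publications row {i + 1}: year {yr[i]} outside covariate range "
            f"[{year_lo}, {year_hi}]"
        )
    # every (country, year) used by a publication needs a covariate row
    if len(pub):
        cov_pairs = set(zip(cov["country"], cov["year"]))
        pairs = np.array(
            [(c, y) not in cov_pairs for c, y in zip(pub["country"], yr)]
        )
        pairs &= ~(unknown | out)  # already reported above
        for i in np.nonzero(pairs)[0][:20]:
            errors.append(
                f"publications row {i + 1}: no covariate row for "
                f"({pub['country'].iloc[i]}, {yr[i]})"
            )
    return errors


def write_corpus(
    publications: pd.DataFrame,
    covariates: pd.DataFrame,
    path,
    truth_events: pd.DataFrame | None = None,
    header: dict | None = None,
) -> None:
    """Write publications/covariates (and optionally the truth log) as CSV.

    ``header`` entries are written as ``# key: value`` provenance lines above
    each table; they are ignored on read.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prefix = "".join(f"# {k}: {v}\n" for k, v in (header or {}).items())
    for name, df, cols in (
        ("publications.csv", publications, PUBLICATIONS_COLUMNS),
        ("covariates.csv", covariates, COVARIATES_COLUMNS),
        ("truth_events.csv", truth_events, TRUTH_COLUMNS),
    ):
        if df is None:
            continue
        with open(path / name, "w", encoding="utf-8", newline="") as fh:
            fh.write(prefix)
            df[cols].to_csv(fh, index=False)


def read_corpus(path):
    """Read a corpus directory; returns ``(publications, covariates, truth)``.

    ``truth`` is ``None`` when ``truth_events.csv`` is absent. Raises
    :class:`CorpusValidationError` listing offending rows when validation
    fails.
    """
    path = Path(path)
    publications = _read_table(path / "publications.csv", PUBLICATIONS_COLUMNS)
    covariates = _read_table(path / "covariates.csv", COVARIATES_COLUMNS)
    errors = validate_corpus(publications, covariates)
    if errors:
        raise CorpusValidationError(errors)
    truth = None
    if (path / "truth_events.csv").exists():
        truth = _read_table(path / "truth_events.csv", TRUTH_COLUMNS)
    return publications, covariates, truth
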