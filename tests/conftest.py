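import numpy as np
import pandas as pd
import pytest

import scholarmigrate as sm


@pytest.fixture(scope="session")
def small_corpus():
    """Default-noise corpus: 10 countries, 600 scholars."""
    cfg = sm.SimConfig(n_countries=10, n_scholars=600, seed=42)
    pubs, cov, truth = sm.generate_corpus(cfg)
    return cfg, pubs, cov, truth


@pytest.fixture(scope="session")
def small_run(small_corpus):
    """Corpus pushed through residence -> events -> panel."""
    _, pubs, cov, _ = small_corpus
    timelines = sm.assign_residence_all(pubs)
    events = sm.detect_events_all(timelines)
    panel = sm.build_panel(timelines, events, cov)
    return timelines, events, panel


@pytest.fixture(scope="session")
def rate_fit():
    """Auto-REML GAMM fit on a 60-country x 12-year simulated rate panel."""
    frame = sm.simulate_rate_panel(n_countries=60, n_years=12, seed=7)
    design = sm.build_design(frame, k=10)
    return sm.fit(design, lambdas="auto")


def toy_publications() -> pd.DataFrame:
    """Hand-enumerable 3-scholar corpus (worked through in test_panel)."""
    rows = [
        ("s1", "p1", 2000, "AA"),
        ("s1", "p2", 2001, "AA"),
        ("s2", "p3", 2000, "AA"),
        ("s2", "p4", 2002, "BB"),
        ("s3", "p5", 2001, "BB"),
        ("s3", "p6", 2002, "BB"),
    ]
    return pd.DataFrame(rows, columns=["scholar_id", "pub_id", "year", "country"])


def toy_covariates() -> pd.DataFrame:
    rows = [
        ("AA", 2000, 30000.0, 5e6),
        ("AA", 2001, 31000.0, 5e6),
        ("AA", 2002, 32000.0, 5e6),
        ("BB", 2000, 2000.0, 8e6),
        ("BB", 2001, 2100.0, 8e6),
        ("BB", 2002, 2200.0, 8e6),
    ]
    return pd.DataFrame(rows, columns=["country", "year", "gdp_ppp_2017", "population"])
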