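# scholarmigrate

Tools for studying international migration of academic scholars from
bibliometric data, and for estimating how scholarly emigration relates to
economic development.

When a researcher's institutional affiliations are tracked across their
publications, changes of affiliation country reveal long-term migration:
someone whose primary affiliations move from one country to another, and
stay there for at least a year, has migrated. Aggregated over many scholars
this yields country-year emigration counts, at-risk populations of "active
scholars", and emigration rates per 1,000 scholars — demographic quantities
that can be modelled against covariates such as GDP per capita.

The package implements the full pipeline:

1. **`synthesize`** — generate synthetic publication corpora with known,
   configurable migration dynamics (real corpora of this kind are
   proprietary, so this module is the reference data source for testing and
   simulation studies);
2. **`residence`** — infer each scholar's country of residence per year as
   the country of primary affiliation with the most publications that year,
   carrying residence forward through publication gaps;
3. **`events`** — detect migration events as year-over-year residence
   changes;
4. **`panel`** — aggregate into a country-year panel of exposures
   (active-scholar person-years), flows, and rates per 1,000, with a
   population/size country filter;
5. **`gamm`** — fit a penalized Poisson generalized additive mixed model and
   locate the turning point of the development–emigration curve.

## The model

For the emigrant count $Y_{ct}$ of country $c$ in year $t$ with exposure
$E_{ct}$ (active scholars at risk, the previous year's stock):

$$\log \mathbb{E}(Y_{ct}) = \beta_0 + s(\log \mathrm{GDP}_{ct}) + s(t)
  + a_c + b_c\,(\log \mathrm{GDP}_{ct} - \overline{\log \mathrm{GDP}})
  + \log E_{ct}$$

with cubic B-spline smooths $s(\cdot)$ (dimension $k=10$, second-difference
penalties, sum-to-zero constraints) and country random intercepts $a_c$ and
random slopes $b_c$ estimated as ridge-penalized coefficients. Fitting is by
penalized IRLS; smoothing parameters come from an outer coordinate search on
an approximate REML criterion (fixed values can always be supplied).
Quasi-Poisson and negative-binomial variants are available.

The *marginal curve* is the predicted rate per 1,000 scholars as a function
of GDP per capita with random effects set to zero and predictions averaged
over the observed years; its interior minimum is the **turning point** —
the GDP per capita at which emigration stops falling and starts rising with
further development (a U shape, around $25,000 PPP in simulated corpora
generated with the default hazard).

## Worked example

```python
import scholarmigrate as sm

cfg = sm.SimConfig(n_countries=15, n_scholars=5000, seed=1)
pubs, cov, truth = sm.generate_corpus(cfg)
print(f"publications: {len(pubs)}  scholars: {pubs['scholar_id'].nunique()}  true moves: {len(truth)}")

tls = sm.assign_residence_all(pubs)
ev = sm.detect_events_all(tls)
print(f"detected events: {len(ev)}")

panel = sm.filter_countries(sm.build_panel(tls, ev, cov), top_n=15, min_population=0)
print(panel[["country", "year", "scholars", "emigrants", "rate_per_1000"]].head(4).to_string(index=False))

frame = sm.to_model_frame(panel)
fit = sm.fit(sm.build_design(frame, k=8), lambdas="auto")
print(f"model: {len(frame)} country-years, deviance {fit.deviance:.1f}, edf {fit.edf:.1f}")

tp = sm.find_turning_point(sm.predict_marginal(fit))
print(f"turning point: {round(tp)} PPP dollars (true hazard minimum: {round(cfg.hazard.argmin_gdp)})")
```

prints:

```
publications: 64169  scholars: 5000  true moves: 449
detected events: 425
country  year  scholars  emigrants  rate_per_1000
     AA  1998        16          0            NaN
     AA  1999        34          0       0.000000
     AA  2000        55          0       0.000000
     AA  2001        70          1      18.181818
model: 285 country-years, deviance 294.0, edf 6.0
turning point: 24351 PPP dollars (true hazard minimum: 25000)
```

The generator planted an emigration hazard quadratic in log GDP with its
minimum at $25,000; the pipeline detects 425 of the 449 simulated moves
(the rest fall in unobservable years or are masked by multi-affiliation
noise), and the fitted marginal curve's minimum lands within 3% of the
planted value. `rate_per_1000` is emigrants per 1,000 scholars at risk
(the previous year's stock), so each country's first panel year has no rate.

The same pipeline is scriptable from the shell:

```sh
scholarmigrate simulate --seed 1 --out corpus/
scholarmigrate panel --corpus corpus/ --out panel.csv
scholarmigrate fit --panel panel.csv --k 10 --lambda auto --out fit.json
scholarmigrate marginal --fit fit.json --grid 400 --out curve.csv
scholarmigrate turning-point --curve curve.csv
scholarmigrate run --config config.yaml   # full pipeline, one config
```

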