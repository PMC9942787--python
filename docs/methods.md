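# Methods

## Residence inference and migration events

A scholar's residence in year $t$ is the country of primary affiliation
with the largest number of publications in $t$ (the modal rule). Two
conventions complete the rule where the data alone do not decide it:

- **Ties** keep the previous year's residence when it is among the tied
  countries, otherwise the lexicographically smallest country code wins.
  Favouring continuity is consistent with residence being a state of at
  least one year's duration, and both branches are deterministic.
- **Gap years** (no publications between the first and last publication
  year) carry the most recent observed residence forward and are flagged
  `imputed`. Absence of publications is not evidence of relocation, and no
  migration event is ever dated to an imputed year by construction: the
  imputed residence equals the previous year's.

Scholars exist for the analysis only inside their *active window*, first to
last publication year; this window defines the "active scholar"
denominators.

A migration event is a change of residence between consecutive years; at
annual resolution such a change is automatically a relocation of at least
one year, the standard long-term migrant criterion. The event year is the
first year of residence in the destination. Moves in consecutive years are
all kept; no extra minimum-stay smoothing is applied on top of the annual
resolution.

## Exposure and rates

Residence in year $t$ places a scholar in country $c$'s exposure
(active-scholar person-years) for $t$. A scholar moving in year $t$ is
therefore in the origin's exposure for $t-1$, the destination's for $t$,
and the origin's emigrant count for $t$. Emigration rates consequently use
the **previous year's scholars** as denominator — the population actually
at risk of leaving. This choice makes `emigrants(c,t) <= scholars(c,t-1)`
an identity, bounds every rate in $[0, 1000]$ per 1,000, and leaves each
country's first panel year without a rate; those rows are dropped from the
model likelihood. (With a same-year denominator, rates above 1,000 are
possible in principle whenever inflows shrink a country's stock in a year
of heavy outflow.)

The country filter used before modelling keeps countries whose mean
population over the panel years is at least 0.5 million, then the top 100
(configurable) by total active-scholar person-years; the population gate is
applied before the ranking.

## The emigration model

$$\log \mathbb{E}(Y_{ct}) = \beta_0 + s_1(x_{ct}) + s_2(t) + a_c + b_c (x_{ct} - \bar x) + \log E_{ct}$$

where $x = \log$ GDP per capita (2017 constant international PPP dollars),
$E$ is the lagged exposure, $Y | x \sim$ Poisson (quasi-Poisson and
negative-binomial with moment-estimated $\theta$ are available for
overdispersed flows; Poisson is the default as the minimal model consistent
with the log-link count formulation).

Numerical construction:

- **Smooths**: cubic B-splines with $k = 10$ basis functions per smooth
  (open knot vector, evenly spaced interior knots over the observed range),
  second-difference penalties $D_2^\top D_2$, and a sum-to-zero constraint
  absorbed by a null-space reparameterization $Z$ so each smooth is
  identifiable against the intercept. $k = 10$ is ample for a U-shape; the
  design builder refuses $k$ larger than the number of distinct covariate
  values.
- **Random effects**: one intercept and one slope coefficient per country,
  with identity (ridge) penalties whose weights play the role of reciprocal
  variance components. The slope covariate is log GDP centered within the
  fitted sample, which decorrelates slopes from intercepts and stabilizes
  the iterations.
- **Fitting**: penalized IRLS on the log link; convergence when the
  relative deviance change falls below $10^{-11}$ or the coefficient step
  below $10^{-12}$ (the tight default supports exact-invariance checks such
  as offset scaling). The linear predictor is clamped at $\pm 30$ to guard
  the exponential during early iterations.
- **Smoothing-parameter selection**: an outer coordinate search per term on
  a $\log_{10}\lambda$ grid (−4…8, then half- and quarter-decade
  refinement), minimizing a Laplace-approximate REML score evaluated at the
  converged working model,
  $\tfrac12 [ \mathrm{dev} + \beta^\top S_\lambda \beta + \log|X^\top W X + S_\lambda| - \log|S_\lambda|_+ ]$.
  The penalty blocks are disjoint, so the pseudo-determinant separates over
  terms. IRLS is warm-started between evaluations. Fixed $\lambda$ values
  bypass the search entirely and make fits bit-reproducible across runs.
- **Limits worth knowing**: as all $\lambda \to \infty$ a
  second-difference-penalized smooth shrinks to its penalty null space — a
  *line*, not a constant — so the "null model" limit retains a
  statistically small linear component; and as the random-effect ridge
  $\lambda \to \infty$ the fit converges to the no-random-effects model.

**Marginal curve**: predictions on a GDP grid with random-effect columns
set to zero, unit exposure scaled to per-1,000, averaged over the observed
years (averaging rates, i.e. the mean of $\exp$, matching how per-country
curves are summarized). When year-averaging is off, the year smooth is
evaluated at the median observed year. Prediction outside the fitted GDP
range raises unless extrapolation is explicitly enabled.

**Turning point**: the default grid is 400 log-spaced points between the
1st and 99th percentiles of the fitted GDP values (avoiding spline boundary
artifacts). The curve's argmin counts as a turning point only if it is more
than two grid steps from either end and the curve is decreasing before and
increasing after it, tolerating wiggles below 0.5% of the curve's
amplitude (smaller wiggles are indistinguishable from numerical ripple of a
penalized spline). The reported value refines the grid argmin by parabolic
interpolation in log GDP.

## The synthetic corpus generator

The generator is the package's ground-truth data source; its defaults
describe a realistic mid-sized bibliometric setting:

| parameter | default | meaning |
|---|---|---|
| `n_countries`, `n_scholars` | 20, 2000 | corpus size |
| `year_start..year_end` | 1998–2017 | study window (20 years) |
| `career_mean_years` | 8 | mean active-career length, `1 + Poisson(mean-1)`, truncated at the window end |
| `pubs_per_year_mean`, `min` | 2.0, 0 | per scholar-year publication count `min + Poisson(mean-min)`; zeros create gap years |
| `hazard` $(\gamma_0,\gamma_1,\gamma_2,h_{max})$ | 21.0, −5.06332, 0.25, 0.5 | emigration hazard $\exp(\gamma_0+\gamma_1 x+\gamma_2 x^2)$ clamped to $[0,h_{max}]$; minimum ≈1%/year at $x=\log 25000$ |
| `gdp` | U(log 1500, log 90000) start; drift 0.02, σ 0.03 | per-country geometric-Brownian log-GDP series (the within-country variation the random slope needs) |
| `population` | lognormal(16, 1.5), +1%/yr | country size; also the home-country sampling weight |
| `multi_affil_prob` | 0.05 | chance a scholar-year attributes a minority of its papers to a second country |

Conventions: a relocation takes effect at the start of a year (the event
year is the first year in the destination); the hazard for a move in year
$t$ is evaluated at the origin's GDP in $t-1$, the at-risk year;
destinations are drawn proportional to current scholar stocks; home
countries are sampled proportional to population. Multi-affiliation noise
attributes a minority — or exactly half, creating a tie — of a year's
papers to the previous residence (or a random other country when there is
none). In a scholar's *first* publication year only a strict minority may
be misattributed: a tie there has no residence history to resolve it, so
allowing one would let pure noise fabricate migration events even under a
zero hazard, breaking the generator's ground-truth contract.

All randomness flows from one root seed through named streams (countries,
careers, moves, publications, noise), so adding a draw site in one stage
never perturbs another and equal seeds give byte-identical corpora.

The macro-level twin `simulate_rate_panel` skips careers entirely: per
country-year it draws GDP log-uniform on [1,000; 120,000], an exposure
uniform on [200; 20,000], and a Poisson emigrant count at the quadratic
hazard. It feeds the model directly and is the basis of the turning-point
recovery study.

**What the generator does not emulate**: real affiliation data have name
disambiguation errors, institution-to-country mapping noise, strongly
skewed productivity distributions, field- and cohort-specific mobility, and
returns migration correlated with past moves. Passing tests show the
pipeline recovers the planted dynamics of this idealized process, not that
the modal rule or the model are robust to those additional artefacts.

## Problem sizes

The turning-point recovery study uses ten replicates of a 100-country ×
20-year panel (2,000 observations, ~220 coefficients); one REML-selected
fit takes a few seconds, the full study well under a minute. Unit and
property tests use corpora of a few hundred to a few thousand scholars; the
rank-correlation check of hazard versus realized rates uses 50,000 scholars
to tame binomial noise in small countries.

## Known limitations

- REML here is the Laplace/working-model approximation with a grid-based
  coordinate search, not an exact marginal-likelihood optimizer; selected
  $\lambda$ can differ from full-REML software, though fitted curves are
  insensitive to this at the problem sizes above.
- No tensor-product smooths and no posterior-simulation confidence bands.
- The negative-binomial $\theta$ is a method-of-moments estimate from a
  Poisson pilot fit, not jointly profiled.
- Turning-point detection deliberately returns "none" for monotone or
  boundary-minimum curves rather than guessing.
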