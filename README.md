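# reefcmr

Capture-mark-recapture analysis of photo-identified sea turtles on coral
reefs, built around **Pollock's Robust Design**. The package is written for
researchers running photo-identification programs — each photograph of a
turtle's facial scale pattern is a "capture", the pattern itself the
permanent mark — who want abundance, apparent survival and population
stability estimates per reef site from opportunistic monthly sighting
records.

## The model

Sampling is organized into six-month **primary periods** aligned with the
Maldivian monsoon seasons (wet *hulan'gu*: May–October; dry *iruvai*:
November–April), each containing up to six one-month **secondary
occasions**. The population is assumed closed within a primary period and
open between them. Between consecutive primaries an animal survives with
apparent-survival probability *S* (mortality and permanent emigration
confounded) and can be **temporarily unavailable** (off the surveyed reef):
an available animal leaves with probability γ″, an unavailable one stays
away with probability γ′. Within a primary, an available animal is detected
each month with probability *p*, which may vary by season, by month, or
between two latent classes of individuals (finite-mixture heterogeneity with
weight π).

Fitting uses the conditional (Huggins-style) likelihood: each capture
history is evaluated by a forward recursion over the latent states
{available, unavailable, dead} starting at the first-capture primary, and
mixture classes are marginalized before conditioning,

    L_i = Σ_c π_c P_c(history) / Σ_c π_c p*_{f(i),c},

where p\*<sub>t,c</sub> = 1 − Π<sub>s</sub>(1 − p<sub>t,s,c</sub>) is the
probability of at least one detection in primary *t*. Abundance is derived
per primary as **N̂ₜ = nₜ / p\*ₜ** with delta-method standard errors. The
candidate set is the full factorial

  {S(.), S(season)} × {γ none, random, Markovian} × {p(.), p(season),
  p(session), p(season.month), p(mixture)} — **30 models**,

ranked by AIC, or by QAIC = −2lnL/ĉ + 2K when any of four contingency
goodness-of-fit components (transience- and trap-dependence-style tests on
primary-pooled histories) rejects; ĉ = Σχ²/Σdf is the variance-inflation
factor. Derived demographic statistics follow the standard definitions:
relative change N̂ₜ₊₁/N̂ₜ per interval, average annual growth
((N̂_final/N̂_initial)^(1/T) − 1)·100%, and the coefficient of variation of
the interval ratios as a stability index.

Because real photo-ID datasets of this kind are rarely deposited, the
package ships an individual-based simulator (`reefcmr.simulate`) that
generates sighting records with exactly this statistical structure plus
logged ground truth, used throughout the test suite for parameter-recovery
and calibration studies.

## Worked example

```python
from reefcmr import (RobustDesignModel, build_capture_matrix,
                     make_scenario, simulate_population)

cfg = make_scenario("stable_homogeneous", seed=5)   # S=0.8, p=0.25, γ=0.3
records, truth = simulate_population(cfg)
matrix = build_capture_matrix(records, cfg.design(), cfg.site, cfg.species)

est = RobustDesignModel(survival="constant", emigration="random",
                        detection="constant").fit(matrix)
print(est.conf_int_)
print(est.abundance().head(3).round(2).to_string(index=False))
```

prints

```
       estimate        lo        hi  se_logit
S      0.814701  0.787069  0.839479  0.088525
gamma  0.354789  0.307547  0.405044  0.108962
p      0.249769  0.237017  0.262970  0.035336
 primary season   n  p_star  N_hat   se     lo     hi
       1    wet 170    0.82 206.89 7.11 192.96 220.82
       2    dry 119    0.82 144.82 5.85 133.36 156.28
       3    wet 131    0.82 159.43 6.16 147.35 171.50
```

Six-month apparent survival is estimated at 0.815 (truth 0.8), monthly
detection at 0.250 (truth 0.25), random temporary emigration at 0.355
(truth 0.3); the abundance series tracks the simulated available population
(200 at the first primary, ~150 thereafter). `run_site_analysis` wraps the
whole per-site pipeline — all 30 structures, goodness-of-fit, AIC/QAIC
ranking, growth and stability — and `write_report` renders the tables and
figures.

A `reefcmr` command-line tool exposes the same steps
(`simulate`, `ingest`, `fit`, `gof`, `report`); see `reefcmr --help`.

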