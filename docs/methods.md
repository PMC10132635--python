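# Methods

## Model and assumptions

The analysis unit is a binary capture matrix (individuals × monthly
occasions) for one reef site and one species, laid over a Robust Design
calendar: six-month primary periods starting only at season boundaries
(May, November), one-month secondary occasions. A final partial primary
(1–6 months) is allowed and the likelihood uses the actual occasion count.
Assumptions inherited from the design: individuals are correctly identified;
the population is closed over the months within a primary; detections are
independent across individuals and months given the latent state; survival
and movement act only between primaries.

Latent dynamics per individual and primary-to-primary interval: survive
with apparent survival *S* (death and permanent emigration confounded),
then move between the *available* and *unavailable* (temporarily emigrated)
states with Pr(available → unavailable) = γ″ and
Pr(unavailable → unavailable) = γ′. "Random" emigration ties γ′ = γ″,
"none" fixes both at 0, "Markovian" leaves both free but time-constant —
sparse opportunistic data cannot support time-varying emigration, and this
reading makes the candidate suite exactly 30 models.

Detection structures: `constant` (1 parameter); `seasonal` (one per monsoon
season present); `monthly` (one per secondary occasion — the "session"
structure); `seasonal_by_month` (one per calendar month, shared across
years, ≤ 12); `mixture2` (two latent classes with class-constant monthly
detection plus the weight π — individual heterogeneity, e.g. boat-shy vs
conspicuous animals). Seasonal survival means one value per interval
starting-season (wet→dry vs dry→wet), two parameters.

## Likelihood

The fit maximizes the conditional (Huggins-type) likelihood: the forward
recursion over {available, unavailable, dead} starts at the individual's
first-capture primary in the available state; the emission of a primary is
Π p^y (1−p)^(1−y) in the available state and an all-zero indicator
otherwise. Mixture classes are marginalized *before* conditioning:

    L_i = Σ_c π_c P_c(history) / Σ_c π_c p*_{f(i),c},

with p\*ₜ,c the class probability of ≥ 1 detection in primary *t*. This is
one concrete convention among the possible mixture-conditioning rules; it is
validated against exhaustive latent-path enumeration in the tests.
Abundance is not a likelihood parameter: N̂ₜ = nₜ / p\*ₜ with
p\*ₜ = Σ_c π_c p\*ₜ,c. A full likelihood with an f₀ parameter (the
convention of some established capture-recapture software) would give
slightly different finite-sample estimates — abundance MLEs differ by the
order of one animal; numeric parity with that software is not promised.
The conditional form composes more cleanly with mixtures and unequal
primary lengths.

The normalization identity used for validation — probabilities of all
observable histories, conditional on ever-detection, sum to one — holds for
the *unconditional* history probability of an animal available at the first
primary; the per-first-capture conditional likelihood sums to the number of
primaries instead, so the package exposes both forms.

## Estimation and numerics

All probabilities are estimated on the logit scale (unconstrained) with
L-BFGS-B and finite-difference gradients from the deterministic start of
0.5 on the natural scale; for mixtures the two class-detection starts are
split (≈0.18/0.82) to break label symmetry, and optional seeded random
restarts are available. Covariance is the pseudo-inverse of a
finite-difference Hessian of the negative log-likelihood; Wald 95% intervals
are formed on the logit scale and back-transformed. Estimates with
|logit| > 12 are flagged as boundary solutions (e.g. a matrix where every
animal is seen at every occasion) but never raise. The abundance standard
error combines the binomial sampling term nₜ(1 − p\*)/p\*² with the
delta-method propagation of the parameter covariance through p\*; the lower
confidence limit is floored at nₜ, and primaries with p\* < 10⁻⁶ get an
undefined (NaN) abundance. Ties in (Q)AIC break toward fewer parameters,
then suite enumeration order, making the whole pipeline deterministic.

## Goodness of fit and overdispersion

Histories are pooled to binary detected/not per primary. Four components
are computed as sums of per-occasion Pearson chi-squares: `test3_sr` /
`test3_sm` contrast later re-detection (occurrence / timing) of newly vs
previously detected animals; `test2_ct` / `test2_cl` contrast immediate
(i+1) vs delayed next re-detection — and the timing among the delayed —
between animals detected and not detected at occasion i. The exact table
constructions follow the classical transience/trap-dependence test family;
columns with expected counts below 2 are merged into their neighbor with
the degrees of freedom reduced, and degenerate tables contribute nothing.
If any component rejects at α = 0.05, model ranking switches from AIC to
QAIC with ĉ = Σχ²/Σdf floored at 1 (ĉ < 1 is underdispersion and is never
used to reward complexity).

`pool_individuals` implements grouping into trios (sorted by
first-detection primary then identifier, OR within group, remainder merged
into the last group) for the sparse-data situation that motivates pooling
in field datasets. Pooling has a statistical cost: under mortality and
recruitment the OR-ed group histories are heterogeneous even when every
individual is homogeneous (groups differ in surviving members), which makes
the transience-style component anti-conservative. The calibration studies
in the test suite therefore run the components on individual histories
(group size 1), where all four components hold their nominal 5% level and
the dispersion ratio centers on 1; trio pooling remains available and its
inflation under dense data is a known limitation, not a defect of the
tests.

## Derived demographics

Relative change is the ratio N̂ₜ₊₁/N̂ₜ per consecutive primary pair (ratios,
not percent changes, so the stability index is invariant to rescaling the
series). Average annual growth is ((N̂_final/N̂_initial)^(1/T) − 1)·100%,
with *T* the elapsed years between the first and last surveyed months (the
May 2016–November 2019 window gives T = 3.5). The coefficient of variation
of the interval ratios (sample SD / mean) indexes stability; sites are
classified increasing/decreasing by the sign of growth and stable/unstable
against the cohort mean CV, with a t-interval across sites drawn on the
growth-vs-CV figure. Annual apparent survival compounds the six-month
estimate (S² for constant survival, S_wet·S_dry for seasonal); confidence
limits are compounded endpoint-wise, which is conservative.

## Synthetic data

The simulator mirrors the model's data-generating process — entry at
primary boundaries (initial cohort plus per-boundary recruitment, recruits
available on entry), survival then availability transitions between
primaries, monthly Bernoulli detection for alive-and-available animals —
and adds the nuisance structure of opportunistic photo-ID data: duplicate
photos within a month (shifted-Poisson count with mean
`sightings_per_detection`), per-individual carapace lengths and tail
morphology for the classification rules, and a dry-season detection boost
applied on the odds scale so probabilities stay in range. Scenario presets
fix the study conditions used by the tests: `stable_homogeneous` (200
initial animals, 40 recruits/primary, S = 0.8, γ′ = γ″ = 0.3, p = 0.25,
8 primaries × 6 secondaries — a roughly stationary population),
`mixture_heterogeneity` (400 animals, classes p = 0.05/0.6, π = 0.5),
`markovian_emigration` (γ′ = 0.75 ≠ γ″ = 0.25), `seasonal_detection`
(dry-season odds ×2.5) and `growing_recruitment` (recruitment ≫ mortality).

What the simulator does *not* emulate — misidentification, spatial movement
between reefs, effort fluctuations beyond the seasonal odds shift,
size-dependent detectability — bounds what passing tests show: they
validate the estimator and pipeline under the model's own assumptions, not
robustness to their violation in field data.

## Validation choices and problem sizes

The likelihood is checked against exhaustive latent-path enumeration (a
deliberately naive independent implementation) on matrices of ≤ 4
individuals over 3 primaries × 2 secondaries, for all 30 structures. The
closed-population reduction (single primary, no emigration) is compared to
a full-likelihood grid-search MLE at populations of 1500–3000 animals: the
conditional and full-likelihood estimators differ by O(1) animals by
construction, so the comparison is run where that gap is far below
three-significant-figure resolution and any disagreement would indicate a
coding error rather than the known estimator difference. Recovery and
coverage use 100 replicates of the stable scenario in the test suite; the
acceptance script uses 60 recovery, 30 mixture-selection and 150
calibration replicates and 25 oracle draws per structure, sizes chosen to
keep a full from-scratch rerun around a minute while leaving Monte Carlo
error well inside the decision margins.

## Known limitations

Emigration parameters are time-constant; no individual covariates, no
Jolly-Seber recruitment parameters, no Bayesian estimation. Mixture
likelihoods can be multimodal — the symmetric start is split and restarts
are available, but global optimality is not guaranteed. The trio-pooled
goodness-of-fit components are anti-conservative under turnover (above).
Wald intervals on the logit scale degrade near boundaries; boundary fits
are flagged rather than profiled.
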