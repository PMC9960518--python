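# Methods

## The problem

Cutaneous T-cell lymphoma (CTCL) is a rare non-Hodgkin lymphoma whose causes
are largely unknown; registry studies ask whether its incidence clusters
geographically and whether risk varies with race/ethnicity and area-based
socioeconomic status (SES). Because case counts per census tract are tiny,
raw tract-level standardized incidence ratios are dominated by Poisson
noise. The standard remedy is Bayesian disease mapping: a Poisson regression
with a spatially structured random effect that borrows strength across
neighboring tracts, shrinking each tract's estimate toward its neighborhood
mean.

This package implements that full analysis — descriptive incidence rates,
the spatial Poisson model, joint race-by-income effects — together with a
synthetic registry generator, because real registry case data are
confidential. The generator is not a test fixture: it is the package's
stated reference population, and every statistical claim made by the test
suite is a claim about data with its structure.

## Descriptive rates

Crude rates are cases per person-years, scaled per 100,000. Confidence
intervals are gamma intervals: for a single Poisson count the exact
chi-square/gamma bounds, and for directly standardized rates the Fay–Feuer
construction (the registry convention; SEER*Stat's default), which bounds a
weighted sum of Poisson counts `y = Σ (w_g / n_g) c_g` using gamma quantiles
with shape `y²/v` below and the `y + w_max` continuity correction above.
Direct standardization uses the 2000 US standard population in 19 age
groups (0, 1–4, …, 85+), shipped as a packaged table of the public
standard-million counts and renormalized to weights.

SES quartiles are assigned over tract values (Q1 = lowest values, always;
display vocabulary such as "Very High income" is the caller's mapping).
Two cutpoint conventions are provided: plain tract-value quantiles, and
case-weighted quantiles, which place ~25% of *cases* in each quartile. The
case-weighted method is the default because published registry tables that
show exactly 25.0% of cases per quartile can only arise that way; the
choice is configurable and the two can disagree materially when cases
concentrate in particular tracts.

Ties at a quartile cutpoint go to the lower quartile — a fixed, documented
rule rather than an error.

## Adjacency

The spatial prior's support is the rook-contiguity graph: tracts are
neighbors iff their boundaries share a segment of positive length
(intersection length > 1e-9 in coordinate units, separating true shared
edges from corner touches under floating-point polygon arithmetic). Rook
graphs can be built from polygons (GeoJSON), from a rectangular grid
shortcut (identical to the polygon path on unit-square lattices, which is
asserted in tests), or read as an explicit edge list.

An intrinsic CAR prior is undefined for a zero-neighbor tract, so islands
must be resolved before fitting. The default policy connects each island to
its nearest-centroid non-island tract with a warning (real coastal
geographies have shore-island tracts); `drop` and `error` policies are
available.

## The spatial model

Cells are tract × 19 age groups × sex × race/ethnicity. Counts are Poisson:

    O_c ~ Poisson(mu_c)
    log mu_c = log PY_c + b0 + x_c' beta + f_{t(c)} (+ u_{t(c)})

with log person-years as offset, dummy-coded categorical covariates
(references: male, NHW, lowest quartile Q1, youngest age group), a
structured tract effect `f` with an intrinsic CAR (ICAR) prior

    pi(f | tau2) ∝ exp( -(1/(2 tau2)) Σ_{i~j} (f_i - f_j)² )

over the rook graph, and optionally an exchangeable unstructured effect `u`
(BYM convolution when both are on; off by default — the structured effect
alone is the primary specification, the full convolution is a switch).
Priors: improper flat on b0 and beta; IG(0.001, 0.001) on both variance
components. Exponentiated fixed effects are relative risks (RR);
exponentiated tract effects are smoothed standardized incidence ratios
(SIR) against the statewide average, which the intercept represents.

Cells with zero person-years are dropped (an error if they carry cases).
A design column with no exposure at all (a declared level absent from the
data) would have an improper posterior under the flat prior, so such
columns — and only such columns — receive a diffuse N(0, 10²) stabilizing
prior, with a warning.

### MCMC

Metropolis-within-Gibbs, 10,000 iterations with a 2,000-iteration burn-in
and every 10th of the remaining 8,000 retained (800 draws) by default:

* **Fixed effects** update one coefficient at a time by random-walk
  Metropolis. Because every design column is an indicator, a proposal
  `beta_j → beta_j + δ` changes the log-likelihood by
  `T_j δ − (e^δ − 1) Σ_{c: x_cj=1} mu_c` with `T_j` the subset case total,
  so no full linear-predictor recomputation is needed.
* **The spatial field** updates nodewise by random-walk Metropolis against
  the Poisson likelihood (per-tract case and expected totals) plus the ICAR
  pairwise penalty. Nodes are swept in graph-coloring classes: within a
  class no two nodes are adjacent, so under the Markov prior they are
  conditionally independent and a whole class updates as one vectorized
  step. The sweep order is the coloring order, fixed by the (deterministic)
  greedy coloring of the node order.
* **Sum-to-zero**: after each sweep the field mean is subtracted and added
  to the intercept, leaving every mu unchanged; the retained draws satisfy
  Σ f_i = 0 to 1e-8 (asserted in tests). The same recentering applies to u.
* **Variances** are conjugate: tau2_f | f ~ IG(a + rank/2, b + ½ Σ_{i~j}
  (f_i − f_j)²) with rank = n_tracts − #components, and tau2_u | u ~
  IG(a + n/2, b + ½ Σ u_i²).
* **Tuning**: proposal scales adapt toward 20–50% acceptance in windows of
  100 iterations during burn-in only and are frozen afterwards, keeping the
  post-burn-in kernel fixed and the chain valid.

Initialization is neutral (beta = 0, f = 0, tau2 = 0.1). Chains are
reproducible: one seeded generator drives all proposals, and the design is
put in a canonical row order (tract, then factor levels) before fitting, so
permuting the input table cannot perturb floating-point summation order —
the retained draws are bit-identical (asserted).

The sampler's primary correctness gate is a conjugate closed form: for the
intercept-only non-spatial model, the flat prior on b0 is exactly the
improper Gamma(0, 0) prior on the rate λ = exp(b0), so the posterior is
Gamma(Σ O, Σ PY). The MCMC mean must agree within 3 Monte-Carlo standard
errors (MCSE from Geyer's initial-positive-sequence effective sample size).

### Summaries

* **RR**: exp(posterior mean beta) with exponentiated 2.5/97.5 percentiles.
* **SIR**: exp(posterior mean f_i) per tract (exponentiate-the-summary, as
  spatial coefficients are conventionally reported); posterior-mean-of-exp
  is available as an option and is never smaller (Jensen). Bounds are
  exponentiated percentiles; a tract is a **cluster** when its 95% interval
  excludes 1 (an 80% level can be requested). The **SIR range** is
  (min, max) over tract point estimates.
* **DIC** = Dbar + pD with pD = Dbar − D(posterior parameter means), D the
  Poisson deviance −2 log L. DICs are only comparable between models fitted
  to the same cell table; the validation harness therefore aggregates once
  over the union of candidate factors and fits all candidates to that table.
* **GD (geographic disparity percent)**: defined here — the quantity has no
  standard closed form in the literature that reports it — as the spatial
  share of linear-predictor variance,
  `GD = 100 × mean over draws of Var_tracts(f) / (Var_tracts(f) +
  Var_cells(X beta))`, variances taken empirically per draw. It is 0 when
  both variances vanish. The formula is echoed verbatim in every fit's
  metadata JSON so the number is never detached from its definition. It
  reproduces the qualitative behavior expected of the summary: near 100 for
  a covariate-free spatial model, near 0 when covariates explain everything,
  and it drops when a covariate that drives the spatial pattern enters the
  model.

### Joint race × SES effects

The joint model replaces the race and income main effects by one crossed
16-level factor (reference: NHW in the lowest income quartile Q1), keeping
age, sex and the spatial effect. Its display table reports within-race
percentages (summing to 100 across income levels inside each race group)
and each level's RR against the common reference. Under a multiplicative
(no-interaction) generating truth the joint RRs recover the products of the
main-effect RRs, which the tests assert.

## The synthetic registry

Defaults define the reference conditions: a 15×15 tract grid (225 tracts,
island-free by construction), 5,000 residents per tract observed for 9
diagnosis years (10.125M person-years), age structure from the 2000 US
standard distribution, even sexes, and a statewide race/ethnicity mix (NHW
0.56 / NHB 0.14 / Hispanic 0.20 / API 0.10) tilted tract-by-tract with
income rank at `segregation` strength so race × income joint effects are
estimable. The reference-stratum rate is 2e-4 per person-year, giving on
the order of 2,000 cases — deliberately a desk-scale epidemic: large
enough for stable estimation, small enough that a full MCMC fit takes
seconds. A real statewide registry of a rare lymphoma has ~10× the tracts
and ~10× the person-years but ~half the cases; absolute DICs, interval
widths and Monte-Carlo error here are therefore not those of real data,
and passing tests certify the method's calibration at this scale, not any
real-world estimate.

Tract median income is log-normal (median $70k, σ_log 0.35) with a
spatially smoothed ICAR component mixed in at weight
`income_spatial_correlation` (default 0.5), so income quartiles form
spatial clusters — making the SES-spatial confounding the model must
untangle actually present. Poverty is a decreasing logistic function of log
income plus noise. The generating truth carries female RR 0.6, NHB RR 1.5,
and top-income-quartile RR 1.5 (all other non-reference levels 0), a
spatial field drawn from the ICAR prior at tau2 = 0.01, and is stored
alongside the data for recovery tests.

ICAR fields are sampled exactly via the eigendecomposition of the graph
Laplacian: independent N(0, tau2/λ_k) coefficients on the non-null
eigenvectors, then re-centered to machine-exact zero sum. On a 2-node path
this implies Var(f_1 − f_2) = tau2 (the single non-null eigenvalue is 2,
its coefficient variance tau2/2), the closed form the Monte-Carlo tests
check. Disconnected graphs are rejected with the component count.

Everything is deterministic given the configuration seed; child seeds are
spawned per component, so geography, population, field and counts are each
individually reproducible.

## What the validation studies do and do not show

* **Parameter recovery** (20 replicates at default scale, 4,000-iteration
  chains with 1,000 burn-in — a shortened protocol, used because the three
  target posteriors mix quickly at this dimension): mean absolute bias of
  the posterior-mean log-RRs below 0.1, 95% CrI coverage within [0.85, 1].
* **Null-map calibration**: with a truly flat risk surface the 95% cluster
  flags fire at well **under** the nominal 5% — around 0.1–1% at these
  expected counts. This is the documented conservatism of shrinkage-based
  cluster detection, not a defect: the hierarchical posterior pulls every
  tract toward the common level when the data show no spatial signal, so
  an interval that still excludes 1 is strong evidence. The flag rate rises
  toward 5% only when per-tract expected counts are large enough for the
  likelihood to dominate the prior. Users should read "no flagged tracts"
  as "no evidence", never as a calibrated 5%-error test.
* **DIC selection** recovers the generating model among
  {intercept, +sex, +sex+income} in ≥80% (empirically 100%) of replicates
  at default scale; **GD** strictly drops when the income covariate that
  drives the spatial confounding enters, replicate by replicate.

## Known limitations

* Single-chain inference; no Gelman–Rubin diagnostics (effective sample
  size and MCSE are provided).
* Only categorical covariates; no smooth (P-spline) terms, space-time
  structure, or scan statistics.
* The GD definition is this package's own; numbers are not comparable to
  other software's "unexplained disparity" output except qualitatively.
* The grid geography has no islands, so the island policies are exercised
  only on constructed cases.
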