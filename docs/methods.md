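# Methods

`amimap` implements a small-area surveillance pipeline for acute myocardial
infarction (AMI) incidence of the kind used for township-level disease
mapping in large cities: record linkage of hospital-discharge and
death-registration streams, proportional population disaggregation,
Bayesian spatial smoothing of stratified incidence, direct age–sex
standardization, and percentile-based geographic inequality metrics. This
note documents the models, the defaults, the numerical choices, and what
the synthetic test bed does and does not demonstrate.

## Case definition and record linkage

Eligible records carry an ICD-10 principal discharge diagnosis or
underlying cause of death of I21–I22 and an age of ≥35 years; each stream
is filtered on its own code field, with no cross-stream veto. Four
deduplication rules then turn records into unique events, in this order:

1. **Same-day merge.** Per person, a record whose admission date falls on
   or before the running maximum discharge date of earlier records chains
   into the same continuous care episode (equality = transfer; strict
   overlap is merged too, and flagged in the audit). Episode length of
   stay is the sum of the constituent stays' lengths in calendar days.
2. **Short-stay exclusion.** Isolated non-fatal episodes with a total
   stay ≤1 day, no death record dated within the stay, and no chained
   readmission are excluded as implausible AMI admissions.
3. **In-hospital death linkage.** A death record dated within an
   episode's stay window for the same person marks the episode fatal and
   is not counted separately. Remaining death records become death-only
   events (onset = death date) — out-of-hospital deaths.
4. **28-day collapse.** Following the WHO-MONICA convention, episodes
   with onset within 28 days of an open event's *onset* merge into that
   event. The window is anchored at the index onset rather than rolled
   forward from the latest record; an anchored window is monotone (a
   wider window can never produce more events) and matches the "28 days
   from onset" reading of the convention. Onset of a hospitalized event
   is its admission date.

Every rule reports what it removed or merged (`LinkageAudit`). The
pipeline is validated against an independent brute-force implementation
(fixed-point interval merging plus recursive window-stripping) on ~10⁴
randomized per-person record sets, and against the synthetic generator's
ground truth, which it must recover exactly when the injected noise
consists of transfers, spurious ≤1-day stays and ≤28-day readmissions.

## Population disaggregation

Township denominators are published as annual sex totals only; age
structure is available at the district level. Person-years per township ×
sex × age group are estimated by proportional allocation within sex:
`person_years(t, s, a, period) = Σ_years pop(t, s, year) × p_district(a | s)`.
Applying age shares within sex (rather than joint age–sex shares to
overall totals) preserves the townships' observed sex composition.
Disaggregation conserves totals exactly by construction. Person-years for
a 3-year period are the sum of the three annual populations; all rates
are therefore per 100,000 person-years, i.e. annualized.

Agreement between two population sources is assessed at the district
level with a classical Bland–Altman analysis: limits of agreement are the
mean paired difference ±1.96 SD, and districts outside the limits are
flagged. A flagged district can be excluded end-to-end (map adjacency is
pruned; counts, person-years and all summaries are recomputed on the
remaining townships) as a sensitivity analysis.

## Spatial model

Counts per township i within one sex × age-group × period stratum follow
the Besag–York–Mollié (BYM) convolution model, the standard disease-
mapping model:

    y_i ~ Poisson(E_i exp(α + u_i + v_i))
    u   ~ ICAR(τ_u),   v_i ~ N(0, 1/τ_v) iid
    τ_u, τ_v ~ Gamma(0.5, 0.0005),   α ~ N(0, 10²)

with E_i the stratum person-years. The intrinsic CAR prior makes each
u_i conditionally normal around the mean of its neighbours with variance
1/(τ_u d_i); it is improper and is identified by recentring u to sum to
zero after every sweep, with the subtracted mean transferred into α so
the likelihood is untouched (exact on a connected map). Degree-0
townships (islands) have u_i fixed at 0 and rely on v_i. The
Gamma(0.5, 0.0005) hyperpriors are a common disease-mapping default and
are configurable. Each stratum is fitted independently; no strength is
shared across periods or age groups. Exposures enter as a person-years
offset (not internal standardization).

### Sampler

Inference is an own-code Metropolis-within-Gibbs sampler:

* α, each u_i and each v_i are updated by adaptive random-walk
  Metropolis on the Poisson log-posterior. Proposal scales are tuned
  toward 0.44 acceptance in blocks of 50 sweeps during burn-in only and
  frozen afterwards, preserving detailed balance.
* Spatial sites are updated simultaneously within graph-colouring
  classes (greedy colouring; two classes on a rook lattice). Same-colour
  townships are never neighbours, so their full conditionals do not
  interact and the blocked update is valid.
* τ_u and τ_v have conjugate Gibbs updates:
  τ_u ~ Gamma(a + (n − islands − c)/2, b + ½Σ_{i~j}(u_i−u_j)²) with c
  the number of connected components, and τ_v ~ Gamma(a + n/2, b + ½Σv²).
* After each Gibbs draw, an **interweaving (ASIS)** step proposes the
  precision again on the log scale in the non-centered parameterization
  (rescaling the whole field, whose standardized version is a priori
  independent of its precision). Without this step the precisions mix
  very slowly (effective sample sizes in the single digits at 4,000
  iterations); with it, R-hat for all parameters is near 1 at the
  default run length.

Defaults: 2 chains × 4,000 iterations, 2,000 burn-in, thin 1, chains
seeded from spawned, independent RNG streams. A run is a pure function of
(data, config, seed). Convergence is summarized by split-R-hat and
effective sample size (computed with `arviz`) for α, τ_u, τ_v and a
random subset of u_i; any R-hat > 1.05 flags the fit. Degenerate cases
(duplicate chains, single retained draw) are reported with warnings.
Setting `fix_tau_u` very large turns the spatial term off, reducing the
model to an exchangeable Poisson-lognormal hierarchy (used as an internal
consistency check).

All-zero-count strata run and return a near-prior posterior with a
warning; non-integer counts and non-positive exposures are errors.

The reported small-area estimate is the posterior mean of
exp(α + u_i + v_i) × 100,000 per township, with equal-tailed 95%
credible intervals from the pooled draws.

## Standardization and inequality

Direct standardization: standardized rate = Σ_s w_s r_s with standard
weights w_s summing to 1 over sex × age strata (renormalized within sex
for sex-specific age-standardization). Percent change between the first
and last period is 100 × (r_end − r_start)/r_start. Absolute geographic
inequality is p90 − p10 of township rates; relative inequality is
p90/p10. Percentiles use linear interpolation between order statistics
(the common statistical-software default; no convention is mandated by
the published tables this mirrors). When p10 = 0 the ratio is undefined
and reported as missing. Township decile classes are rank-based with
bins differing in size by at most one; ties break by township id, so the
classification is deterministic. Rates, ratios and percent changes are
reported to 1 decimal, matching conventional epidemiological precision.

## Synthetic city generator

Because registry microdata of this kind are confidential, the package
ships a generator that emulates the study conditions with known ground
truth:

* **Geography.** ~300 townships (default 16 districts × 19) laid out on
  a near-square planar lattice filled in snake order, so districts are
  contiguous blocks and the map is connected. Rook adjacency stands in
  for administrative contiguity: the analysis needs only the adjacency
  graph, not real polygons.
* **True rates.** log rate(i, stratum) = baseline(stratum) + u_i + v_i.
  The structured field u is drawn from the ICAR distribution restricted
  to the non-null eigenspace of the graph Laplacian (covariance = the
  Laplacian pseudo-inverse), rescaled to an exact empirical SD
  (default 0.3) and recentred; v is iid normal (SD 0.1). One field pair
  is shared across strata — high-risk areas are high-risk for all
  groups. Stratum baselines default to published township-level AMI
  incidence medians for a large Chinese megacity, 2007–2018, per sex ×
  age group × period (e.g. males 35–49: 96.5 → 148.8 per 100,000 across
  the four periods).
* **Population.** Township totals (residents ≥35, the denominator
  population) are log-normal around a median of 33,903 with σ = 0.82 —
  chosen as the average of the spreads implied by published 10th/90th
  township-population percentiles, which a symmetric log-normal cannot
  match simultaneously. Sex split ≈50/50. District age shares default to
  (0.55, 0.27, 0.13, 0.05) over 35–49/50–64/65–79/≥80 — a plausible,
  young 35+ structure for a rapidly grown megacity — with mild
  district-level jitter. Townships inherit their district's age structure
  exactly, so proportional disaggregation is exact by construction and
  any disaggregation error in tests is attributable to code, not data.
  A census-like copy of the totals carries small multiplicative noise
  (SD 1%) plus one deliberately discordant district (yearbook = 1.3 ×
  census) for the Bland–Altman check.
* **Events.** Stratum counts are Poisson(rate × person-years); each
  event materializes as records (non-fatal → one stay of ≥2 days; fatal
  in-hospital → stay with died status plus, by default always, a
  matching death record; fatal out-of-hospital → death record only; the
  fatal fraction defaults to 0.3, of which 30% die out of hospital —
  plausible values, as no split is published). Noise is then injected:
  same-day transfer splits (default probability 0.026), spurious ≤1-day
  stays by phantom persons (0.013), and readmissions within 28 days of
  onset (0.022) — rates chosen to match the relative frequencies the
  published deduplication counts imply. Every generator output is a pure
  function of (config, seed).

What the generator does **not** emulate: recurrent true events in the
same person more than 28 days apart, migration and population change over
time, township age structures that deviate from their district, real
boundary geometry, and any covariate structure. Passing tests therefore
demonstrate the correctness of the pipeline's logic and the model's
recovery behaviour under the stated generative family — not robustness to
misspecification in real registries.

## Problem sizes used in tests

The test suite exercises the linkage oracle on 10⁴ randomized per-person
record sets, noise cancellation on five 100-township cities at full
population scale, spatial-model recovery and interval calibration on 20
simulated 100-township cities (one stratum each, 2 chains × 4,000
iterations), and a full end-to-end run on a 50-township city at 2,000
iterations. The acceptance script runs the full pipeline at study scale
(304 townships, all 32 strata, 2 × 4,000 iterations). These sizes keep a
complete run on one CPU in the minutes range while leaving every
code path at realistic event counts.

## Known limitations

* The exact likelihood/prior specification used with the original
  OpenBUGS analyses of this kind is not published in main texts; the BYM
  convolution model with the stated hyperpriors is this package's
  explicit choice of the standard model family.
* The ICAR recentring-with-transfer is exact only on connected maps; on
  multi-component maps the per-component recentring is approximate (the
  component means cannot all be absorbed into a single intercept).
* Raw-rate comparisons use log((y + 0.5)/E) to handle zero counts.
* The single-area conjugate check compares against the Gamma(y, E)
  posterior, which corresponds to a flat prior on the log rate; the
  sampler's vague intercept prior approximates but does not equal it.
* Inequality metrics require ≥10 areas and Bland–Altman ≥3 districts;
  smaller inputs are rejected rather than extrapolated.
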