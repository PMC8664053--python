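# Methods

`hhsurvey` implements the sampling methodology of a municipal household
health survey: precision-driven sample-size planning over sex × age
strata, construction of size-homogeneous Primary Sampling Units (PSUs)
from census tracts, a self-weighting two-stage systematic PPS draw of
households, non-response accounting under a three-visit contact protocol,
and design-based evaluation of proportion estimates through the
coefficient of variation (Cv-p̂) and the design effect (deff). Everything
is exercised end-to-end on synthetic census frames, because microdata for
surveys of this kind are typically not public.

## Sample-size planning

Inputs are census counts N_s per stratum s (2 sexes × 7 age groups:
0–2, 3–4, 5–9, 10–14, 15–19, 20–59, 60+) and the municipal household
total D. With r_s = N_s / D the expected persons of stratum s per
household, the plan requires every stratum to contribute at least
m_min = 30 individuals in expectation — the usual normal-approximation
threshold for a proportion — so each stratum needs
h_s = round(m_min · D / N_s) households, and the base household sample is
n₀ = max_s h_s (the rarest stratum binds; in practice girls aged 3–4).
The field sample inflates for anticipated non-response:
n = floor(n₀ / response_rate) with a default anticipated response rate of
0.90.

Rounding conventions matter at this scale and are fixed as: ratios kept
unrounded internally (4-decimal display only), h_s and the expected
individual counts e_s = round(r_s · n₀) rounded half-up to nearest, and
the inflation truncated (floor). These conventions reproduce the packaged
reference planning tables cell-for-cell. One subtlety: when the binding
stratum's h rounds *down*, its expected count lands marginally under
m_min; the planner emits a warning instead of silently re-inflating (for
the two packaged municipalities the binding requirement rounds up, so no
warning fires).

The precision profile reports, for a stratum with n expected persons and
hypothesised proportion p, se = √(p(1−p)/n), the 95% CI p ± 1.96·se and
Cv-p̂ = 100·se/p, over a default grid p = 10%…70% in steps of 10. The
closed form is the default; a Monte-Carlo mode (binomial resampling)
agrees within simulation error and exists because anticipated precision
is sometimes presented as a "simulation". No finite-population correction
is applied by default (an `fpc_N` option exists); at p = 0.5,
Cv = 100/√n exactly.

## Synthetic census frames

The generator emulates the frame the design assumes: census tracts of
roughly 300 households / 1,000 inhabitants. Tract sizes are Poisson
around `mean_households_per_tract` (default 300), truncated below at 50
to avoid degenerate tracts, with a `fixed_tract_sizes` switch for
calibration studies; household sizes are zero-truncated Poisson with mean
3.33 persons (≈1,000 per 300 households); persons are assigned to the 14
sex × age strata multinomially, by default with the stratum shares of the
larger packaged municipality. Ages are generated directly as groups — the
design's strata are categorical, so no continuous-age model is needed or
claimed.

Binary indicators follow a logit-normal tract-level random effect: tract
t gets z_t ~ N(0,1) and a person in domain d carries the indicator with
probability expit(μ_d + σ_d·z_t). (μ_d, σ_d) are calibrated by
Gauss–Hermite quadrature and root-finding so the marginal prevalence hits
the requested value exactly and the intra-cluster correlation
ρ = Var(p_t)/(p(1−p)) hits the requested `icc`; a one-way ANOVA moment
estimator on generated frames recovers ρ within ±0.02. Missingness is
completely at random at the requested rate.

What the generator does *not* emulate: spatial geometry (tract adjacency
is by code order only), household-composition structure (members are
independent draws from the stratum distribution, so there is no
within-household correlation beyond the tract effect), age-specific
household sizes, and non-ignorable missingness. Tests passing on these
frames therefore validate the *design machinery* — selection
probabilities, variance estimation, deff behaviour — not any claim about
a real population's social structure.

## PSU construction

PSUs must have homogeneous household counts: coefficient of variation of
sizes at most 10% (population SD over mean). Starting from tracts in
code order, each pass splits any unit larger than 1.5× the mean size
into ⌈size/mean⌉ near-equal fractions (whole households,
largest-remainder) and greedily merges consecutive units smaller than
0.5× the mean into their successor. If a pass changes nothing while the
CV still exceeds the threshold — which happens for moderately dispersed
tracts where no unit crosses either trigger — a final rebalance cuts the
code-ordered household sequence into near-equal consecutive chunks, the
same divide-and-group vocabulary taken to completion; only if even that
fails does construction raise with diagnostics. Already-compliant inputs
pass through unchanged. Households are conserved exactly and each
household belongs to exactly one PSU; adjacency is by tract code, the
proxy for geography available without shapes.

## Two-stage draw and self-weighting

First stage: PSUs in code order, sizes M_i cumulated, interval
I = ΣM_i/a, real random start U ~ Uniform[0, I), selection of the PSUs
containing U + kI for k = 0…a−1. The fractional-interval form keeps
π_i = a·M_i/ΣM_i exactly proportional to size without requiring a to
divide anything; a PSU with M_i > I is a certainty unit (warned, π capped
at 1). Second stage: systematic sampling of households within each
selected PSU at the *fixed* design fraction b/M_i. Applied to the updated
field listing M_i′ this draws round(b·M_i′/M_i) households, so the
realized take grows or shrinks with the frame — by design, because
keeping the fraction fixed preserves equal overall probabilities:

    f = (a·M_i/ΣM_i) · (b/M_i) = a·b/ΣM_i

for every household, a self-weighting design with constant weight 1/f.
b is a configuration input (≈ planned n / a, e.g. 642/30 ≈ 21); frame
growth (M_i′ ≠ M_i) breaks exact equiprobability, the draw records
realized per-stage probabilities, and the default estimator keeps the
self-weights, as is standard for this design.

## Fieldwork and non-response

Each sampled household receives up to three visits (different days); a
visit finds nobody home with probability q independently. The first
successful contact resolves the household: refusal with probability
p_refusal, interview otherwise; all visits failed means non-response by
absence. Closed-form outcome probabilities — P(absence) = q³,
P(refusal) = (1−q³)·p_refusal — anchor the simulation tests. Rates over
X sampled households: NRR-Total = 100·x/X split additively into
NRR-Refusal and NRR-Absence, exact before rounding, reported to 1
decimal.

## Estimation

The proportion estimator is the weighted ratio p̂ = Σw·y / Σw over domain
respondents. Variance is by ultimate-cluster Taylor linearization:
per-PSU totals z_i = Σ_{k∈i} w_k(y_k − p̂)/W over *all* m design PSUs
(zero-contribution PSUs retained — the standard subpopulation
convention), v(p̂) = m/(m−1)·Σ(z_i − z̄)². First-stage units are treated
as with-replacement draws, absorbing all later stages; no
finite-population correction and no joint inclusion probabilities — the
standard treatment for self-weighting systematic-PPS designs and what
mainstream survey software reports. Simulation shows the estimator mildly
conservative in this design's regime (variance ratio ≈ 1.1 at small
sampling fractions), as with-replacement estimation should be. CIs use a
t critical value with m−1 degrees of freedom (z optional), truncated to
[0,1]. Estimation requires at least two contributing PSUs.

Diagnostics: Cv-p̂ = 100·se/p̂ (undefined at p̂ = 0),
deff = v(p̂)/(p̂(1−p̂)/n) with the SRS-with-replacement denominator
(undefined at p̂ ∈ {0,1}), and pass counts under the evaluation criteria
Cv below 20%, deff at most 1.5, and deff below 2.

Item missingness is completed by predictive mean matching: a linear
predictor fit on complete rows (ordinary least squares), each missing row
receiving the observed value of one of its k = 5 nearest-predicted donors
chosen uniformly at random (Euclidean distance on the linear predictor,
seed-controlled). Imputed values are always observed values, so binary
stays binary. The procedure refuses to run above 20% missingness — beyond
that, matching on one linear predictor is too strong an assumption to
patch silently.

## Orchestration and randomness

The pipeline (frame → PSUs → draw → fieldwork → estimation → evaluation)
spawns one RNG stream per stage from the master seed, with per-replicate
children, so changing fieldwork parameters never perturbs the draw and
every run is reproducible from the manifest. The replication harness
measures CI coverage against the frame's person-level proportion —
design-based coverage over sampling randomness.

## Monte-Carlo study geometries

The diagnostic studies are scaled down in absolute size but keep the
design's sampling *fractions*, to which with-replacement variance
estimation is sensitive:

* Coverage: one icc=0 frame of 150 tracts × 100 households (2.5
  persons/household), a = 30, b = 10 (f₁ = 0.2, f₂ = 0.1, domain
  n ≈ 750), 500 replicate draws. Observed coverage ≈ 0.96.
* Kish deff: frames of 100 tracts × 20 households, one person per
  household, a = 25, b = 20 (whole-cluster takes, b̄ = 20 exactly), 30
  frames × 12 draws per ρ ∈ {0, 0.02, 0.05}; mean estimated deff against
  1 + (b̄−1)ρ within 15%.
* Inclusion uniformity: 10 equal PSUs × 200 households, a = 5, b = 10
  (f = 0.025), 20,000 replicate draws; per-household frequencies sit on f
  (simultaneous 4.75-SE band ≈ 1% family-wise; a literal per-household
  3-SE band would be violated by chance alone across 2,000 simultaneous
  binomial counts).
* Fieldwork: 10,000 households at p_refusal = 0.2, q = 0.5 against the
  closed form within 3 binomial SEs.

## Numerical choices and edge cases

Round-half-up (`floor(x+0.5)`) everywhere a planning count is rounded —
banker's rounding would break the reference tables. ICC calibration
brackets σ by doubling and solves by Brent's method to 1e-10; icc = 0
short-circuits to σ = 0. Systematic sampling with k = length returns all
units; k = 0 returns none; an empty PSU listing draws 0 households with a
warning. Degenerate estimates (p̂ ∈ {0,1}) carry NaN diagnostics and are
flagged rather than dropped; exact se = 0 counts as passing all precision
criteria.

## Known limitations

* The with-replacement variance approximation overstates variance at
  large first-stage fractions and the estimator is not design-unbiased
  for systematic sampling with strong periodic structure; the frames here
  have none.
* PSU construction guarantees code-order adjacency only, not spatial
  contiguity.
* PMM uses a single linear predictor; it preserves marginal prevalence
  under MCAR but is not a multiple-imputation engine (no between-
  imputation variance).
* The fieldwork model has no day-of-week structure or persuasion effects;
  it is the minimal process consistent with the three-visit protocol and
  its closed form.
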