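# Methods

## Counterfactual model

The unit of analysis is the facility-year: deliveries, maternal deaths by
cause (obstetric hemorrhage, hypertensive disorders of pregnancy, other),
condition caseloads, and intrapartum stillbirths. The first year of the
series is the pre-intervention reference year. Three counterfactuals are
implemented:

- **steady_MMR** — deaths per delivery in the reference year, applied to each
  later year's deliveries. Simple, but confounded by case-mix change.
- **steady_CFR** (default) — reference-year case-fatality rates for OH and
  HDoP applied to each later year's *observed* caseload, plus an other-cause
  term. Rising caseloads with falling CFRs are thereby attributed to case
  management rather than case mix. The other-cause term either passes the
  observed other-cause deaths through (`hold_observed`, default — under which
  it cancels in the averted difference) or scales the reference-year count by
  deliveries (`scale_by_deliveries`).
- **steady_SBR** — reference-year stillbirths per delivery applied to later
  deliveries.

Deaths averted in a year = projected − observed. Deliveries stand in for
live births in all rate denominators; the published tables are reproducible
only under that reading and the two terms are used interchangeably in this
setting.

The **ARC adjustment** bounds attribution: with a national annualized rate
of change `g` (default −3.6%/yr), the counterfactual MMR declines as
MMR_ref·(1+g)^t, and the attributable share is the steady-MMR projection
minus this declining projection. It is reported as context and never
subtracted from the headline counts, because the secular trend itself partly
reflects programs of this kind.

**Rounding.** Yearly projected counts are rounded half-up for presentation
(`round_yearly`), which reproduces the published projection rows exactly;
fractional values are retained internally and used for all DALY conversion
(`keep_fractional`). Rounded and fractional totals can differ by at most
0.5 per year.

## DALY engine

DALY = YLL + YLD. The value of L life-years starting at age a is the
GBD-1990 burden integral (age weight C·x·e^(−βx) blended by K with an
unweighted year, discounted at rate r anchored at onset), evaluated in
closed form with λ = r + β:

    V(a, L) = K·C·e^(ra)/λ² · [e^(−λa)(λa+1) − e^(−λ(a+L))(λ(a+L)+1)]
              + (1−K)(1−e^(−rL))/r

The second term takes its r→0 limit (1−K)·L via `expm1` below r = 1e-12;
the first term degenerates to K·C·((a+L)²−a²)/2 when λ = 0. The closed form
is cross-checked against adaptive quadrature to 1e-6 relative over random
parameter draws in the test suite.

Defaults (units in years unless noted): K = 1, C = 0.1658, r = 0.03/yr,
β = 0.04/yr; maternal onset age 29.9 with 43.4 years remaining life
expectancy; stillbirth life expectancy at birth 61.2. "Undiscounted" is
defined as K = 0 and r = 0 jointly, so undiscounted values equal raw
durations (43.4, 61.2) — the convention the published undiscounted figures
follow.

**YLD.** Each averted maternal death is accompanied by M = 2 averted
lifelong disabilities of weight D = 0.3, sharing the decedents' age profile
(onset at age of death, lifetime duration), so YLD = M·D·YLL exactly. This
onset convention is required to reproduce the published discounted YLD of
17.18 = 2·0.3·28.64. Stillbirth DALYs have no YLD component and are
independent of M and D.

An age-group distribution path (proportion-weighted 5-year bins with
per-group life expectancies, e.g. interpolated from a life table) is
implemented for fidelity to the described procedure; the per-group death
proportions behind the scalar averages are unpublished, so the scalar pair
is the default and reproduces all headline values. Life tables support
bilinear interpolation in (age, calendar year); the packaged life table is
synthetic and exercises the interpolation only.

## Costing and ICER

Ledger amounts are base-year (2015) real USD across four funder categories;
the opportunity cost of volunteered professional time is valued at
role-specific daily rates (physician $1100, nurse anesthetist $750,
midwife/engineer/nurse-practitioner/consultant $500,
nurse/resident/biostatistician $330 per 10-hour day). `adjust_inflation`
deflates new nominal ledgers with a user-supplied index; the packaged ledger
is already in 2015 USD.

The published budget table rounds each line item to the nearest $100 before
summation and its grand total ($2,363,100) reflects that; the raw cells sum
to $2,362,910. `cost_table` reproduces the presentation convention
(half-up, since the table's exact-$50 ties round upward); `total_cost`
reports the raw sum, which is what the ICER uses. The $190 difference is
3 orders of magnitude below any decision threshold.

ICER = (program cost − comparator cost)/DALYs averted, comparator cost 0 by
default (the null program spends nothing). Classification against
GDP per capita (default $1,268): below 1× highly cost-effective, below 3×
cost-effective, else not cost-effective; zero or negative DALYs averted is
an undefined-ICER error, never a number.

## Sensitivity analysis

Parameters are independent by declaration (no correlations are specified in
the source assumptions; average age and remaining life expectancy are
therefore drawn independently — a fidelity caveat, since jointly they
over-disperse total life span). Distributions:

- uniform: average age [26.9, 32.9], remaining LE [39.1, 47.7], stillbirth
  LE [55.1, 67.3], disability weight [0.2, 0.4], disability multiplier
  [1, 3] (continuous), professional time ±25% of the ledger value;
- normal, mean = observed with bounds read as ±1.96 SE: yearly prevalences
  and CFRs (binomial SE: √(p(1−p)/n) on deliveries resp. cases) and yearly
  death/stillbirth counts (Poisson SE: √count), truncated at 0.

Each joint draw rebuilds the post-reference years (cases = prevalence ×
deliveries, condition deaths = cases × CFR clipped to [0,1]) and re-runs
the full pipeline; the reference year is never perturbed. 10,000 draws run
in a few seconds; intervals are percentile-based (2.5/97.5), not normal
approximations, because the ICER is a convex function of DALYs and its draw
distribution is right-skewed. Draws on which the model raises are rejected
and counted; more than 1% rejections aborts with a diagnostic. Fixed seeds
give bitwise-identical results.

The tornado evaluates the ICER at each parameter's 5th and 95th percentile
with the others at their mid values; the reported "variance share" is the
normalized squared swing (scale-invariant in the output units). A
rank-correlation (Spearman ρ²) contribution measure over the Monte Carlo
draws — the convention of spreadsheet Monte Carlo tools — is provided
separately; the two agree on the ranking here. Entries below a 1% share are
suppressed.

The published ±5 uncertainty on the 236 averted deaths is notably tighter
than binomial/Poisson propagation yields (Poisson noise on ~70 condition
deaths alone exceeds it); this package's 95% interval half-width is ≈19
deaths with the distributions above. The Monte Carlo *mean* is insensitive
to this and matches the published central estimate.

## Synthetic data

The generator emulates the observed structure: deliveries growing
geometrically, log-linear yearly trends in prevalence (rising), CFR
(falling — the intervention effect), and SBR (falling), with binomial cases
and condition deaths, Poisson other-cause deaths, and binomial stillbirths —
the minimal count-noise model consistent with the SE treatment above.
Log-linear trends keep rates in (0, 1) at any horizon. Default trend values
are calibrated to the observed 2007→2011 endpoints (e.g. OH CFR 14.8%
falling at −0.556/yr log slope).

Because the observed CFR decline is front-loaded, a two-parameter trend
cannot reproduce the intermediate years; `ScenarioConfig.from_series`
therefore calibrates per-year rate schedules exactly to a series, under
which the noise-free generator reproduces the observed counts to within
rounding and `known_truth` equals the deterministic arithmetic on the
observed table (≈237.4 deaths, ≈128.7 stillbirths averted).

`known_truth` returns closed-form expectations of the estimators under the
generative model. The steady-CFR estimator is conditionally unbiased (given
reference cases c > 0, E[deaths/c] equals the true CFR), so
E[estimate] = Σₜ E[casesₜ]·(CFR₀ − CFRₜ); parameter-recovery tests check the
estimator mean over 500 simulated facilities against this within 3 standard
errors. What passing these tests does **not** show: robustness to
overdispersion, reporting artifacts, case-definition drift, or referral-mix
change — none of which the year-level binomial/Poisson model represents.

## Problem sizes and numerics

All deterministic checks run on the packaged 5-year series in milliseconds;
the Monte Carlo acceptance checks use 10,000 draws and the recovery tests
500 replicate facilities, sizes at which the relevant standard errors are
an order of magnitude below the tolerances being checked. Floating point is
used throughout; rounding to printed precision happens only at the
presentation layer. Degenerate inputs (zero cases, zero DALYs, empty
ledgers, out-of-range ages) raise typed errors rather than returning
sentinel values.

## Known limitations

- Attribution is by steady-state projection, not causal inference; the
  quasi-experimental design is taken as given.
- Clinical care costs (drugs, admissions) are outside the costing scope.
- The independence assumption across sensitivity parameters is conservative
  in some directions and anti-conservative in others (see above).
- Neonatal outcomes and referral-network spillovers are not modelled.
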