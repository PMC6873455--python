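# Methods

## Problem and unit of analysis

The package quantifies regional variation in what an insurer pays for an
episode of surgical care in a working-age (18–65) population.  An *episode*
is an index inpatient admission for one of five procedures — primary hip
replacement (PHR), primary knee replacement (PKR), coronary artery bypass
grafting (CABG), lumbar spinal fusion (LSF), colectomy — plus all claims
through 90 days after discharge.  The geographic unit is the Hospital
Referral Region (HRR), reached from the provider zip code through a
crosswalk; regions with fewer than five cases of a procedure are dropped for
that procedure.

## Episode construction

Index admissions are inpatient facility claims carrying an index procedure
code.  Candidates are excluded, each with exactly one reason, in a fixed
order chosen so that tallies are reproducible:

1. `dual_coverage` — beneficiary has evidence of a second payer (modelled as
   a beneficiary-level flag; claims for these patients may be incomplete);
2. `trauma` — trauma diagnosis on the index claim, applied to PHR/PKR only;
3. `multilevel_fusion` — two or more distinct (level-specific) fusion codes
   on an LSF index claim;
4. `admitted_from_facility` — admission source SNF, long-term care, hospice;
5. `died_before_discharge`;
6. `non_elective` — emergent admission, for procedures analysed as
   elective-only (PHR, PKR, LSF).  For CABG and colectomy emergent status is
   instead a case-mix covariate (admission acuity), because urgent
   presentations are part of those procedures' normal case mix;
7. `overlapping_episode` — a qualifying admission that starts inside an
   earlier included episode's 90-day window does not open a new episode; it
   is treated as a readmission of the earlier one.  First admission by date
   wins; ties break on claim id.

Time windows are fixed day counts: the post-discharge window is days 1–90
after discharge inclusive, and the lookback is days −183 to −1 relative to
admission (six months operationalised as 183 days).  Lookback payments are
summed on the price-standardized scale so the covariate does not re-import
the regional price levels the pipeline removes.

Payments in the window are partitioned into four components: *index
hospitalization* (the index stay plus any facility claim dated inside it),
*readmissions* (inpatient facility stays admitted in days 1–90; a stay
admitted on day 90 counts in full — attribution by event onset),
*post-acute care* (rehab, SNF, outpatient facility, home health, hospice,
DME), and *professional fees* (clinician claims in any setting, kept as one
undivided category because inpatient and outpatient professional services
cannot be split reliably in claims).  A claim with an unrecognized class is
a hard error, never a silent bucket.  Amounts are split in exact cents at
generation; reports round to whole dollars, half away from zero.

## Price standardization

Payments are deflated by the labor-share-weighted wage index of the provider
zip:

    standardized = paid / (labor_share · w + (1 − labor_share)),

with default labor share 0.62, mirroring inpatient-prospective-payment-style
standardization in which only the labor share of a payment scales with the
local wage level.  One index per zip is applied to all claim classes; a
per-class index column is accepted where present.

## Cost model and empirical-Bayes reliability adjustment

Episode cost `y_ij` (episode *i*, region *j*) follows a log-link model with
a multiplicative regional effect:

    E[y_ij | u_j] = exp(x_ij' β) · u_j,   u_j ~ Gamma(mean 1, variance τ),

with gamma-type conditional variance `φ μ²`.  Case-mix covariates: age
(linear + quadratic, in decades centered at 45), sex, race (dummies;
missing race imputed from the sponsor's race), sponsor-rank
(junior-enlisted indicator, a socioeconomic proxy), Charlson comorbidity
index (integer), log1p of prior-six-month payments (in $1000), DRG weight
(centered at 1; CABG/LSF/colectomy), admission acuity (CABG/colectomy), and
cancer management (colectomy).

Estimation is an iterative moment / quasi-likelihood scheme:

1. with offsets `log û_j` (initially 0), estimate β by a gamma-family
   log-link GLM;
2. form `μ_ij = exp(x_ij' β)` and regional totals `O_j = Σ_i y_ij`,
   `E_j = Σ_i μ_ij`, hence indirectly standardized ratios `r_j = O_j/E_j`;
3. `φ` = Pearson dispersion of the full fit;
4. `τ̂ = max(10⁻⁸, mean_j[(r_j − 1)² − φ Σ_i μ_ij²/E_j²])` — the moment
   estimate of the between-region variance after subtracting each ratio's
   sampling variance;
5. `û_j = (α̂ + O_j/φ)/(α̂ + E_j/φ)` with `α̂ = 1/τ̂` — equivalently
   `w_j r_j + (1 − w_j)` with reliability `w_j = (E_j/φ)/(E_j/φ + α̂)`,
   the conjugate gamma-Poisson posterior mean on dispersion-scaled totals;

iterated until `max|Δβ| < 10⁻⁶` (at most 50 passes).  The reported adjusted
mean for region *j* is `û_j × mean(μ)` — the shrunken ratio scaled by the
national average case-mix-predicted cost, so `û_j = 1` places a region
exactly at the national mean.  τ̂ at its floor is reported as "no detectable
HRR variation".

**Gauge fixing.**  The intercept and a common scale of all `u_j` trade off
along a direction that leaves every fitted mean unchanged; unpinned, the
iteration drifts along it indefinitely.  The offsets therefore carry a copy
of the effects normalised to `mean(log u) = 0`, while the reported `û_j`,
`O_j`, `E_j`, `φ`, `τ̂` are the shrinkage-formula values evaluated at the
final β, so all stated invariants (`û_j` between 1 and `r_j`; `û_j = 1`
exactly when `O_j = E_j`) hold exactly.

**Convergence.**  Under the study conditions the loop converges in well
under ten passes.  When case mix is strongly collinear with region (heavy
confounding), β and the regional effects disentangle at a geometric rate
near 0.85 and the 50-pass cap can be reached with β still moving at the
10⁻⁵ level; the fit is then returned with `converged=False` and a warning.
All downstream quantities are stable at that precision.

**Components with zero-cost episodes** (readmissions, post-acute care; most
episodes have neither) cannot enter a gamma GLM directly.  The expected
component cost is taken as the national component share of the total-model
prediction, `μᶜ_ij = s_c μ_ij` with `s_c = Σ yᶜ / Σ μ`, followed by the same
moment/shrinkage steps on component totals with a *linear* conditional
variance (`φ_c μᶜ`, quasi-Poisson-type — the natural family for zero-inflated
totals, and exactly the scaling under which step 5 is conjugate).  The
dispersion is estimated within-region (residuals against `μᶜ r_j`) so the
regional signal does not inflate the sampling term; a region with no
component payments at all contributes zero residuals.  Professional fees,
which are strictly positive, go through the full GLM path.

## Ranking, quintiles, and variation statistics

Regions are sorted ascending on adjusted mean cost (ties broken by HRR id)
and cut at `ceil(qJ/5)`: quintile sizes differ by at most one.  Regions are
re-ranked separately for each payment component — a region can sit in the
cheapest quintile for totals and the dearest for readmissions.  Quintile
averages are unweighted across member regions (the region is the analysis
unit); episode-weighted averages are available behind a flag.  95% CIs come
from a seeded percentile bootstrap (default 1000 replicates) over member
regions; a single-member quintile is flagged degenerate.  The headline
statistic is the Q5 − Q1 spread in dollars and as a percentage of Q1, both
rounded half away from zero; differences are computed before rounding the
means.  A Q1 mean of zero leaves the percentage undefined (flagged), with
the dollar spread still reported.

## Synthetic claims generator

The generator emulates the structure the pipeline consumes, with every
generative parameter known: one provider zip per HRR with wage index uniform
on (0.8, 1.25); `u_j` gamma with mean 1 and variance τ (default 0.04);
episode totals `exp(x'β) u_j ε` with mean-1 gamma noise of CV 0.5 (gamma
noise keeps costs positive and matches the model's conditional family — the
conditional outcome family is this package's assumption, chosen consistent
with the gamma random effect); default coefficients: intercept 9.5
(≈ $13.4k mean episode), +0.05 per decade of age, −0.02 female, +0.04
junior-enlisted rank, +0.10 per Charlson point.  Totals are split in exact
cents across components with expected shares 62% index / 12% readmissions
(conditional on a readmission occurring, Bernoulli 0.08) / 6% post-acute
(across Poisson(1.2) claims) / 20% professional; shares of absent events are
reallocated proportionally, so the episode total remains exactly
`exp(x'β) u_j ε`.  Paid amounts on disk are wage-inflated — the exact
inverse of the standardizer — and lookback claims are generated in the 183
days before admission.  A configurable `confounding_strength` ties the age
and comorbidity distributions to a latent regional factor, producing data
where case mix is correlated with region.  Exclusion triggers (dual
coverage, trauma, multi-level fusion, facility admission, in-hospital
death, a day-91 out-of-window claim) are planted disjointly at configured
rates and recorded per episode in a ground-truth sidecar; a configurable
fraction of HRRs is generated below the five-case minimum.

What the generator does **not** emulate: real code-set semantics, calendar
effects, actuarially calibrated cost levels or procedure-specific cost
scales (all procedures share one β by default), hospital-level structure
within regions, longitudinal correlation beyond the single episode, and
denial/adjustment claim flows.  Passing tests therefore establish that the
pipeline's logic and estimators behave as specified under the assumed model,
not that real claims meet those assumptions.

## Study conditions used by the tests and the acceptance script

Parameter recovery runs 60 HRRs × 100 episodes at τ = 0.04 across 20 fixed
seeds (the suite) or 5 derived seeds (the acceptance script); the
adjustment-direction check runs 40 HRRs × 60 episodes with confounding
strength 1.5; the packaged end-to-end study is 40 HRRs × ~100 episodes
across all five procedures (~3,600 episodes, ~22,000 claims) with every
exclusion trigger planted.  These sizes were chosen as the smallest at which
the moment estimator's sampling error is well inside the recovery bands.

## Known limitations

- With gamma-type dispersion the reliability weight `(E_j/φ)/(E_j/φ + α̂)`
  is computed on dollar-scaled totals, so for large regions it is very close
  to 1 and total-cost shrinkage is mild; strong shrinkage appears where it
  matters, in low-volume regions and rare components.
- τ̂ for rare components (readmissions) is a noisy moment estimate: per-seed
  values range widely and can hit the floor, in which case component
  variation is reported as undetectable for that run.
- The standardization formula is a documented stand-in for the payer's
  proprietary pricing; parity with any specific pricer is out of scope.
- Charlson index is consumed as a precomputed column; computing it from
  diagnosis codes is out of scope.
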