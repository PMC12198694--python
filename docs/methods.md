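# Methods

## Model structure and assumptions

The model is a two-arm decision tree over a one-year horizon from a health
care system perspective, comparing a legacy EMR era with an integrated
shared-record (NGEMR) era for a cohort of patients referred from primary care
(polyclinic, "NUP") to a specialist outpatient clinic ("SOC"). Structural
assumptions:

- Every patient accrues the arm-specific polyclinic visit cost at entry; the
  modeled cohort enters via a primary-care referral.
- Access is summarised by the waiting-time stratum (<20 vs ≥20 days), which
  conditions the probability of actually attending the specialist
  appointment.
- Attendees may receive duplicate tests (a repeat of a recent diagnostic on
  transition between facilities, priced as a surcharge on the SOC visit) and
  may be admitted afterwards.
- Non-attendees either experience a combined "ED visit and admission" event
  or remain healthy; there is no ED-visit-without-admission path.
- Utility depends only on admitted status (0.89 admitted, 0.91 nonadmitted,
  applied for the year); no decrement for ED visits or duplicate testing.
- No discounting, no capital/implementation costs (variable bill-size
  perspective only), exactly two strategies.

Branch ordering is fixed (favourable outcome last within each chance node,
waiting <20 days first at the root) purely for reproducible enumeration.

## Parameters

21 inputs (2021 S$): per-arm waiting-time proportions, stratified attendance
probabilities, duplicate-test probabilities, post-specialist admission
probabilities, visit costs (NUP, SOC with/without duplicates), plus shared
ED-and-admission probability (0.30), admission cost, ED cost (141, fixed) and
the two utilities. Where the source text is more precise than its rounded
summary table, the precise values are used (attendance <20d 86.6%/88%,
waiting proportion 45.5% post, duplicates 29.4%/20.7%, admission
11.83%/11.55%), which minimises rounding error in the reproduced base case.

Probabilities and utilities carry beta distributions and costs gamma
distributions, moment-matched from (mean, SE): ν = m(1−m)/se² − 1,
α = mν, β = (1−m)ν for the beta; shape = m²/se², scale = se²/m for the
gamma. The admission cost is special: its base-case value (2707 S$) is a
median-based fee benchmark, while its uncertainty is an explicit
gamma(shape 2.06, scale 1549.32) whose median (≈2702) sits on the base case
but whose mean (≈3192) does not. Deterministic analyses therefore use the
printed mean column throughout, and only the PSA and bound computations use
the explicit gamma. The ED visit cost has no published uncertainty and is
treated as fixed (degenerate) everywhere.

## Cost-effectiveness and uncertainty analysis

- Base case: rollback of both arms, ΔC, ΔE, ICER = ΔC/ΔE (undefined at
  ΔE = 0; ties classify as weak dominance toward the cheaper/more effective
  arm), NMB(λ) = λE − C. Reference thresholds 0.5× and 1× 2021 GDP per
  capita (48,899 / 97,798 S$ per QALY).
- PSA: 1000 Monte Carlo iterations by default; every non-fixed parameter is
  drawn independently (no correlation structure is published), both arms are
  rebuilt from the same joint realization, and one shared `numpy` Generator
  with the table's canonical parameter order makes runs bit-reproducible
  given the seed. "Cost-effective" is the strict inequality λΔE − ΔC > 0.
- CEAC: the cost-effective fraction over a WTP grid (default 0 to 150,000 in
  steps of 1,000 S$/QALY, covering both reference thresholds).
- Tornado: each non-fixed parameter swung to its exact 95% distribution
  quantiles (IQR quantiles for the admission cost, whose SD is unavailable),
  others at base case. Entries are ranked by the width of the incremental-NMB
  range at the 0.5×GDP reference WTP: ΔE changes sign inside several
  parameters' bounds, so an ICER-range ranking would be dominated by sign
  pathologies (ICERs through ±∞); the per-bound ICERs are still reported.
  The two arms' post-specialist admission probabilities describe the same
  background admission rate, with the small arm difference an assumed
  intervention effect; their one-way swings therefore shift both arms by the
  same amount (preserving the assumed effect) rather than letting a
  background-level shift masquerade as the dominant driver of ΔC. All other
  per-arm parameters are data-derived per era and swing independently.
- Threshold analysis: bisection on a criterion that is affine in any single
  parameter — ΔC for cost saving, ΔC − λΔE for "ICER equals λ" — to a
  residual of at most 1e-6 S$ (the bracket is shrunk to ~1e-13 so the root
  also agrees with the closed-form linear solve to 1e-9). No sign change in
  the interval raises an error rather than clamping.

## Synthetic billing extracts

The generator stands in for the study's unlinked NUP and SOC extracts
(pre/post period = EMR/NGEMR era). What it emulates:

- SOC waiting times: gamma per period, integer days (floored), with shape
  pinned by a coefficient of variation of 0.75 and scale solved so that
  P(wait < 20 days) equals the period target (0.37 / 0.455). The real
  waiting-time law is unpublished; only the sub-20-day proportions are.
  "<20 days" is strict (wait_days ≤ 19).
- Attendance Bernoulli conditional on the wait stratum; duplicate tests
  Bernoulli among attendees; no-shows generate no bill.
- Bills: per-visit gamma with CV 0.5 by setting, period and visit type, with
  acute visits priced at 0.75× and chronic at 1.25× the period's published
  mean so the 50:50 pre-period mix reproduces it exactly in expectation;
  duplicate-test visits carry the assumed surcharge (76.97 / 78.74 S$).
- Case-mix shift: acute fraction 0.50 (pre) vs 0.65 (post), so naive
  post-period cost means are confounded and visit-type matching matters.
- Default size 15,000 visits per setting/period, consistent with the
  binomial SEs the published table reports (se 0.004 at p = 0.37 implies
  n ≈ 14,600); the end-to-end recovery check uses 100,000 per
  setting/period.

Estimation re-derives the data-derived parameters: binomial proportions (and
SEs) for waiting and stratified attendance, and matched cost means — exact
stratified reweighting of post-period visit-type strata to the pre-period
mix, the one matching variable available, with SE
sqrt(Σ w_t² s_t²/n_t) (the matched-weighted SE; the source does not state
how its cost SEs were computed). SOC visit costs are estimated from attended,
duplicate-free visits. Everything the extracts cannot inform (duplicate-test
and admission probabilities, ED, admission/ED costs, utilities, the
with-duplicate SOC price) passes through from ancillary literature specs.

What the generator does **not** emulate: patient-level linkage between
settings, seasonal/COVID backlog effects, heavy-tailed or zero-inflated bill
distributions, within-patient repeat visits, or the real extracts' exact
marginals beyond the published summary level. Passing recovery tests show
the estimators are consistent under the assumed generating process, not that
the process matches the real extracts.

## Numerical choices and known limitations

- All quantile computations use exact scipy distribution functions, never
  normal approximations (the published 13.2% lower bound for the NGEMR
  duplicate-test probability lands at 13.4% from the rounded mean/SE).
- Chance-node probabilities must sum to 1 within 1e-12; rollback agrees with
  exhaustive path enumeration to the same tolerance.
- Published inputs are rounded, so per-arm totals reproduce to ~0.1–0.2%
  but the printed incremental quantities (2.73 S$, 0.00006 QALYs, ICER
  46,349) do not survive input rounding — differences of near-equal numbers
  amplify it severalfold; the package asserts their signs and the ICER
  identity instead.
- The reported "fewer hospitalizations" effect is basis-dependent: the
  post-specialist admission probability drops by ≈2.4% relative while the
  overall modeled admission rate drops by ≈1.5%; both are computable.
- One-year horizon only: no Markov extension, readmissions, maintenance or
  cybersecurity costs, and no EVPI.
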