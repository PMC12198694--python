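# emrcea

Decision-tree cost-utility analysis of upgrading from a legacy electronic
medical record (EMR) to an integrated, shared-record system (Singapore's
Next Generation EMR, "NGEMR"), for health-economics analysts and health-IT
policy teams who want the full analysis — base case, probabilistic and
deterministic sensitivity analyses, and breakeven searches — as a tested,
scriptable Python pipeline instead of a point-and-click model.

## The model

Each referred patient enters primary care (a National University Polyclinics
visit), is referred to a specialist outpatient clinic (SOC), and flows
through a chance tree over a one-year horizon (no discounting):

```
wait stratum (<20 days / ≥20 days)
 ├─ attends the specialist appointment
 │    ├─ duplicate tests / no duplicate tests
 │    │     └─ admitted / not admitted
 └─ does not attend
      ├─ ED visit and admission
      └─ remains healthy
```

Twelve terminal paths per arm accumulate costs (polyclinic visit, SOC visit
with or without the duplicate-test surcharge, admission, ED) in 2021 S$;
utility is u_adm = 0.89 on any admitted path and u_non = 0.91 otherwise.
Rollback gives each arm's expected cost C and QALYs E, and the comparison is
summarised by

- ICER = ΔC/ΔE (intervention minus comparator),
- net monetary benefit NMB(λ) = λ·E − C at willingness-to-pay λ, with
  λ set at 0.5× and 1× 2021 GDP per capita (S$48,899 and S$97,798 per QALY).

Uncertainty: probabilities and utilities carry moment-matched beta
distributions, costs gamma distributions (the admission cost an explicit
gamma(2.06, 1549.32)); the PSA redraws every non-fixed parameter per
iteration, and one-way (tornado) and threshold analyses swing or solve single
parameters with everything else at base case. A synthetic visit-level
generator emulates the polyclinic/SOC billing extracts the parameters came
from, including the acute/chronic case-mix shift between periods that makes
visit-type matching necessary, and `parameters_from_cohort` re-estimates the
data-derived inputs from such a cohort.

## Worked example

```
$ emrcea base-case --out outputs
INFO emrcea: base case: costs 686.79 / 689.96 S$, QALYs 0.90704 / 0.90709, dC 3.1706, dE 4.46e-05
```

Expected one-year cost per referred patient is 686.79 S$ under the legacy
EMR and 689.96 S$ under NGEMR; the upgrade buys 4.46e-05 QALYs for 3.17 S$
per patient, i.e. a positive but small health gain at a small extra cost
(an ICER around S$71k/QALY from these rounded published inputs — incremental
quantities are very sensitive to input rounding, unlike the arm totals).

```
$ emrcea threshold --parameter p_wait_lt20 --arm NGEMR --lo 0.455 --hi 1.0 --out outputs
INFO emrcea: threshold p_wait_lt20 (NGEMR): breakeven 0.573740, residual -7.96e-13
```

If the share of NGEMR-era patients seen within 20 days rose from 45.5% to
about 57%, the upgrade would become cost-saving outright. Other subcommands:
`psa`, `ceac`, `tornado` (duplicate-test probability ranks most influential),
`simulate` and `estimate` (synthetic cohort round trip). All outputs are
CSVs embedding the seed and the parameter-table hash.

## Layout

| module | contents |
| --- | --- |
| `emrcea.parameters` | distribution specs, moment matching, CI/IQR bounds, table I/O |
| `emrcea.tree` | tree construction, rollback, path enumeration |
| `emrcea.cea` | ICER, NMB, dominance, WTP thresholds, base-case report |
| `emrcea.uncertainty` | PSA, CEAC, tornado, threshold search |
| `emrcea.synthetic` | cohort generator, matching, parameter re-estimation |
| `emrcea.cli` | `emrcea` command-line front end |

See `docs/methods.md` for modelling assumptions, parameter provenance and
numerical choices.
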