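# Methods

## Scope and data model

The pipeline costs one fiscal year of service delivery per facility from
the provider's perspective. A facility ledger is a directory bundle of
seven delimited tables (metadata, cost centres, capital items, recurrent
items, staff time, usage records, visit outputs); keeping entity types
in separate normalized tables makes study data diffable and easy to
audit. Economic and financial valuations travel in parallel: economic
cost values every resource consumed (donated equipment enters at
replacement value), financial cost only actual outlays (donated goods
enter at zero). Unknown service codes are hard errors — silently
dropping rows would bias totals — while unknown columns are ignored
with a warning. Missing cost rows are treated as absent (zero) and
logged; the pipeline makes no attempt to impute expenditures, only
visits (below).

## Annualization

Capital outlays are converted to equivalent annual costs by dividing
the replacement value by the present-value annuity factor
`a(r, n) = (1 − (1+r)^−n)/r`, with the exact continuity limit
`a(0, n) = n` so a zero discount rate reproduces straight-line
depreciation to machine precision. Defaults: discount rate 3%/year (the
standard rate in health-economic costing guidance); equipment life 4
years (midpoint of the usual 3–5 range, overridable per item);
furniture 10 years; training 3 years. Training is costed as a capital
good from facilitation costs, staff per diems and transport allowances;
its 3-year life is a modelling choice exposed in config — treating
refresher training as recurrent instead is equally defensible and can
be emulated with a 1-year life. Buildings are valued as annual
rental equivalents (rent per m² × floor area from a local rental
survey) and pass through annualization unchanged. Annualized values are
kept at full precision; rounding happens only at report time.

## Allocation

Three routes take cost to services:

* **Direct.** Usage records (drugs, diagnostics, supplies) sum by
  service; staff salaries split by timesheet fractions (service cost =
  salary × fraction); items booked to a final centre go to its service.
* **Step-down.** Overhead centres are processed in a single pass,
  largest accumulated cost first by default (`declared` order is also
  available; the order used is recorded in the audit trail). Each
  centre's accumulated pool is distributed over all not-yet-processed
  centres plus the final centres by the centre's basis; a processed
  centre never receives cost again, so no cycles can arise.
* **Ancillary.** Laboratory and pharmacy centres are processed after
  all overheads and distribute to final services by their shares of
  total recorded usage cost.

Each overhead centre steps down by **one** basis, resolved as: explicit
config override, else the basis mapped from the dominant subcategory of
the centre's own costs (utilities/maintenance/building capital → floor
area; administration, transport and centre-level salaries → staff
headcount), else staff headcount. Transport has no canonical basis in
the costing literature; headcount is the default here because facility
transport scales with staffing, and it is config-overridable. Staff
time not attributable to any study service ((1 − Σ fractions) × salary)
joins the overhead pool: booked to the staff member's own centre when
that centre is overhead or ancillary, otherwise to a facility-level
pool spread over final centres by headcount after the real overheads.

Allocation shares are proportional to basis measurements with the last
positive share set by complement, so shares sum to exactly 1 and no
floating-point residue leaks. An all-zero basis over a non-empty pool
is a hard error naming the source centre. Input categories are
preserved through every step: allocated administration stays "other
fixed", allocated pharmacy salaries stay "salaries", so the five-way
per-visit breakdown remains meaningful after allocation. Conservation —
matrix total + unallocated = total input, economic and financial — is
enforced by tests at 1e−6 relative tolerance and holds to machine
precision in practice. Reciprocal (simultaneous-equation) allocation is
deliberately out of scope.

## Unit costs and reporting

Unit cost per visit divides each allocated category cost by the
service's annual visit count; a service with positive cost and zero
visits raises an explicit error rather than reporting an infinity.
Where registers were missing, visits may be imputed from dispensing
records as `round(units / units-per-visit)` with half-to-even rounding
(unbiased over many ledgers). "Other costs" in reports is the sum of
allocated building maintenance, utilities, transport and
administration; supplies fold into the diagnostics column in the wide
per-visit table (a long-form output keeps them separate). Money is
rounded to 2 decimals and shares to whole percent (half-up) only at
presentation.

Subgroup summaries treat each facility as one unweighted observation
(mean and sample SD over facilities; SD absent at n = 1); a
visit-weighted mean is available behind a flag. Facilities not offering
a service are excluded from that service's n — including them as zeros
would conflate service absence with zero cost. The two-group comparison
defaults to the Mann–Whitney U test because unit costs are strongly
right-skewed; a Welch t-test on log costs is the alternative. With all
observations identical the rank test's p is reported as 1 (no evidence
of difference). PPP conversion is a single multiplier
(inflation ÷ PPP factor), fixed as inflate-then-convert; with constant
factors the order is purely presentational. Factor values are required
config inputs per country.

## Synthetic studies and ground truth

The generator emulates a 40-facility, two-country design: 30 facilities
in a lower-cost country (public hospital/district/sub-district/health
centre levels plus NGO SRH clinics) and 10 in a higher-cost one, all
six service lines offered. Visit volumes and per-visit cost components
are lognormal — strictly positive and right-skewed, with dispersion
defaults (σ = 0.6 for costs, 0.8 for volumes) giving across-facility
coefficients of variation of the same order as published multi-facility
cost studies. Default per-visit component medians follow the published
lower-cost-country pattern (HIV treatment drug-heavy at ~61% drugs;
cervical screening fixed-heavy), with a 2× country multiplier for the
higher-cost country.

Each ledger is assembled *backwards* from chosen per-visit targets:
capital values are backed out through the annuity factor (35% building
rent, 40% equipment of which 15% donated, 15% furniture, 10% training);
25% of other-fixed cost routes through an administration centre
(headcount basis, 60%) and a maintenance centre (floor-area basis,
40%); a pharmacist salary (8% of direct salaries) reaches services
through usage shares. The ground truth is computed from these choices
and explicit share arithmetic — never by running the allocation engine
— so pipeline-vs-truth comparisons cannot share bugs. Overhead and
ancillary centres carry zero floor area and headcount, so in generated
ledgers overheads distribute directly to final centres; the
overhead-feeds-overhead step-down path is exercised by independent
brute-force oracle tests instead.

What passing tests show — and do not show — about real data: the
generator reproduces the *structure* the method assumes (heterogeneous
cost levels, skewed volumes, donated goods, overhead pools, ancillary
departments), so exact ground-truth recovery validates the arithmetic
of annualization, step-down and unit-cost division. It does not emulate
misreported visit registers, missing expenditure records, within-year
price changes, or correlated cost components across services, so
agreement on synthetic data says nothing about measurement quality in
real ledgers.

## Numerical choices and limitations

* Problem sizes in the default test run: 40–100 synthetic facilities
  per suite, 200 for the country-contrast recovery check; each facility
  has ~35 ledger rows, so the whole suite runs in seconds.
* Tolerances: conservation 1e−6 relative (observed ~1e−16); ground
  truth 1e−9 relative; annuity factor vs discounted-sum oracle 1e−9.
* Ties in step-down ordering (equal pool costs) fall back to declared
  order via a stable sort.
* Facilities report whole-facility or departments-only costing scope;
  hospital-wide administration above the costed departments is outside
  the ledger either way, so "above service delivery" costs are never
  included — a scope flag records which interpretation a ledger uses.
* No regression-based cost-function estimation, cost-effectiveness
  ratios, or reciprocal allocation; the pipeline stops at unit costs
  and their descriptive variation.
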