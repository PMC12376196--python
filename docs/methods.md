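# Methods

## Evaluation model

Each intervention is reduced to three per-unit dollar components in a
single AUD reference year (carried as metadata; no inflation adjustment is
performed): implementation **cost**, **resource savings** (medical,
property, productivity) and **intangible savings** (the monetized value of
health improvement).  From these:

* **BCR** = (resource + intangible savings) / cost.  Cost ≤ 0 (possible
  only for tax changes whose revenue gain exceeds the welfare loss) yields
  the `NO_COST` sentinel rather than a ratio.
* **QALYs gained** = intangible savings / VSLY, the value of a statistical
  life year (AUD per QALY).
* **ICER** = (cost − resource savings) / QALYs gained.  When resource
  savings alone cover a positive cost the intervention is dominant and the
  ICER carries the `NET_SAVING` sentinel.
* **Classification** against a willingness-to-pay threshold (default
  A$50,000/QALY, boundary inclusive): `NET_SAVING` → cost_saving,
  `NO_COST` → no_cost_dominant, finite ICER ≤ threshold → cost_effective,
  else not_cost_effective.  The sentinel precedence is: non-positive cost
  dominates, so a negative-cost row is no_cost_dominant even though its
  resource savings trivially exceed its cost.

## Costing

Ingredients (bottom-up) costing: cost = Σ quantity × unit price over
non-overhead items.  Overhead and joint costs are excluded because
delivering one more intervention barely moves them.  Capital items with
lifetime n > 1 years are converted to an equivalent annual cost with the
annuity factor r/(1 − (1+r)^−n) at the economy-wide discount rate (default
3%/year, the same rate used to present-value future savings); at r = 0
this degenerates to straight-line n-ths.  The published source says only
that multi-year resources were "annualized"; the equivalent-annual-cost
form was chosen because it is NPV-consistent with the 3% rate used
everywhere else, and that consistency is enforced by a property test
(discounting the annual cost over the lifetime recovers the capital to
1e-9 relative).

Special environmental rules:

* **Foregone consumption** (advertising bans, outlet density, sales hours,
  minimum pricing): half the pre-tax purchase price of the alcohol not
  consumed — the supply-chain profit share, exposed as a parameter
  (default 0.5) for sensitivity analysis.
* **Volumetric tax changes**: administrative shift cost plus deadweight
  loss (consumer benefit loss minus tax revenue increase); may be
  negative.
* **Establishment liability**: an upper bound — 7.1% of expected annual
  lawsuit claims (claims value × 51% last-drink-at-licensed-premises ×
  50% who would sue) plus an aggregate court-cost allowance, default $0.
  The lawsuits themselves only transfer incident costs between payers and
  are excluded.  The 51% share is a parameter because its geographic scope
  in the source is ambiguous.
* **Time**: travel time at 60% of the wage rate, delay time at 90%.
* **Jurisdiction conversion**: multiply by the destination/source ratio of
  occupation salaries (labor), PPP (non-labor) or pre-tax drink prices
  (consumption).  Round-tripping is the exact identity.

## Benefits

Direct route: benefit = relative harm reduction × incidence × per-person
or per-event harm unit cost (resource and intangible components
separately; a basis mismatch is an error).  Transfer route: source-country
benefits × the target/source ratio of costs per alcohol-attributable harm.
Spillover savings (drug use, smoking, violence) are a separate additive
component.  Demonstration-stage estimates are attenuated by 25%
(effectiveness shrinks at scale).  Multi-year benefit streams are
present-valued at the discount rate before entering the ratios;
single-year benefits bypass discounting.

## VSLY calibration

The source tables print dollar components and ICERs but not the VSLY they
used.  `implied_vsly` inverts the ICER formula row by row
(intangible × ICER / net cost); `calibrate_vsly` takes the median over
rows with net cost ≥ $50 (smaller denominators amplify whole-dollar
rounding).  The environmental/workplace/health table implies
≈A$182,000/QALY with a coefficient of variation of about 0.1%; the
youth/school table implies ≈A$232,000/QALY with a CV near 2%.  The
package reports this inter-table discrepancy (possibly differential
treatment of youth outcomes in the source) and does not reconcile it;
each table is evaluated at its own calibrated value unless an explicit
VSLY is supplied.

## Fixtures and their quirks

The two printed tables carry 33 + 17 = 50 rows.  One drink-driving program
(subsidized ridesharing) appears in the study-description and adjustment
tables but has no printed cost-effectiveness row, so the category count of
that table (12) is one short of the overview table's 13, while the pricing
block prints 5 rows against the overview's 4; the row registry resolves
identities — Positive Action is evaluated twice (grades 3–8 and 3–5) as
one program — and reproduces the overview's total of 49 interventions.

Printed sentinel cells are stored verbatim as `NET_SAVING` / `NO_COST`
tokens.  The consistency checker recomputes each row from its own printed
components and flags:

* `sum_ok` — resource + intangible within $1 of the printed total (all 50
  rows pass);
* `bcr_ok` — recomputed BCR within ±0.15 of print.  Exactly four rows
  fail, all casualties of printed-input rounding: Prime for Life (354/19 =
  18.6 vs 18.2), the wine-excise replacement (27/3 = 9.0 vs 8.8), and the
  two volumetric rows with tiny or integer-printed figures (61/0.04 = 1525
  vs 1537; 9564/151 = 63.3 vs 63).  The synthetic rounding model
  reproduces this: the analytic worst-case BCR shift from whole-dollar
  rounding exceeds 0.15 exactly when the printed cost is small;
* `icer_ok` — at the calibrated VSLY, recomputed ICERs for rows with net
  cost ≥ $250 match print within 1% on the first table (all 11 checkable
  rows pass) and within 5% on the youth/school table, whose implied-VSLY
  dispersion is ~5× larger.  Two printed verdicts contradict their own
  components and are flagged rather than corrected: "interlock mandated
  for all offenders" prints "Net saving" although its printed resource
  savings ($1,794) fall $118 short of its cost ($1,912), and "Project
  Toward No Drugs" prints "$0" per QALY although its resource savings
  exceed its cost.  Dominance is always evaluated on stored values.

## Synthetic data generator

`generate_portfolio` emulates the structure of the evaluation inputs, not
any particular intervention: 2–6 ingredients per intervention with
log-normal unit prices (median $40, log-sd 0.8), occasional capital items
(probability 0.2, lifetimes 2–10 years) and overheads (0.15); uniform
effectiveness on [0.02, 0.30]; Poisson incidence (mean 25 events);
log-normal per-event harm costs (median $2,000, log-sd 0.6) split by a
Beta-distributed intangible share with mean 0.8 — matching the ≈80–85%
intangible share of the printed rows — and concentration 150; a 25%
demonstration probability with the 25% benefit discount applied.  VSLY
defaults to the calibrated A$182,000.  A single seeded NumPy generator
instance drives each run, so identical configs are bit-identical and
parallel tests cannot interleave draws.

Ground-truth BCR/ICER/QALYs/classification are computed inside the
generator from the closed-form definitions, deliberately duplicated rather
than imported from the pipeline, giving an independent oracle: the
parameter-recovery tests run the real pipeline over the emitted CSVs and
require agreement to 1e-9 relative (observed ~1e-15) on portfolios of
1,000 interventions across five seeds.  `perturb_rounding` then applies
printed-style whole-dollar rounding, and deviations must stay inside the
exact worst-case bound (numerator off by at most one unit, denominator by
half a unit).

What the generator does **not** emulate: study-level effectiveness
heterogeneity, correlation between cost and effectiveness, benefit streams
spread over multiple years, or spillover components.  Passing the recovery
tests therefore demonstrates arithmetic fidelity of the pipeline, not
robustness to the messiness of real effectiveness literatures.

## Uncertainty

The source reports no standard errors (no confidence intervals were
computable for its inputs), so the engine emits point estimates only;
sensitivity is supported through explicit parameters (VSLY, threshold,
profit share, liability shares, discount rate) rather than probabilistic
analysis.

## Problem sizes

Fixture computations cover all 50 printed rows and complete in well under
a second; the synthetic recovery check uses 1,000 interventions per seed
(five seeds in the test suite, one seed in the acceptance script).
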