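# Methods

## Model and assumptions

The package evaluates management scenarios on an expected-value basis only:
no Monte-Carlo realizations, no within-season population dynamics. The
season-level uncertainty is a two-stage lottery — outbreak / no outbreak,
then the population class conditional on an outbreak — and every reported
quantity (expected yield fraction, expected yield, expected cost, expected
net revenue) is the exact expectation over that lottery. Yield and crop
price are treated as independent, so the gross term factors as
E(Y)·E(P).

Management effectiveness is a rule engine, not a per-scenario table:

- an aphid-resistant variety is effective against every population class
  (virulent biotypes able to colonize resistant varieties are excluded by
  default; the retained fraction `q` for resistant varieties is a config
  field, so biotype damage can be represented by setting it below 1);
- otherwise, management is effective if at least one applied insecticide's
  mode-of-action group lies outside the realized class's survival set;
- with no application and a susceptible variety the outcome is
  "no management"; both "no management" and "ineffective" retain fraction
  `q` of attainable yield, effectiveness retains all of it.

Applications are resolved per class: the first application occurs whenever
the plan holds one (prophylactic sprays are calendar-based and also happen —
and are paid for — in no-outbreak years; threshold-based sprays occur only
in outbreak years). The rescue (second) application fires only when the
scenario includes efficacy scouting, an outbreak occurs, and the realized
class survives the first product's group. At most two applications are ever
made. The same logic yields the expected application and scouting counts
used on the cost side, which makes E(C) — and hence E(R) — affine in both
probability axes; this affinity is what lets the break-even solvers work in
closed form.

The eight case-study scenarios are regression-tested against hand-expanded
formulas (e.g. SHPN-I: EY = 1 − 0.127·p_o·(p_s + p_c)), and a brute-force
outcome-tree enumeration serves as an oracle for the closed-form evaluator
at 10⁻¹² tolerance.

## Parameters of the bundled 2018 Iowa configuration

| parameter | value | units | meaning |
|---|---|---|---|
| attainable yield Y | 3537 | kg/ha | ten-year (2009–2018) Iowa average |
| retained fraction q (S / R) | 0.873 / 1.0 | – | 12.7% outbreak loss on susceptible varieties |
| crop price E(P) | 0.33 | USD/kg | 2018 Iowa market price |
| outbreak probability p_o | 0.435 | – | share of 23 high-risk trial site-years with an outbreak |
| insecticide product (generic / 3A / 1B / 4C) | 22.88 / 13.83 / 21.98 / 61.78 | USD/ha | survey means per mode-of-action group |
| application cost | 20.02 | USD/application | custom-rate survey |
| scouting | 10.50 | USD/activity | 2 early visits always; 6 for monitoring; 1–2 for efficacy |
| seed (S.H / S.C / R.C) | 155.13 / 117.65 / 111.56 | USD/ha | survey means at 345,940 seeds/ha |
| herbicide product (H / C) | 89.70 / 118.61 | USD/ha | by the variety's herbicide trait |
| fixed items | 847.09 total | USD/ha | tillage, herbicide application, planting, early scouting, harvest, land rent |

Costing conventions, chosen once and used throughout:

- **Variable-cost default.** E(C) includes only the items that differ
  between scenarios; the fixed items are reportable via `include_fixed` and
  shift every scenario by the same 847.09 USD/ha, leaving all comparisons
  and break-evens unchanged. Early-season scouting (2 visits) is classified
  fixed; monitoring and efficacy scouting are variable.
- **Product choice.** Wild-type (-W) spray scenarios are costed at the
  all-products mean (22.88 USD/ha); resistant-pest (-I) scenarios start with
  the cheapest class, a pyrethroid (13.83), with an organophosphate rescue
  (21.98). This convention simultaneously reproduces the 29% outbreak
  threshold and the 48%/57% resistance thresholds. Sulfoxaflor (4C, 61.78)
  is configured but never auto-selected, since cross-resistance is outside
  the eight-scenario set.
- A prophylactic spray tank-mixed with a fungicide pass is still costed at
  the full 20.02 application rate (no cost-sharing rule is available).
- All money is 2018 USD; single-season snapshot, no discounting.

## Solvers

Break-even probabilities are roots of the affine difference
E(R)_a(x) − E(R)_b(x), computed from evaluations at x = 0 and x = 1. A
crossing outside [0, 1], or parallel lines, returns "none" with a
diagnostic. Closed-form crossings are cross-checked against Brent bisection
roots (tolerance 10⁻⁹, 500 randomized cost/price/yield configurations) in
the test suite. Reported percentages round half-up to the nearest integer
percent, via decimal arithmetic to avoid binary-float artefacts at ties.
Probability sweeps default to 0.1 increments (configurable); thresholds are
never read off grids.

Sensitivity presets modify exactly one factor: yield low/high (3026/4035
kg/ha), price average/high (0.40/0.52 USD/kg), a hypothetical technology
fee on aphid-resistant seed (the S.H − S.C premium, 37.48 USD/ha, added to
R.C), and a uniform 12% reduction of every input cost.

## Empirical estimators and the synthetic fixture

Outbreak frequency is the unweighted share of trial site-years flagged as
outbreaks; per-site-year yield loss is 100 − (U/H)·100 with U the untreated
control and H the best insecticide treatment. Negative losses (U > H) are
reported, not clipped. The mean outbreak-year loss uses outbreak site-years
only by default (an all-records option exists), and q = 1 − mean/100.

The original trial records are not deposited, so the package includes a
synthetic generator for testing: Bernoulli outbreak flags; outbreak-year
losses from a normal truncated to [0, 60] percent whose location is solved
so the truncated mean equals the requested loss mean (default 12.7%, SD 8
percentage points — a spread typical of efficacy trials); treated yield
normal(3537, 300) kg/ha floored at 500; non-outbreak losses are N(0, 0.5)
noise. The generator reproduces summary statistics (rates, means), not the
spatial/temporal correlation, treatment structure or heteroscedasticity of
real trial networks — passing round-trip tests shows the estimators are
correct, not that real trials look like the fixture. Case-study constants
(q = 0.873, p_o = 0.435) always come from the configuration, never from the
fixture.

## Numerical choices

- Probability blocks must sum to 1 within 10⁻¹²; violations raise errors
  naming the block.
- Scenario ranking breaks E(R) ties by lower E(C), then lexicographic code
  (stable mergesort).
- Slopes below 10⁻¹² USD/ha are treated as parallel in the break-even
  solver.
- CSV record output uses `%.17g` and round-trip float parsing so that
  save/load is bit-exact.

## Known limitations

- Only expectations are computed; risk attitudes (variance, downside risk)
  are out of scope.
- Seed-applied insecticides, aphid resurgence after sprays, and multi-year
  resistance evolution are not modelled.
- The resistant-variety net revenue computed from the itemized tables
  (937.04 USD/ha) differs by ≈0.3% from the published headline value; the
  residual traces to rounding in the source's yield/price/seed means, and
  the seed-mean choice is exposed in the configuration.
- The cost structure implied by the published thresholds involving the
  rescue scenario (SHPE-I) against other scenarios cannot be reconstructed
  from per-item cost tables (the implied second-application cost is far
  above the component sum 21.98 + 20.02 + 10.50 = 52.50 USD/ha). The
  package uses the component sum and documents the discrepancy rather than
  calibrating to the printed thresholds; notably, with this convention the
  SHPE-I vs SHXN-I crossing at baseline price falls at 0.88, suggesting the
  published ">88%" figure may compare the rescue scenario against no
  management rather than against the single application.
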