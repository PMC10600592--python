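# Methods

## Model structure and assumptions

The projection is a discrete-state cohort model with annual cycles. Each
calendar year is computed independently: the year's diagnosed diabetic
population is split into major-amputation, minor-amputation and
no-amputation states by annual incidence rates, and two all-cause death
streams are read off the amputee and non-amputee compartments. Nothing is
carried between years — there is no persistent amputee stock, no
re-amputation, no diabetic-foot-ulcer intermediate state, and amputees are
not removed from the next year's at-risk pool. These are deliberate
simplifications: the model targets settings where only a base-year case
count and a handful of literature transition rates are available, and the
externally supplied case series is assumed to already account for attrition
of the diabetic population (the growth anchors come from national
projections that incorporate mortality). A consequence worth keeping in
mind is that "deaths among amputees" means deaths among the *year's
incident* amputees, not among a cumulative amputee population, so it
understates the steady-state figure.

The model is linear in population size (homogeneity) and conserves the
population exactly within each year (major + minor + non-amputees = cases).
Both properties are enforced by construction and re-checked as property
tests.

## Parameters

| Parameter | Units | Shipped default | Notes |
|---|---|---|---|
| base_count | diabetics | 54,805 (2022) | diagnosed cases aged ≥20 in the example region |
| growth anchors | % ratio end/start | 131.7 (2022–2030), 133.9 (2030–2045) | national projection ratios; interpreted as end = start × pct/100 |
| incidence_major | per 100,000/yr | 94.82 | pooled literature estimate |
| incidence_minor | per 100,000/yr | 139.97 | pooled literature estimate |
| mortality_amputee | per 1,000 py | 86.8 | applied to the year's incident amputees |
| mortality_nonamputee | per 1,000 py | 23.81 | applied to the remainder |
| uncertainty_fraction | — | 0.20 | extremes half-width |

## Case-series interpolation

Anchor end-point values are the *unrounded* chained products of the growth
factors (54,805 × 1.317 × 1.339 = 96,646.59 → displayed 96,647); rounding
the 2030 anchor before chaining would end the series one unit low.
Interpolation between anchors is linear in absolute counts, not log-linear —
the convention the source projections use, and the one that reproduces the
reference intermediate years exactly.

## Decline schedules

A schedule has an initial multiplier applied at the base year, a period
length, and a per-period survival factor. Three compounding modes are
provided:

- **annualized** (default): geometric, `m0·f^((y−y0)/p)`;
- **stepwise**: drops only at whole periods, `m0·f^floor((y−y0)/p)`;
- **interpolated**: linear between the whole-period values — the form a
  spreadsheet produces when intermediate years are filled by straight-line
  interpolation between period knots.

All three coincide at whole-period years. The shipped `mixed-decline`
scenario (initial multiplier 0.8 at the base year, per-3-year factors 0.8
for major and 0.9 for minor, interpolated mode) is the schedule that
reproduces every cell of the published declining-incidence reference table,
including its off-period years and extremes bounds; `mixed-decline-annualized`
is the same schedule with geometric compounding (it differs from the
reference table in a single uncertainty bound, the 2030 total's upper
limit); `uniform-decline` applies a 20% per-3-year decline to *both* incidence
rates, the narrative reading of the scenario. The two readings coincide at
the base year, so base-year outputs are identical across all three. The
package takes no position on which schedule is "right" — schedules are pure
configuration — but the table-consistent one is used wherever reference
values are asserted.

## Rounding and uncertainty

A single display rule is used everywhere: round half up (ties at .5 go
upward), on otherwise unrounded arithmetic. Extremes bounds are
`round((1 ± fraction) · unrounded value)` — computed on outputs, not by
perturbing each input rate. The output-space reading is the one consistent
with the reference tables (128.68 × 1.2 = 154.4 → 154, whereas rounding
first would give 129 × 1.2 = 154.8 → 155); a parameter-perturbation
envelope mode is provided as a clearly non-default alternative
(`parameter_extremes_bounds`). One further display convention is
reverse-engineered from the reference tables: the displayed amputation
*total* is the sum of the rounded major and minor counts rather than the
rounded unrounded sum (the two differ only once across both reference
tables, at the declining scenario's final year: 13 + 48 = 61 vs
round(61.5…) = 62); uncertainty bounds for the total are still computed
from the unrounded sum.

## Validation

Validation is a single-year comparison of the projected amputation total
against observed facility counts, reporting the signed difference and
inclusive interval containment. Only totals are compared (facility
major/minor splits are typically incomplete), and no correction is applied
for facilities missing from the observed total, so the observed count is
best read as a lower bound on the true one.

## Synthetic data

The generator emulates the structure the pipeline consumes: uniform draws of
the four transition rates within invariant-respecting ranges, contiguous
growth anchors with growth ≥100% over 5–15-year spans and base counts of
20,000–120,000 (the scale of a mid-size region's diabetic population), and
observed counts drawn Poisson around the unrounded projected total scaled by
a reporting-completeness fraction, split across facilities multinomially.
Poisson observation is the minimal canonical noise model for rare-event
counts in a large population; the deterministic projection itself has no
stochastic layer. What the synthetic layer does *not* emulate: age/sex
structure, time-correlated reporting gaps, facility-level heterogeneity in
case mix, or any feedback from amputations onto the case series — so
passing tests demonstrate arithmetic and plumbing correctness, not
epidemiological realism of the defaults. All randomness flows from one
explicit seed through a `numpy` generator.

## Numerical choices and degenerate inputs

- All internal arithmetic is double precision and unrounded; integers
  appear only in display views and CSV output.
- Zero population, zero incidence, zero uncertainty fraction and empty
  projection series are all valid and produce the obvious degenerate
  outputs (all-zero rows, degenerate intervals, header-only tables).
- Invariants are enforced at construction time (frozen dataclasses), with
  configuration errors naming the offending key.
- Problem sizes are desk-scale throughout: a full run is 24 years of closed
  -form arithmetic, and the heaviest tests are the 10,000-draw Monte-Carlo
  mean check and a 1,000-draw invariant sweep, chosen to make sampling
  error negligible relative to the asserted tolerances.

## Known limitations

The model inherits the limits of its inputs: a single base-year count, two
growth anchors, and four literature rates. It cannot express age/sex
gradients, incidence trends other than multiplicative schedules, or
cumulative amputee survivorship. The extremes intervals are scenario
bookkeeping, not statistical confidence intervals.
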