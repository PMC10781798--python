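# Methods

## Problem and scope

Most solid oral dosage forms (SODF — tablets and capsules) reach patients
in push-through blister cards: laminate sheets of aluminum and/or plastic
carrying one formed chamber (alveolus) per dose. The laminates are
composite materials with essentially no recycling route, so the card area
is, one-for-one, waste. `blistercalc` models three linked questions:

1. **Geometry** — given a measured card (length *i*, width 2*b*, *n*
   chambers of base diameter *d* or base *e* × *f*), how is its area
   apportioned between chambers and inter-chamber/seal space?
2. **Layout** — how small could the card be if the same chambers were
   re-arranged on a rectangular grid with the technical minimum seal
   margin, and how much material would that save?
3. **Extrapolation** — given national dispensing volumes in defined daily
   doses (DDD), what do the per-card figures imply in annual tonnes,
   compacted cubic metres, freight-train metres and per-capita square
   metres of packaging waste?

## The layout model

Chambers sit on an r × c grid with a uniform seal distance *k* between
neighbours and to every card edge. A round-chamber card then measures

    area(r, c, d, k) = (r·d + (r+1)·k) × (c·d + (c+1)·k)

with *d* replaced by *f* across rows and *e* along rows for elongated
chambers. The two-row arrangement used for the headline savings figures is
the r = 2 special case,

    (2d + 3k) × (k + n/2 · (k + d)),

which is also evaluated literally for odd *n* (fractional columns); the
general grid form requires *r* to divide *n* and flags other row counts
infeasible. No staggered/hexagonal packing, chamber rotation or depth
(volume) optimization is attempted — the model is deliberately the same
rectangular-grid idealization a blistering line realizes.

Structural consequences, each property-tested against an independent
oracle (brute-force factor-pair enumeration up to n = 60; randomized
monotonicity probes):

- area is strictly increasing in *k*, in every chamber dimension, and in
  rows/columns at fixed counts;
- for fixed *n* and *k* > 0 the squarest factor pair minimizes area;
- on the 24-chamber reference configuration the inter-chamber/seal area
  overtakes the total chamber base area from k = 3 mm.

**Seal margins.** Cold-formed aluminum-aluminum laminates cannot be bent
at 90° and need a wider weld: the default policy is 4 mm for
aluminum-aluminum and 2 mm for every thermoformed (plastic-containing)
laminate, overridable per material. Unknown materials get the conservative
4 mm with a logged warning.

**Calibrated mean chamber diameter.** The published 24-chamber
arrangement table never prints the mean round-chamber diameter it used.
A grid search over d ∈ [10, 12] mm in 0.01 mm steps, minimizing the
maximum deviation across all 16 printed cells, lands on d = 11.0 mm with a
maximum deviation of 0.05 cm² (pure printing rounding); the test suite
re-derives this before asserting any cell. `MEAN_ROUND_ALVEOLUS_D_MM`
carries that value.

**Savings convention.** The marketed card area is 100%; savings are
computed per product and then averaged (mean of ratios). The published
cohort mean (37%) is *not* the ratio of the printed mean areas
(33.4/52.1 → 35.9%), which is why the mean-of-ratios reading was adopted.
Cohort-level savings percentages for the real 45-product cohort require
the per-product supplementary measurements, which have no machine-readable
form; they are therefore exercised on synthetic cohorts only and pinned by
the structural properties above instead of by the printed means.

## The waste chain

Per product: `DDD × (WHO DDD mg) / (strength mg)` gives dosage forms per
year — the multiplication by the WHO reference dose makes the published
"divide DDD by strength" rule dimensionally consistent and reduces to it
when the reference dose equals the strength. Dividing by package size
gives fractional package equivalents; dividing by the per-card count gives
fractional cards; cards × gross card weight gives tonnes. Counts are never
rounded up: the published train lengths (770/851 m) only reproduce with
fractional wagons, and package "equivalents" are explicitly fractional.

Derived quantities use fixed market constants (all overridable):
laminate density 1.4 t/m³ (polyvinyl chloride, maximum compaction),
70 t / 15.4 m freight wagons, ×1.105 private-insurance uplift (10.5%
privately insured), population 83.2 million. The footprint area of a card
is *i* × (rows × *b*), which equals the face area 2*b*·*i* for the usual
two-row card. Whole-market extrapolation is a rule of three over DDD
totals restricted to ledger entries flagged `include_in_market` (the
exclusion of mainly-topical/parenteral groups is a flag, not an ATC
engine, because no machine-readable group list exists).

## Per-card metrics and reporting conventions

Internal units are mm/mm²/g; cm², km², t appear only at function and
report boundaries. Tare (packaging) weight is always derived as
gross − n × SODF mass, never measured. SODF volume, whose measurement
method is undocumented in the source, uses a cylinder for round forms and
an elliptic cylinder (π/4 · l · w · h) for elongated forms and capsules;
it is advisory and excluded from all quantitative anchors.

Two aggregation ambiguities in the source are documented rather than
resolved: the printed cohort mean tare of 43.6% is not reproducible from
the printed class means (which imply ≈73%), and the printed
chamber-to-form area ratios (4.3× aluminum-aluminum, 1.7× mixed) are
means of per-product ratios, not ratios of the printed mean areas (which
give 4.09 and 1.54). This package computes per-product values and averages
them.

"Total blister card area" in the class summaries is the per-*package*
total (cards per pack × 2b·i): the printed 373 cm² equals the printed
per-card class means times cards per pack, and 373/97.6 reproduces the
printed 3.92 cm² per dosage form, whereas a per-card reading is
inconsistent with 16 forms per card.

Classes with n ≤ 2 members (the capsules) are reported as individual
values, never as mean ± SD. Spearman correlations use mid-ranks for ties;
the two-sided p value is an exact full enumeration for n ≤ 9 and the
t-approximation with n − 2 degrees of freedom otherwise.

## The synthetic cohort generator

The generator emulates the published cohort's composition (27 round / 16
elongated / 2 capsules; 13 aluminum-aluminum, 1 pure plastic, rest
aluminum-plastic) and its per-class distributions. Directly sampled
metrics — strength, package size, forms per card, per-package blister
area, chamber area fraction, form mass and height, within-row gap *h*,
laminate areal density, chamber-to-form area ratio per material class —
follow truncated normals with the published mean ± SD and range as
defaults. The truncnorm location is calibrated (Brent root-finding on the
analytic truncated mean) so the truncated mean equals the configured mean
exactly; SDs are parent-scale, so empirical SDs are compared to the
analytic truncated SD (truncation shrinks variance, drastically so for the
heavily skewed strength distributions).

Everything else is derived, never sampled, so records are internally
consistent by construction: chamber area = fraction × card area / n;
form footprint = chamber area / ratio (ratio ≥ 1.05 keeps the form inside
the chamber); card sides from a feasible row layout (2 rows when *n* is
even, else 3 when divisible, else 1) with the sampled within-row gap,
shrinking the gap towards its observed 2 mm floor and, as a last resort,
inflating the card 5% over the minimal layout when the sampled area is
infeasibly tight; gross weight = areal density × face area + n × form
mass. Lengths are quantized to 0.1 mm and masses to 1 mg, mimicking the
instruments. The two capsules are emitted deterministically from their
individually published values. The implied row gap *g* is derived and can
exceed the observed 54 mm maximum on extreme draws; it is floored at *h*
so the gap-ordering invariant always holds.

Defaults not fixed by the published tables, chosen once: within-row gap
SD 1.5 mm (only mean and range are printed), areal density
0.18 ± 0.05 g/cm² (anchors mean gross weights near the printed 13–16 g),
chamber aspect ratio 2.0 ± 0.3 for elongated chambers, DDD ledger
log-normal with mean 2 × 10⁸ DDD/product/yr and σ_log = 1 (same order as
the published national masses under the identity WHO-DDD = strength
convention).

A single integer seed drives named substreams (one per metric), so adding
a metric does not perturb the draws of the others and cohorts are
byte-reproducible.

What the generator does **not** emulate: real inter-metric correlations
(beyond construction-order dependence), brand-level values, empty blister
fields (c′ compartments), and the material–chamber-size association
(aluminum-aluminum chambers being systematically larger). Passing tests
therefore demonstrate correctness of the *pipeline* under realistic
marginals, not recovery of any real brand's measurements.

## Problem sizes and numerical choices

Tests run the 45-product study-condition cohort for pipeline checks and
an n = 1000 cohort for parameter recovery (means within 3 standard errors
of the configured means; empirical SDs within 15% of the analytic
truncated SDs). The layout identity between the two-row closed form and
the grid form is checked on 1000 random (d, k, even n) triples at 1e-9
relative tolerance. The circle area agrees with a chord-length numerical
integral to 1e-9. All report rounding (areas 0.1 cm², percentages
integer, masses integer t, waste areas 0.1 km², per-capita 0.01 m², train
integer m) happens in the report layer only.

## Known limitations

- Rounded card corners are ignored (punching sends the corner remnants to
  waste regardless).
- No uncertainty intervals: the chain propagates point estimates, as the
  source does.
- The whole-market scaling factor (market DDD total) is an input, not a
  computed quantity.
- The generator's feasibility adjustments (gap shrinking, rare 5% card
  inflation) bias the sampled card-area and fraction means by well under
  one standard error at n = 1000, but they are biases, not noise.
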