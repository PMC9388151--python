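# Methods

This note documents the models, defaults and numerical choices behind
`foodprint`, and what the synthetic test bed does and does not show.

## Composition inference

A product's ingredient list induces the constraint polytope
`{p ≥ 0, Σp = 100, p₁ ≥ p₂ ≥ … ≥ pₙ, p_i = d_i for declared i}`.  Two
label-law exceptions are honored:

* **≤ 2% any-order rule.**  Monotonicity is not enforced between two
  ingredients whose current estimates are both at or below 2%.  At the
  bounds stage (which runs before any estimate exists) the exception is
  applied only to pairs of *declared* values; during projection it is
  applied dynamically.  Without this exception, legally valid labels would
  be reported as infeasible.
* **QUID values above 100.**  When declared values sum above 100 (dried or
  concentrated ingredients), all declared values are rescaled by
  100/Σd and the ratio is stored per ingredient as a raw-equivalent factor,
  preserving raw-commodity mass for impact accounting.  Declared pairs that
  themselves violate the ordering are kept verbatim (labels are ground
  truth) and logged as relaxation notes.

**Bounds.**  Exact per-ingredient intervals over the polytope are obtained
from 2n small linear programs (HiGHS).  An empty polytope raises an error
that names the violated constraint class (e.g. "undeclared ingredients can
absorb at most X% under the ordering constraint").  The test suite checks
the LP bounds against an independent brute-force enumeration of the polytope
on a 0.1 percentage-point grid.

**Priors.**  Declared percentages observed in the corpus are pooled into
cells keyed by (food category, rank bucket), rank buckets `1, 2, 3, 4, 5+`
(long tails are sparse, so ranks ≥ 5 share a bucket).  The cell statistic is
the **median** — robust to the strong right skew of declared percentages.
Unknowns initialize from the most specific non-empty sample: cell → category
marginal → rank-bucket marginal → midpoint of the ingredient's feasible
interval.

**Projection.**  The unknown sub-vector is iterated through (a) rescaling
onto the remaining mass `100 − Σd`, (b) a pool-adjacent-violators pass that
respects fixed entries (free runs are pooled, then clamped to their fixed
neighbours) and the 2% exception, and (c) clipping to the per-ingredient
bounds — until the composition changes by less than `1e-6` percentage
points, with a 100-iteration cap.  Any residual mass after convergence is
distributed across free entries proportionally to their remaining slack
toward the active bound, which keeps the box constraints intact.  Inference
is fully deterministic (no RNG).  The scheme is a heuristic cyclic
projection, not an exact Euclidean projection onto the polytope; the
property tests assert what actually matters downstream — feasibility, mass
balance and order consistency — over randomized products.

**Coverage gate.**  Products are presented only when at least 75%
(inclusive) of estimated mass maps to a food category; the threshold is
configurable.

## Impact propagation

Intensities are per kg of raw commodity; the per-100 g functional unit
contributes the fixed factor 0.1 kg.  Per Monte-Carlo iteration and mapped
ingredient, one production observation is drawn with probability
proportional to its production-share weight (uniform if all weights are 0).
Organic ingredients are restricted to the organic subset of their category
only when it holds ≥ 5 observations, otherwise they draw from all systems.
Fish categories first pick aquaculture vs capture with probability 0.5 each
and then draw within that system; if one system is absent the draw falls
back to the whole pool.  Unmapped ingredients contribute zero (they are
already accounted for by the coverage gate).  Post-retail processing,
packaging and transport are outside the system boundary.

Mean, SD (ddof = 1) and the 5/10/25/50/75/90/95th percentiles are computed
from the same draw matrix.  Default `n_iter` is 1000; the MC mean converges
to the analytic weighted expectation at the usual `1/√n` rate (tested).
All sampling flows from one `numpy` `SeedSequence`, so runs are
bit-reproducible given a seed.

## Composite index

Per indicator: `scaled = 100·x/max(x over corpus)`; the composite is
`100·mean(scaled)/max(mean(scaled))`.  The index is linear (a score of 50 is
half the impact of the top product), equal-weighted, scale-free per
indicator, and order-preserving.  It is corpus-relative by construction:
scores are only comparable within one reference, so the scaling constants
("reference maxima") are saved with results and can be reused to score new
products on a frozen scale.  An indicator that is zero across the whole
corpus contributes a zero component, with a warning.

## NutriScore

The 2017 Santé publique France / FSA tables ship as an editable YAML
resource; all point logic reads from it, so future table revisions can be
swapped in.  Band edges are applied with a uniform strictly-greater
convention.  Beverages use their own energy/sugar/fvno ladders and letter
cut-points; because the beverage fvno component reaches 10 points, beverage
totals extend to −20 and the 0–100 scale (`100·(total+15)/55`) is clipped
at 0.  Plain water's special-case letter A is not modeled — the `beverage`
variant returns B as its best class.  The added-fat variant requires total
fat on the panel (saturated/total ratio); it is an error to omit it rather
than a silent fallback.  The protein cap (penalties ≥ 11 and fvno below its
exemption level suppress protein points; cheese exempt) follows the
published rule.  Alcoholic products are rejected: NutriScore does not
account for alcohol.  The 2017 tables are the default because they were the
ones in force for 2019-era retail data; swap the YAML to explore revisions.

## Validation harness

Validation products must have more than one ingredient, all or all-but-one
declared percentages, and a declared sum of 100 (the missing ingredient is
filled with the residual).  Masking trials hide a seeded random choice of up
to `max_combos` (default 100) unique combinations of n declared values,
keeping the list order; `n` ranges from 2 to all ingredients, with `n = 0`
allowed as a control.  Known and estimated scores of one product share a
per-product Monte-Carlo seed, making the no-masking identity exact.
Accuracy is reported as `log2(estimated/known)` and as the percent
difference `(estimated − known)/known`; trials with a known score of 0 are
excluded with a warning.  Prior tables are built from the full corpus,
including the validated products' own declared values — a small optimism
that mirrors how priors would be built in production, where the product
being scored is part of the assortment.

Aisle profiles average the composite score and the numeric (1–5) nutrition
score per retail Aisle (products in several Aisles count in each), with SEM
where an Aisle has ≥ 2 products, and report the Spearman correlation across
Aisle means.

## Synthetic test bed

The generator emulates the study conditions: ~111 categories (including
zero-impact water and salt) with ≥ 5 lognormal, right-skewed observations
each (spread σ_log = 0.8) and gamma production-share weights; ground-truth
compositions drawn from a symmetric Dirichlet (α = 1, i.e. uniform on the
simplex before sorting) and sorted descending; declared percentages revealed
at rate 0.104 with a 3× bias toward rank 1 (the characterizing-ingredient
convention); ~12% drinks (water-dominated); an unmappable additive as the
least-abundant ingredient of a quarter of larger products; nutrition panels
composed from fixed per-kind nutrient profiles so classes A–E all occur.
Category median intensities are hand-set to plausible per-kg magnitudes
(beef ≫ pork ≫ grains ≫ vegetables; almonds water-intensive, etc.).

What the synthetic corpus does **not** emulate: real brand/recipe
correlation structure, multi-retailer taxonomies, compound-ingredient
nesting depth, country-of-origin sourcing, seasonal assortment, or the
empirical intensity distributions of the public farm-level databases
(HESTIA, the Blue Food Assessment) that a production deployment would plug
in.  Passing tests
therefore demonstrate algorithmic correctness and the qualitative accuracy
trends (error shrinking as more composition is known; flat in ingredient
count), not the headline accuracy fractions of any real retail corpus —
those depend on licensed data and are intentionally not targets here.

Test and demo problem sizes (e.g. 60–200 products, 100–10,000 MC
iterations, ≤ 4-ingredient products for the brute-force cross-checks) were
chosen so every check runs in seconds on a laptop while leaving the
statistical assertions well-powered.

## Known limitations

* The inference projection is heuristic; pathological declared patterns can
  hit the iteration cap (logged as a note) before reaching the fixed point.
* "Similar products" for priors means (category, rank bucket) — no brand,
  retailer or recipe-type conditioning.
* Compound ingredients are flattened: the parent name is mapped and
  sub-ingredients are consulted only when the parent is unmapped.
* Water added during processing is never imputed beyond the listed
  ingredients.
* The composite index is corpus-relative; cross-corpus comparison requires
  sharing reference maxima.
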