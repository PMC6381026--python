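# Methods

## Effect sizes

A dataset is n ≥ 2 finite pairs (xᵢ, yᵢ).  All areas are measured inside
the **scope** rectangle, by default the observed bounding box
[min x, max x] × [min y, max y]; a *theoretical* scope (e.g. the known
limits of a rating scale) may be supplied and must enclose the data.  A
zero-width or zero-height scope (all x equal, or all y equal) is an error:
the empty-corner fraction is undefined there.

The **CE-FDH ceiling** is the running maximum Mₖ of y over ascending
distinct x; the **floor** is the running minimum mₖ scanned from the right.
The ceiling is *left-anchored* (column [x₍ₖ₎, x₍ₖ₊₁₎) has level Mₖ) and the
floor *right-anchored* (column (x₍ₖ₋₁₎, x₍ₖ₎] has level mₖ).  This pairing
is the unique one under which a 180° rotation of the scatter maps the floor
onto the ceiling and swaps the two effects exactly — a property the test
suite checks both symbolically (closed forms) and on random data.  Multiple
points at one x collapse to their max (ceiling) or min (floor) before the
scan; only extrema matter, so ties are irrelevant.

Under a theoretical scope wider than the data, the first and last frontier
levels extend horizontally to the scope edges (continuity of the step).
One consequence, found by the property tests and worth knowing: adding a
point *within* the current x-range can never increase the necessity effect
(it can only raise the ceiling), but a point that *extends* the x-range
leftwards with a low y lowers the extended edge strip and can legitimately
increase it.  Effects are exact ratios of rectangle areas accumulated
left-to-right; they are reported at full precision and rounded half-up to
3 decimals only for display.

Benchmark labels use half-open intervals with inclusive lower bounds:
small < 0.1 ≤ medium < 0.3 ≤ large < 0.5 ≤ very large.

## Permutation test

Y is reshuffled without replacement; X, and hence the scope (y min/max are
permutation-invariant), stay fixed, so the scope is computed once.  The
p-value is the plain proportion of reshuffled effects ≥ the observed effect
(comparison tolerance 1e−12 to absorb float noise in area sums).  The
observed arrangement is *not* added to numerator and denominator — the
worked example's p = 4/10 fixes this convention — but a conservative
(b+1)/(m+1) mode is available (`plus_one=True`).  Random reshuffles are
drawn independently (repeats possible), the standard Monte-Carlo practice;
the default count is 1000.  An exhaustive oracle enumerates all n!
orderings (guarded at n ≤ 8) and anchors the Monte-Carlo test in the suite.

The `permutable_fraction` diagnostic reports the share of points strictly
above the ceiling's first step: only these can be reshuffled into the empty
corner and weaken the observed effect.  A strong floor concentrates y-mass
high and inflates this fraction — the mechanism behind the type-I inflation
under sufficiency.

Without the plus-one correction the test is mildly anti-conservative at
finite permutation counts; under the null envelope the measured rejection
rate at α = 0.05 with 200 reshuffles sits around 5–7%, within two binomial
standard errors of nominal at 400 replicates.

## Population simulator

The simulator emulates a stylized survey population: a discrete 9-level
predictor, uniform; a continuous outcome, uniform between envelope limits
U(x) = min(u + x − 1, 9) and L(x) = max(l − (9 − x), 1) with u, l ∈ 1..9.
True effects are closed forms: N(u) = Σ₁⁸ (9 − U(x))/64 and
S(l) = Σ₂⁹ (L(x) − 1)/64, each taking the nine values 0 … 0.5625 and
related by S(l) = N(10 − l).  Samples are balanced (exactly n_per_x
subjects per level; N = 9·n_per_x, with the study's range 18–495 mapping to
n_per_x 2–55) and clipped into the envelope to guard float rounding; the
degenerate pair u = 1, l = 9 (the line Y = X) is allowed and remains
analyzable.  The Y-distribution is a pluggable hook (`y_sampler`); only
uniform is implemented and tested.

What this generator does *not* emulate: skewed or heavy-tailed marginals,
unbalanced X designs, measurement error, or dependence between subjects.
Passing tests therefore certify the test's operating characteristics under
clean uniform envelopes, not under real survey data.

## Simulation study

Three experiment sets, mirroring the questions "power without sufficiency",
"sufficiency at small N", "type-I error without necessity":

| set | fixed                | varying             | default replicates |
|-----|----------------------|---------------------|--------------------|
| 1   | l = 1 (S = 0)        | u, n_per_x          | 2000               |
| 2   | n_per_x = 5 (N = 45) | u, l                | 2000               |
| 3   | u = 9 (N = 0)        | l, n_per_x          | 500                |

Varying parameters are drawn independently and uniformly over their grids
(u, l ∈ 1..9; n_per_x ∈ 2..55) — a design choice, since a canonical
assignment rule is not fixed by the study design.  Each replicate samples a
population, runs the permutation test (default 1000 reshuffles) and flags
p < α (α = 0.05).  Seeding: the master seed spawns one `SeedSequence` child
per replicate plus one parameter stream; each child collapses to a 31-bit
integer stored in the record, so any single record is reproducible in
isolation.  An experiment set is byte-identical across reruns of the same
master seed.

Significance is then modelled by maximum-likelihood logistic regression on
any subset of {true necessity, true sufficiency, √N}; √N uses the *total*
sample size 9·n_per_x.  On (quasi-)complete separation the fit falls back
to a lightly L2-penalized GLM (`alpha = 1e−3`) with a `SeparationWarning`;
penalized fits report no standard errors.  Predicted power is the
inverse-logit of the fitted linear predictor.  Rejection-rate summaries use
Wilson score intervals; continuous grouping variables can be binned into
quantile groups (the study's reporting uses terciles, with edges logged).

Scaled profiles: the test suite and the acceptance script run 300–500
replicates of 200 reshuffles per experiment — sizes chosen so that every
directional conclusion (power near 1 for effects ≥ 0.094 at n_per_x ≥ 15,
type-I control at ≤ 5% + 2 SE without sufficiency, strictly increasing
type-I error across l = 1, 5, 9, and a √N coefficient indistinguishable
from zero at the 1% level) is resolved well beyond its sampling noise; the
full 2000 × 1000 designs are available through `ExperimentConfig.for_set`
defaults.

## Known limitations

- Only the step-function (CE-FDH) frontier is implemented; regression-based
  ceilings, multi-predictor analyses and bottleneck tables are out of scope.
- Only the necessity effect is significance-tested (the sufficiency effect
  is a simulation input, not a tested estimand).
- The logistic power surfaces are reproducible in shape and sign, not as
  specific coefficient values: they depend on the replicate draw.
- The CE-FDH estimate is biased upward in small samples (the empty corner
  can only shrink as points accrue under a fixed scope), visible in the
  simulator's convergence behaviour.
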