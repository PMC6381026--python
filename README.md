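# ncaperm

Necessary Condition Analysis (NCA) effect sizes with permutation
significance testing, plus a simulation laboratory for measuring the
test's power and type-I error.

## Who this is for

NCA is used in psychology, management and epidemiology to ask whether a
minimum level of a predictor *X* is *necessary* for a high level of an
outcome *Y* — e.g. whether a certain degree of self-rated depression is
necessary for a high level of suicidal ideation.  The evidence is an empty
upper-left corner in the X–Y scatter: no cases combine low X with high Y.
`ncaperm` is for researchers who want to (a) compute these effect sizes,
(b) attach a permutation p-value, and (c) understand — by simulation from
populations with *known* true effects — when that p-value can and cannot be
trusted.  The headline finding the simulation machinery reproduces: the
test has very high power, but its type-I error rate is inflated by the
*sufficiency* of X (an empty lower-right corner), which is paradoxical for
a method meant to find necessary-but-not-sufficient conditions.

## The method

The default ceiling technique, **CE-FDH** (Ceiling Envelopment – Free
Disposal Hull), is the non-decreasing step function through the *ceiling
points* — points whose Y exceeds the Y of every point with smaller X.  With
distinct x-values x₍₁₎ < … < x₍ₘ₎ and running maxima
Mₖ = max{yᵢ : xᵢ ≤ x₍ₖ₎}, the necessity effect is

    d = Σₖ (x₍ₖ₊₁₎ − x₍ₖ₎)(y_max − Mₖ) / ((x_max − x_min)(y_max − y_min))

the fraction of the scope rectangle left empty above the ceiling
(d < 0.1 small, 0.1–0.3 medium, 0.3–0.5 large, ≥ 0.5 very large).  The
mirror quantity below the floor step (running minima scanned from the
right) is the sufficiency effect.  Significance is assessed by reshuffling
Y without replacement, recomputing d each time, and reporting
p = #{d_perm ≥ d_obs} / #reshuffles.

The simulator draws populations on the [1,9]×[1,9] square bounded by an
upper limit U(x) = min(u + x − 1, 9) and lower limit
L(x) = max(l − (9 − x), 1): X is uniform on the integers 1..9 and Y | X=x is
uniform on [L(x), U(x)].  The true effects are then closed forms of u and l
(e.g. u = 3 gives 21/64 = 0.328; l = 5 gives 10/64 = 0.156), so power and
type-I error can be measured exactly against the truth.

## Worked example

```python
import numpy as np
from ncaperm import (load_worked_example, necessity_effect,
                     permutation_test, pvalue_from_reshuffles)

observed, reshuffles = load_worked_example()   # 12 points, X on 1..3
print(necessity_effect(observed))
# necessity effect = 0.167 (medium); empty corner area 3 / scope 18

print(pvalue_from_reshuffles(observed, np.array([r.y for r in reshuffles])))
# necessity effect = 0.167, p = 0.400 (10 permutations)

print(permutation_test(observed, n_permutations=1000, seed=42))
# necessity effect = 0.167, p = 0.654 (1000 permutations)
```

Three of the 18 unit cells of the scope rectangle are empty above the
ceiling, a medium-sized necessity effect; but 40% of the ten given
reshuffles (65% of 1000 random ones) reach an effect at least that large,
so the effect is far from significant in this small sample.

The `examples/` directory holds one short script per capability (effect
sizes, significance testing, population simulation, the power study), and
the same operations are available from a shell:

```sh
nca effect --input data.csv
nca test --input data.csv --permutations 1000 --seed 42
nca simulate --u 3 --l 5 --n-per-x 50 --seed 1 --out sample.csv
nca study --set 3 --replicates 500 --out records.csv
nca power --records records.csv --predictors true_sufficiency,sqrt_N
```

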