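# Methods

## Model

The package treats the choice among *m* treatments as a discrete
multicriteria optimization. The feasible set is the one-hot assignment
vectors x ∈ {0,1}^m, Σx = 1 (each patient follows exactly one protocol).
Every criterion is linear in x, with coefficients that are normalized
subgroup summary scores; with a canonical 3-age-group × 2-phototype grid
the ten criterion families yield 60 criteria, indexed
k = base_offset(family) + 2(j−1) + (h−1), a bijection onto 1..60 that the
suite checks exhaustively. The weight method scalarizes the vector
objective into Λ(x) = Σₖ λₖ fₖ(x), with λ constant within each family.
Because the feasible set is finite and tiny, the optimizer enumerates all
m assignments; under strictly positive weights every maximizer is a
max-efficient (Pareto) point, which the package certifies independently
by exhaustive pairwise dominance rather than by appeal to the theorem.

The medicoeconomic index of one treatment is Λ restricted to that
treatment's coefficients. Its interpretable anchor: an inert, cost-free
treatment scores exactly the sum of the ratio-family weights (every
post/pre ratio is 1), so values above that anchor indicate net
improvement after the cost penalty −t_C·C/K.

### Two scoring modes

The source model's general criterion list and its closed-form index
disagree on two families, and the package exposes the disagreement as an
explicit `mode` argument instead of resolving it silently:

* `paper_eq2`: the low-echogenity-pixel family scores pre/post (a
  *decrease* in LEP is the clinical benefit); questionnaire families
  score mark/10.
* `mei_eq5` (default): the LEP family scores post/pre, mirroring the
  closed-form index; the questionnaire families would need pre/post
  marks, which a once-administered questionnaire cannot supply, so they
  fall back to mark/10 with a diagnostic.

The case-study weights set t_L = t_Q = t_S = 0, so both modes reproduce
the same published values. The adverse-effect family keeps the printed
negative sign (−t_R·R) by default even though R counts the *absence* of
adverse effects; `r_as_benefit=True` flips it for users who want the
arguably intended direction. Default is fidelity to the printed model.

### Variants and aggregation

`simplified` (default) sums unweighted cell blocks and is exact for
small or homogenous samples; `weighted` multiplies each cell block —
including the R term — by the cell's population fraction P and requires
P everywhere. The two coincide exactly at P ≡ 1, a property test.
Aggregation follows the input table: cells are whatever strata the table
carries (the case-study age-group values come from cells already
averaged over phototype), and sums run over present cells only — a
treatment with no phototype-3 subjects simply has no such row. Families
with zero weight and missing data contribute nothing; a positively
weighted family with missing data is an error naming the family.

## Parameters

| parameter | meaning | default |
|---|---|---|
| t_E … t_C | criterion-family weights, dimensionless, ≥ 0, hierarchical sum 1 (tolerance 1e-9) | none — caller-supplied |
| K | cost ceiling, monetary units; normalizes cost to C/K | none — caller-supplied |
| mode | criterion scoring convention | `mei_eq5` |
| variant | population weighting | `simplified` |
| r_as_benefit | sign of the adverse-effect term | `False` (as printed) |

Ties in the selection are reported with an explicit flag and broken
deterministically toward the lowest treatment identifier; the source
formulation's implicit preference for the second treatment on ties is an
artifact of variable elimination, not a policy, so it is not copied.

Percent-encoded columns (`no_adverse_pct`, `pop_pct`) are divided by 100
on ingest and stored as fractions; a file may carry the percent or the
fraction column, never both. Age-group and phototype labels are free
strings matched exactly.

## Economic baselines

ICER = Δc/Δe and INB = λ·Δe − Δc are provided for two-treatment
comparisons with caller-defined effect units (an index difference or
QALYs). ICER is undefined at Δe = 0 — the package raises rather than
returning an infinity, since dominance, not a ratio, is the right
assessment there. The identity INB > 0 ⟺ λ > ICER (Δe > 0) is
property-tested away from the break-even point, where floating-point
rounding can flip the two sides independently.

## Synthetic cohorts

The simulator emulates the study design the index was built for: arms ×
(age group, phototype) cells, n patients per cell. Baselines are
log-normal, moment-matched to a given mean and coefficient of variation
(positivity is required by the ratio criteria; no within-cell
dispersions are published for such cohorts, so the default CV = 0.15 is
an explicit, configurable choice). Post-treatment values are baseline ×
multiplicative effect factor × log-normal noise; pixel counts are
rounded to integers at patient level; the LEPs/LEPi ratio is simulated
directly as a parameter, matching its independent appearance in the
summary tables. Adverse events are Bernoulli; questionnaire marks come
from a caller-supplied discrete distribution on 1..10. One root seed
drives a per-arm, per-cell `SeedSequence` split, so output tables are
bitwise reproducible and adding a cell never perturbs other cells.

What the simulator does **not** emulate: longitudinal trajectories,
dropout, correlation between skin parameters within a patient, or
measurement floor/ceiling effects of real ultrasound segmentation.
Passing simulation tests therefore show that the index recovers known
orderings from data matching its own distributional assumptions, not
that those assumptions hold in clinical data.

`ranking_recovery_experiment` measures, over seeded replicates, how
often the index ranks a truly better arm first. The acceptance-level run
uses a 3 × 2 cell grid, 50 patients per cell, 200 replicates: a 30%
effect-factor gap is recovered in ≥ 95% of replicates, and a zero-gap
control stays inside the binomial 99% band around 0.5
(0.5 ± 2.576·√(0.25/200)). Unit tests use smaller grids and replicate
counts to keep the default suite fast; the experiment scales linearly in
both.

## Numerical choices

All sum constraints use absolute tolerance 1e-9 (hand-entered decimal
weights such as 1/8 round-trip text exactly at that level). Table
round-trips are exact to 1e-12. The published case-study values are
compared at the precision their printing supports: recomputing from
printed (rounded) summary means reproduces 6-decimal printed values to
about 1e-6–1e-5, so reproduction is asserted at 1e-5 and the
full-precision recomputations are additionally pinned at 1e-9 as
regression anchors.

## Known limitations

Three published case-study values are not reproducible from the
published summary tables under any implemented formula variant: the
overall treated-arm value 0.812143 (recomputed 0.812726; consistent with
upstream rounding of the aggregated means), the placebo value 0.569481
(recomputed 0.756981; the gap equals a cost term evaluated at C = K
instead of C = 100, suggesting a computational erratum), and the 50–59
age-group value 0.897944 (recomputed 0.782455). The demo's reproduction
report labels these discrepant rather than tuning inputs to force
agreement. The index itself has no sampling distribution attached — no
confidence intervals are defined for it — and weight elicitation is out
of scope: weights are inputs, and any change of weights changes the
index.
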