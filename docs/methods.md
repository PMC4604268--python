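# Methods

## Model and representations

A diagnostic task is a pair (hypothesis space, cue list).  The hypothesis
space carries m ≥ 2 mutually exclusive labels with priors p(H₁)…p(Hₘ)
summing to 1.  Each cue is categorical with ≥ 2 values and a likelihood
distribution p(value | hypothesis, context) where the *context* is either
empty — the cue is conditionally independent of earlier cues given the
hypothesis — or a full assignment of values to all earlier cues.  Cue
order is authoritative and never reordered: contexts may refer only to
earlier cues, and tree layers follow it.  An "unknown/unclear" result is
an ordinary category with its own likelihoods, not missing data.

All probabilities are proportions in [0, 1] internally; percent is
display-only.  This single convention avoids double-scaling bugs when
tasks mix percent and count phrasings.

Posterior computation is done in exact rational arithmetic
(`fractions.Fraction`; float inputs are converted exactly via
`Fraction(float)`), with floats derived at the boundary.  This makes the
central equivalence *exact* rather than approximate: for any task, N and
evidence, the probability-format posterior equals the count ratio
f(evidence & H)/f(evidence) read off the exact-rational frequency tree,
because N cancels term by term.  The property suite asserts rational
equality, not closeness.

Sequential updating (posterior of test 1 becomes the prior for test 2) is
provided as a separate entry point and equals the one-shot multi-cue
posterior; for context-dependent cues the chain resolves each cue's
likelihoods against the evidence accumulated so far.

## Frequency-tree conversion and rounding

`to_frequency_tree` partitions N by the priors, then partitions each node
by the cue's context-resolved likelihoods, layer by layer, **rounding at
each layer from the already-rounded parent count**.  This matches how
frequency versions of textbook tasks are actually constructed (e.g.
9900 × 0.096 = 950.4 → 950, then 950 × 0.04 = 38 exactly) and keeps every
displayed invariant true: children always sum to their parent.

The rounding policy is: round half to even per child, then a
largest-remainder correction so the sibling group sums exactly to the
parent (ties in the correction broken by declared branch order).  A floor
mode and an exact-rational mode (no rounding; used by the oracle suites
and by lossless round trips) are also provided.  When a rounded count
collapses to 0 while its exact expectation is positive, a
`DegenerateCountWarning` is emitted — the chosen N is too small for the
rarest branch.

`tree_to_task` inverts the conversion with likelihoods as exact count
ratios and full contexts (one distribution per path), which is lossless
for dependent and independent trees alike; it refuses zero-count internal
nodes with children, where the conditional is unrecoverable.

## Response scoring

A numeric answer is scored against the exact posterior as *exact* when
within 0.05 percentage points, *rounded* when it equals the exact percent
rounded to the nearest whole point (half away from zero: 7.5 → 8), else
*incorrect*.  The published classification rule names the two accepting
outcomes but no tolerance; 0.05 pp is this package's reading of "the
exact solution" quoted to one decimal, and nearest-whole-percent is its
reading of "rounded to the next full percentage point".  Both constants
are module-level and documented.

## Fast-and-frugal trees

A fast-and-frugal tree over L binary cues has one exit per level and two
at the final level.  Induction (ZigZag):

* k is the smallest natural number with 1/2ᵏ strictly below the
  positive/negative base-rate odds, capped at L.  Levels 1..k exit on the
  positive cue value toward the positive outcome.
* After level k, exit sides alternate starting with a negative exit (the
  k positive exits are exhausted first).
* Cue choice per level: the remaining cue with the greatest PPV on
  positive-exit levels and greatest NPV on negative-exit levels
  (ZigZag-val), or greatest sensitivity/specificity (ZigZag-sens).  The
  published recipe specifies the alternation phase's criterion; applying
  the same criterion to the initial positive-exit block is this package's
  completion of the rule.
* Statistics are computed once on the full dataset, not re-computed on
  the cases surviving to each level; the recipe does not specify, and
  whole-sample ranking keeps induction order-invariant and cheap.
  Statistics are compared as exact rationals; undefined statistics (zero
  denominators) rank below all defined ones; ties are broken by a seeded
  draw, so induction is reproducible per seed and seed-invariant in the
  absence of ties.
* If the positive outcome is the majority class, outcome roles are
  swapped internally — the rule presumes a minority "disease" class.
* Each cue's positive value must be declared in the dataset sidecar; no
  polarity inference.

Classification walks the levels in order; a category matching no exit
value (e.g. "unknown") passes to the next level, and at the final level
falls back to the declared default label.  Evaluation reports confusion
counts, sensitivity, specificity and frugality (mean cues inspected).
`exit_structure_roc` enumerates all 2^(L−1) exit-side assignments
(refusing L > 12) and returns the distinct (false-alarm rate, hit rate)
points plus the two degenerate classifiers.

An explicit exit-structure constructor (`fft_from_exit_structure`, CLI
`--exit-structure`) reproduces published trees directly.  Note a
documented tension left unresolved: the k-inequality applied to the
chest-pain cohort's base rates (15:74) yields k = 3, while the published
tree has the exit pattern of k = 1.  The rule is implemented as stated;
the published tree is available verbatim via `green_mehr_tree()` or the
override.

The naive-Bayes comparator multiplies per-cue likelihood ratios onto the
prior odds under conditional independence; it agrees with the exact joint
posterior to rational precision whenever the generating task is in fact
conditionally independent (asserted in the suite).

## Cue validity and merging

Validity of a binary cue is the fraction of object pairs — distinct
criterion values, cue discriminating — in which the cue-positive object
has the higher criterion.  Tied-criterion pairs are excluded (the target
relation is strict).  Merged cues (`AND`/`OR`/`XOR`) are appended as new
columns with positive polarity "combination true"; degenerate results
(e.g. XOR of a cue with itself) yield constant columns whose validity is
undefined and raises.

## Synthetic data

`sample_cases` implements natural sampling: each record independently
draws its hypothesis from the priors and then each cue value from the
context-resolved likelihoods.  Records are i.i.d. — sequential
*encounter* is an acquisition story, not autocorrelation.  Every
stochastic operation takes an explicit seed (default 0) and is
byte-reproducible per seed.

`green_mehr_fixture` reconstructs the 89-patient chest-pain cohort from
its published aggregates: routing counts 33 / 29 / 17 / 10, 15 positive
outcomes all routed to high-risk exits (10 at the first-level exit, 5 at
the final positive exit — the split between those two exits is not
published and is fixed arbitrarily), classification counts 50/39 and
confusion counts (15, 35, 0, 39) under the published tree.  Record-level
detail beyond these aggregates (e.g. chest-pain values within the
first-exit group) is synthetic and deterministic; conclusions that depend
on per-leaf counts of the full outcome tree cannot be drawn from it.

`merged_cue_environment` builds three-cue pair-comparison environments
with target validities 0.80 / 0.60 / 0.60 and a merged cue (C2 op C3) of
validity exactly 1.  Construction: the criterion is a bonus of 10 for
merged-positive objects plus Uniform(0,1) jitter, so whenever the merged
cue discriminates it points to the higher criterion — validity 1 for
every seed, by construction, not statistically.  C1 is the above-median
criterion indicator with exactly 20% of each half flipped, giving
validity (1−ε) = 0.80; the (C2, C3) cell probabilities are solved in
closed form so each component's validity is 0.60: with equal-merged-value
pairs contributing ½, validity_C2 = q + (1−q)/2 for AND (q = p(C3⁺|C2⁺)),
(1+r)/2 for OR (r = p(C3⁻|C2⁻)), and ½ + (s−t)/2 for XOR
(s = p(C3⁻|C2⁺), t = p(C3⁺|C2⁻)); setting q = r = 0.2 and s − t = 0.2
hits 0.60.  Cell counts use largest-remainder quotas and cells/flips are
interleaved along the criterion ranking, so realized validities sit at
their targets up to O(1/n) for every seed — these are engineered stimuli
with fixed cue structure, which is what the environments they emulate
were.  What this generator does **not** emulate: sampling noise in cue
structure, continuous criteria with ties, more than three cues.

`estimate_task` recovers priors and likelihoods as exact empirical
proportions, with or without contexts; cells with no records are omitted
(their conditionals are undefined; validation flags them downstream).
The parameter-recovery property suite draws *balanced* two-hypothesis
tasks (priors uniform in [0.4, 0.6]): recovery precision is limited by
the smallest per-hypothesis stratum, and at n = 10⁵ the balanced design
makes the asserted ±0.01 band at least a 4-standard-error statement about
estimator correctness rather than a bet on binomial tail events.  For the
same reason the mammography natural-sampling check asserts ±0.01 only on
proportions whose strata support it (prevalence, false-positive rate) and
a 3-SE band on the sensitivity, whose stratum holds only ~10³ records at
1% prevalence.

## Problem sizes and numerical choices

Property suites run 200 seeds for the format-equivalence and
sequential-updating invariants (exact rational assertions), 10 seeds ×
10⁵ records for parameter recovery, and n ≤ 50 environments against a
brute-force pair-enumeration oracle for validity.  Random tasks draw 2–3
hypotheses, 1–3 cues, arity 2–3 with Dirichlet(1) rows, so every branch
has positive probability.  Distribution sum checks tolerate 1e-9;
float-vs-float posterior comparisons use 1e-12; everything structural is
exact.

## Known limitations

* Continuous cues are out of scope; categories only.
* FFT induction requires binary cues with declared polarity; polychotomous
  cues pass through classification (non-exit values) but cannot anchor
  exits.
* No AUROC integration — only raw exit-structure ROC points.
* CART / logistic-regression comparators are out of scope.
* The chest-pain fixture is aggregate-faithful, not record-faithful (see
  above).
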