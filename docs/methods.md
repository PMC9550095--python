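# Methods

This note records the model, the parameter choices, the numerical
conventions, and the known limitations of the package. It states nothing
that the test suite or `scripts/acceptance.py` does not itself compute.

## Continuous optimizer

The swarm model is deliberately minimal. Positions live in a box
[LB, UB]^D with LB < UB componentwise; every proposal is clamped to the
box, so all evaluated points satisfy the bounds by construction. The
osphresis flight adds `step_scale · U[−1, 1]` per component. The update
rule's ± sign is absorbed into the signed uniform draw. The step is an
*absolute* length — on a ±8192 box a unit step is minuscule — so
`step_scale` is exposed (default 1) rather than silently rescaled to the
range; faithfulness first, usability second.

Scouting flights are temporaries: a member's position changes only in the
vision phase, which relocates the entire swarm to the global best
whenever an iteration improves it. Comparisons for replacing the best are
strict (`<`), so ties keep the incumbent and plateaus cannot cause drift.

Budget accounting is exact: every objective evaluation passes through one
`BudgetCounter.spend()` and nothing else evaluates the objective. The
chaotic-opposition initialization costs exactly 2N FFEs; the chaotic
local search costs one FFE per candidate, at most K per trigger, with an
early exit on the first strict improvement. (A worst-case complexity
bookkeeping that charges one CLS evaluation per iteration would
undercount what is actually spent; the counter counts evaluations.) The
best-so-far trace records (FFE, fitness) at every strict improvement and
is non-increasing by construction.

Chaotic machinery: the logistic map at μ = 4 maps (0,1) into [0,1]; the
initial state is drawn uniformly and redrawn if within 1e−12 of
{0.25, 0.5, 0.75} (fixed or pre-fixed points whose orbits collapse).
Inside the local search the state is additionally nudged into
[1e−16, 1−1e−16] each step because a floating-point orbit can touch 0 or
1 exactly. The chaotic population in the initialization maps the *last*
N/2 members (the opposition population mirrors the first N/2), so every
member contributes to exactly one derived population. The chaotic
variant is the literal componentwise product β·x clamped to the box; a
`normalized` mode (`LB + β(x − LB)`) is available because the literal
product is bound-asymmetric and shrinks toward the origin, but literal
is the default. Sorting in the initialization is a stable sort on
fitness, so insertion order breaks ties deterministically.

The CLS trigger defaults to `maxFFEs/3` (8,350 at the benchmark budget of
25,050 = N + N·maxIter with N = 50, maxIter = 500). λ is recomputed from
the budget position at each trigger.

## Benchmark suite

cec01–cec03 are the data-free problems at their published dimensions and
ranges: Chebyshev polynomial fitting (degree D−1, penalties for leaving
[−1, 1] on a 32·D+1 grid and for undershooting T_{D−1}(1.2) at ±1.2),
the 4×4 inverse-Hilbert residual Σ|HZ − I|, and 6-atom Lennard-Jones
energy (pairwise r⁻¹² − 2r⁻⁶, squared-distance guard 1e−12, plus the
known 12.7120622568 offset). cec04–cec10 are **unshifted, unrotated
analogues** of Rastrigin, Griewank, Weierstrass, Schwefel (on coordinates
scaled ×10 so the classic domain fits the ±100 box), Happy Cat, Ackley
and expanded Schaffer F6. Every suite function is offset so its global
minimum value is 1, the suite's convention; the registry stores an exact
minimizer where one is representable (verified to 1e−9 in the tests) and
none for Lennard-Jones and Schwefel, whose minimizers are irrational.
Because the official shift/rotation data are not used, published
per-function scores for cec04–cec10 are not comparable; dimensions,
ranges and the optimum convention are.

## Binary wrapper

Design points that were genuinely open, and what was chosen:

- **Flip rule.** V-shaped transfer functions measure displacement
  magnitude, so the flip argument is the companion displacement of the
  current move scaled by λ^a (a = `flip_anneal`, default 2): early
  candidates differ from their parent in many bits, late candidates in
  one or two. The exponent was set by comparing mean achieved fitness on
  two synthetic instances (30 and 80 features) disjoint from any test
  fixture; 2 and 3 were indistinguishable and the milder schedule was
  kept. Using the companion *position* as the argument (the plain rule,
  still available through `binarize_step`'s default) gives a ~0.85 mean
  flip probability over a uniform [−4, 4] companion and no exploitation
  phase; it is measurably worse on every instance tried. At least one
  bit always flips — a zero-flip candidate duplicates its parent and
  wastes an FFE.
- **Initial masks** are Bernoulli(1/2); companions get the full
  chaotic-opposition treatment. One-shot companion binarization
  (`initial_bits`) is exposed but yields ~85%-dense masks over a uniform
  companion box, which measurably handicaps the search.
- **Fitness weights** α = 0.99 (the convention of the hyper-learning
  binary-dragonfly protocol this experiment design follows); the
  companion box [−4, 4] spans the effective range of all four V-shaped
  transfer functions; V2 (tanh) is the default transfer function. All
  three are config-exposed.
- **CV protocol.** One stratified 10-fold partition is drawn per run and
  reused by every fitness evaluation: this keeps the fitness a
  deterministic function of the mask (making the mask→error cache valid)
  and reduces fitness noise. The reported accuracy re-evaluates the best
  mask under the same partition — there is no holdout. Features are
  min-max scaled per column before KNN (Euclidean distance is
  scale-sensitive); constant columns map to 0.
- **FFE semantics.** Every candidate evaluation costs one FFE, cached or
  not: the cache accelerates, it does not refund budget, so budgets stay
  comparable across methods. The wrapper's CLS trigger reuses the
  `maxFFEs/3` rule (336 at the 1,010 protocol budget).
- **Fast CV path.** Inside the wrapper loop the masked squared-Euclidean
  distance matrix is a single matrix–vector product over a precomputed
  (n², p) per-feature table; a test asserts exact agreement with the
  sklearn path (StratifiedKFold + KNeighborsClassifier) on random masks.
  Datasets whose table would exceed ~1.6 GB fall back to sklearn.

## Synthetic data

The planted-subset generator draws labels Bernoulli(class balance),
gives the s informative columns class means ±Δ/2 with unit noise, leaves
the rest standard normal, and permutes columns (planted indices reported
post-permutation). A Gaussian class-shift model is used because the
wrapper only needs controllable signal-to-noise structure; it does not
emulate real datasets' marginals, correlated features, or class
imbalance pathologies, so passing recovery tests demonstrates search
behaviour, not performance on any particular real dataset.

The patient-table generator produces the 15-column case-report layout
(id, location, country, gender, age, two date offsets, two travel flags,
six binary symptoms; categoricals as small integers) with a binary
death/recovery label at 35% prevalence and n = 400 — a scale typical of
early single-source case-report compilations. By default gender
(P(male) 0.72 vs 0.45), age (66 ± 10 vs 42 ± 12, clipped to [0, 95]) and
symptom_2 (0.75 vs 0.20) depend on the label; every other column,
including id and symptom_6, is label-independent by construction.

A known consequence of the single-partition CV protocol, measured with
an intensive steepest-descent probe: a zero-signal column pays for
itself whenever it accidentally repairs at least one CV prediction
(0.99/n > 0.01/|O| for n below ~1,500), so the *fitness-optimal* mask
retains such a column for roughly 1 partition in 5. Mask-recovery
metrics (Jaccard against the planted set, exclusion counts for id) are
therefore capped by the protocol itself, independent of optimizer
quality; the wrapper's best masks keep the planted columns plus a few
such repair columns. The accuracy comparison (best mask vs all features)
is unaffected.

## Statistics

Scores are lower-is-better by default (fitness); a flag inverts for
accuracy tables. Ranks use scipy's average-rank method per row. The
Friedman statistic is the classic uncorrected form (no tie correction),
which is what reproduces the published comparison values. Critical
values are upper-α quantiles of χ²(k−1) and F(k−1, (k−1)(n−1)). Holm
p-values are one-sided by default (the control is hypothesized better;
only one-sided tails reproduce the published magnitudes); the threshold
at ascending sort index i is α/(k−1−i), and rejection stops at the first
failure. The bundled published comparison tables are internally
inconsistent in two rows (re-ranking the printed means permutes three
methods in one row and swaps two in another); the rank table is bundled
separately so the omnibus statistics can be reproduced from the ranks
exactly, and the re-ranking path is asserted against the arithmetic.

Wilcoxon: zero differences are dropped (the original prescription), tied
absolute differences share average ranks, and for n ≤ 25 the null is
enumerated exactly by dynamic programming over doubled (integer) rank
sums — 2ⁿ sign assignments without 2ⁿ work; above that a normal
approximation with tie correction and continuity correction is used.
α = 0.05 is the default significance level throughout (it is the level
the published critical values 19.7 and 1.89 imply).

## Problem sizes in the checks

The budget-conservation sweep uses 10-member swarms at a 260-FFE budget
across all twelve registered problems; the convergence smoke test uses
the 2-D sphere at 5,000 FFEs over 10 seeds (median best < 1e−2); the
initialization-dominance check pairs 100 seeds on the 10-D sphere at
N = 50; feature-selection experiments use the full 1,010-FFE protocol
with 10 runs. These sizes are the package's own choices for routine
verification; all parameters scale up through the configuration objects.

## Known limitations

- The wrapper's search quality at the 1,010-FFE protocol budget is
  adequate for tens of features; for thousands of features (the scale of
  the largest public FS benchmarks) the budget explores a vanishing
  fraction of mask space and results will be noisy.
- No parallel execution; runs are sequential by design (determinism).
- The CEC-style functions are analogues, not the official data-dependent
  instances (above).
- Reported accuracy shares the search's CV partition and therefore
  inherits its optimism; add an outer holdout if unbiased error
  estimates are needed.
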