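# Methods

## Problem and model

The package addresses wrapper feature selection for classification:
choose a subset of feature columns that maximizes the accuracy of a
classifier trained on them while keeping the subset small.  The search is
over binary masks, obtained by thresholding a continuous position
x ∈ [0, 1]^D at 0.5 (values ≥ 0.5 select; the boundary selects).  The
objective, minimized, is

    f = α (1 − P) + (1 − α) N_f / N_t

with P the validation accuracy of a k-nearest-neighbour classifier
trained on the training split restricted to the selected columns.  The
empty mask is infeasible and scores the worst possible value 1.0, which
keeps the objective total over the whole box.  α is not a published
operating value; the default 0.99 encodes accuracy-first selection (the
size term then acts as a tie-break at (1 − α)/N_t per feature, which is
what produces the minimal perfect-accuracy subsets seen in practice) and
is exposed in the configuration.

### Classifier

The k-NN (default k = 5, odd by construction) is implemented in-package
so that all ties are deterministic: equal distances resolve to the lower
training-row index (stable sort), and a tied majority vote resolves to
the label of the single nearest neighbour.  scikit-learn's classifier is
used in the test suite as an independent cross-check on tie-free data,
not in the implementation.  Features are min–max scaled to [0, 1] using
training-split statistics before distance computation (constant training
columns scale to 0); this keeps distances comparable across features of
different ranges and is toggleable.

### Split protocol

Every dataset is partitioned into stratified equal thirds — training,
validation, test — by a seeded per-class shuffle; within each class the
thirds differ by at most one row, with remainders going to training
first.  Stratification is a deliberate choice: small biomedical classes
would otherwise vanish from a third entirely.  Validation drives the
optimizer; the test third is touched only by final reporting.

## Optimizer

Two populations of N agents evolve for T iterations in a box.  Per
iteration, for each ant: an antlion is chosen by roulette wheel (under
minimization, weights are max-shifted, w_j = max f − f_j + 1e−12, so
all-equal fitness degrades to a uniform draw); the global bounds are
divided by the exploration ratio I and centred on the chosen antlion and
on the elite; for each guide and dimension a fresh T-step ±1 random walk
is generated, min–max normalized into the guide's interval, and read at
index t; the ant moves to the average of the two guide values, clipped to
the box.  Ants strictly fitter than their antlion replace it; the elite
is the best antlion ever seen, so the fitness trace is non-increasing by
construction.

The exploration ratio is I = 10^w · t/T with w stepped from 2 to 6 at
t/T > 0.1, 0.5, 0.75, 0.9, 0.95; below the first threshold no shrinking
is applied (I = 1), matching the reference behaviour of the base
algorithm.  Both bound vectors are divided by I — the shrink is applied
symmetrically, otherwise intervals invert.

**Interval placement.**  The shrunk interval is attached to a randomly
chosen side of the guide, drawn per dimension.  A purely additive
translation (c/I + guide, d/I + guide) degenerates when the global lower
bound is 0, as it is in feature selection: c/I = 0 pins the interval's
lower end to the guide itself, coordinates can only drift upward, and
selected bits can never switch off.  The random side flip restores
walks *around* the guide; drawing it per dimension rather than once per
guide vector decorrelates the exploration of different features and
measurably improves agreement with the exhaustive oracle (mean 6.8/10 vs
5.2/10 optimal hits over five benchmark instances).

**Degenerate rules.**  A constant walk (impossible for unit steps but
covered by the contract) normalizes to the interval midpoint.  Ties in
replacement require strict improvement, avoiding position churn without
fitness gain.  Positions are clipped, not reflected, at the box — the
binarization is threshold-based, so the distinction is immaterial
downstream.  A non-finite objective value aborts the run naming the
offending position.

## Chaotic schedule

Five maps on the unit interval are provided, each a closed-form
recurrence: logistic a·x(1−x) (a = 4), sinusoidal a·x²·sin(πx)
(a = 2.3), tent (x/0.7 below 0.7, (10/3)x(1−x) otherwise; the boundary
0.7 belongs to the second branch), singer
μ(7.86x − 23.31x² + 28.75x³ − 13.3x⁴) (μ = 1.07), and piecewise with
breakpoints at p, 0.5, 1−p (p = 0.4).  Operating values for μ, p and the
initial state are not published beyond admissible ranges; the defaults
above sit inside those ranges and are configurable.  The default initial
state is x₀ = 0.7 except for the tent map, where 0.7 is a fixed point of
the second branch and the orbit would collapse; tent defaults to
x₀ = 0.6.  Construction rejects initial states with provably collapsing
orbits (logistic {0.25, 0.5, 0.75}, tent {0.7}, and the interval
endpoints for all maps).

The map advances once per optimizer iteration (a single schedule signal
shared by all ants) and couples to the base ratio as Î = max(1, I^x).
The published description links the map to the exploration rate only
qualitatively; this exponent form was chosen because it reproduces the
described alternation — Î → 1 (full exploration) as x → 0 and Î → I
(the base envelope) as x → 1 — and is bounded by [1, I] so the chaotic
variant never exploits harder than the base schedule.  An envelope-free
alternative (Î = 1/x) is available as `coupling="replace"` for
sensitivity checks.  With the base schedule the chaotic machinery is
never constructed at all.

## Synthetic benchmarks

The generator plants `n_informative` Gaussian columns whose class means
are δ·σ apart (adjacent classes) among `n_noise` columns drawn
identically for all classes, with balanced classes by default and the
ground-truth informative index set returned.  Defaults (300 samples,
3 informative + 7 noise, δ = 3, σ = 1, two classes) emulate a small
biomedical dataset with a strong, sparse signal.  What it deliberately
does not emulate: correlated features, non-Gaussian marginals, class
imbalance (available via `class_weights` but off by default), label
noise, and interaction effects where features are informative only
jointly.  Passing tests therefore demonstrate correct optimization of
the stated objective on separable signals, not robustness to those
real-data complications.

A consequence worth stating explicitly: planted features are mutually
*redundant*.  At δ = 3 three informative columns already yield perfect
validation accuracy, so the global optimum of the fitness keeps only as
many planted features as accuracy needs — on the 5-informative/15-noise
benchmark that is a 3-feature mask, and recall of the planted set tops
out near 0.6 for a *correct* minimizer.  Recall against the full planted
set is thus a property of the benchmark's redundancy, not of optimizer
quality; selection size and oracle agreement are the discriminating
measures here.

The exhaustive oracle scores every nonempty mask (capped at 15 features,
i.e. 32 767 evaluations; ties resolve to the lexicographically smallest
bit vector) and is the gold standard in tests: optimizer runs must never
beat it and should usually match it.

## Experiment protocol and metrics

Each optimizer is applied M times (default 20) with per-run seed
base + index; every run forces the all-features position into the
initial antlion population, so the initial elite — and hence every
subsequent elite — is at least as fit as selecting everything.  Reported
measures over the M best-of-run results: mean, min, max, and sample
standard deviation (1/(M−1)) of the fitness; mean test accuracy of the
selected masks; mean selected fraction; and a Fisher-score aggregate.
The per-feature Fisher score is Σ_k n_k(μ_kj − μ_j)²/σ_j² with μ_j and
σ_j taken over the entire dataset and σ_j² the population variance
(divide by N) — the whole-dataset convention is implemented as printed
in the source formulation even though it differs from the classical
within-class normalization, and zero-spread features score 0 with a
warning.  The reported aggregate is the mean over runs of the *sum* of
scores over each run's selected features; a per-feature mean is
available via `mode="mean"` since the scalar aggregation of the source
tables is not fully specified.

## Problem sizes and determinism

Validation suites use 60–600 samples and 4–20 features: large enough
that planted signals dominate sampling noise (Fisher scores of δ = 3
columns sit two orders of magnitude above null columns at n = 600) and
small enough that an exhaustive oracle and repeated-run statistics are
computed in seconds.  All randomness flows through
`numpy.random.default_rng` seeded per run; identical (seed, config)
pairs produce bit-identical traces, reports and files.  The chaotic maps
consume no RNG draws, so base and chaotic runs with the same seed see
the same random-walk stream and differ only through the schedule.

## Known limitations

Wrapper selection with k-NN refits the classifier for every evaluated
mask; cost grows quadratically with sample count.  Only box constraints
are supported; the binarization threshold is fixed at 0.5; no
cross-validation scheme beyond the fixed three-way split is provided;
and competitor metaheuristics (genetic algorithms, particle swarms) are
out of scope — comparisons here are between the base and chaotic
schedules only.
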