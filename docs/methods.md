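# Methods

This note records the models, defaults and numerical choices behind
`plateopt`, and what the synthetic benchmarks do and do not demonstrate.

## Search space and featurization

A search space is an ordered list of parameters, each categorical (with a
finite label list) except at most one numeric temperature parameter. The
candidate set is the full Cartesian product in lexicographic
parameter-definition order with 0-based ids; deterministic ids are what make
run-mask bookkeeping and seeded replay possible. Feasibility rules are pure
predicates per condition; the temperature rule keeps a condition iff the
temperature is **≤** the boiling point of every in-scope solvent-like value
(equality is feasible: only *exceeding* the boiling point is ruled out). The
rule's scope is configurable per space file, so co-solvents with defined
boiling points can be included or excluded from the check.

Featurization: one-hot flags per categorical value, a single numeric column
for temperature, or per-value descriptor vectors (optionally PCA-reduced to
the smallest component count reaching a configured explained-variance
threshold). PCA projections are fitted once on a parameter's full descriptor
table — every value in the space, not just observed ones — so feature
meaning is stable across a campaign. All encoded columns are min-max scaled
to [0, 1] **over the feasible pool** (not the unfiltered product), because
the surrogate should see the geometry of the actual candidate set; constant
columns are dropped and recorded. Temperature is scaled jointly with the
other features; the ARD kernel then learns its own length scale for it.

## Surrogates

One independent Gaussian process per objective; no cross-objective
correlation is modelled (permuting one objective's training column leaves the
other's posterior unchanged, and the test suite asserts this). Inputs are
the pool features; targets are standardized per objective and all posteriors
are de-standardized back to AP units. Kernel: constant × Matérn-5/2 with
independent per-dimension length scales, bounds [0.1, 100] (the lower bound
keeps one-hot dimensions, whose pairwise distance is √2, from collapsing),
signal variance bounds [1e-3, 1e3], plus a white-noise term with a floor of
1e-4 in standardized units (upper bound 10). Hyperparameters maximize the
marginal likelihood by L-BFGS-B capped at 50 iterations per start, with one
seeded restart by default; refitting with identical inputs and seed is
bit-reproducible. Replicate observations stay as separate rows — the fitted
noise term absorbs their scatter — rather than being averaged.

Posterior linear algebra (means, variances, covariances and
cross-covariances between arbitrary candidate subsets) is computed in-package
from the fitted kernel via a Cholesky factor of the training covariance;
the unit tests verify it against the fitted scikit-learn regressor's own
predictions. Rank-deficient posterior covariances are factorized with
escalating diagonal jitter (1e-10 up to a cap of 1e-4 relative); fitting
errors out beyond the cap, while sampling falls back to an eigendecomposition
factor (clipping negative round-off eigenvalues), since near-zero posterior
variance is legitimate there. Joint sampling is only ever done over
requested id subsets — never the full pool covariance of a large space.

## Pareto machinery

Maximization is the internal convention; minimization objectives are negated
at ingestion. Hypervolume uses an exact sort-and-sweep for two objectives
and exact recursive slicing over the last objective for more (intended for
d ≤ 4). Front extraction keeps duplicate copies of front points; hypervolume
de-duplicates, so ties contribute once. Reference points are not part of
the problem statement, so the package fixes a convention: componentwise
minimum of the relevant point set minus 1% of each objective's range
(minus 1.0 for a degenerate zero-range objective). For benchmark scoring the
set is the full ground-truth table, shared by all algorithms on a dataset;
within a campaign it is the observations to date, frozen per iteration.
HV% compares fronts on both sides: 100·HV(front(found))/HV(front(truth)).

Acquisition code evaluates many two-objective HVI queries against a fixed
front through a precomputed dominance staircase with cumulative areas
(O(log k) per query); sampled points below the reference point are clipped to
it, i.e. contribute zero improvement.

## Acquisition

All strategies select batches greedily, one slot at a time, never propose a
run condition or a duplicate, break ties by lowest pool id, and are
deterministic given (model, pool, config, seed).

- **Sobol**: scrambled Sobol points in the feature unit hypercube, each
  mapped to the nearest un-run, not-yet-picked candidate by Euclidean
  distance. Used for iteration 1 of every campaign and as the benchmark
  baseline.
- **q-NEHVI**: for each slot, joint posterior realizations are drawn at the
  *anchor* set (all observed conditions plus pending picks); each candidate
  is sampled from its posterior conditioned on the realization (a "fantasy"),
  and its hypervolume improvement over that realization's sampled front is
  averaged over Monte-Carlo samples. Integrating over sampled fronts rather
  than the noisy observed front is what makes the criterion noise-aware: a
  candidate coinciding with a noisy observation retains positive value. The
  per-realization staircase plays the role of a cached box decomposition and
  is rebuilt per slot as anchors grow.
- **q-NParEgo**: per slot, a weight vector drawn from the unit simplex
  (floored at ε = 0.01 and renormalized), objectives normalized to [0, 1] by
  the observed min/max frozen per iteration (a degenerate zero range maps to
  a constant 0.5, with a warning), augmented Chebyshev scalarization with
  ρ = 0.05, and a Monte-Carlo noisy expected improvement over the same
  fantasy machinery. In the degenerate limit where no candidate improves on
  the fantasized baseline (e.g. a zero-variance posterior), ranking falls
  back to the scalarized posterior mean, recorded in the provenance.
- **TS-HVI**: q joint posterior draws over the un-run pool; draw j picks the
  remaining candidate whose sampled objective vector has maximal HVI over
  the *observed* front. If every sampled HVI is zero the slot falls back to
  the maximal sampled objective sum (recorded).
- **Utopia exploitation**: pure exploitation for a final round — rank
  candidates by Euclidean distance of the posterior mean vector to the
  Utopia point, default (110, 110) AP; no uncertainty term.

Defaults: mc_samples = 128 in `AcquisitionConfig`; the benchmark harness
passes 32 as its compute budget (see below).

**Temperature constraints** (≤ k unique temperatures per batch): *naive*
runs the inner strategy unrestricted until k distinct temperatures appear
among the picks, then restricts the pool to those temperatures; *nested*
first scores every temperature level by the mean single-point acquisition
value over its un-run candidates (seeded random subsample above 5,000 per
level), keeps the top k, and runs the inner strategy on the restricted pool.
Both work for any k and any inner strategy. Under a constraint, benchmark
initialization picks k temperature levels at random (seeded) and restricts
the Sobol plate to them. Utopia exploitation under a constraint uses the
naive wrapper, which reproduces "temperatures of the top-ranked candidates,
in rank order, until k are found".

## Synthetic landscapes and the benchmark harness

`generate_synthetic_landscape` builds a ground-truth oracle over a
combinatorial space: per-parameter categorical main effects (Gaussian, scale
1.0), pairwise interaction tables (scale 0.4), sparse high-magnitude cliff
interactions (2% of value pairs, scale ≈ 3 — the isolated optima that defeat
grid screening), and a quadratic response in normalized temperature with a
random optimum. The latent field is squashed through a logistic centred on
its median (width 0.75 sd) onto [0, 100] AP units. The second objective is a
correlated latent (default trade-off correlation −0.5) so the true front has
several points; construction errors out if the requested minimum front size
(default 3) is not met. The default landscape is 8 ligands × 4 precatalysts
× 4 bases × 5 solvents × 5 temperatures, filtered by solvent boiling points
(65/65/80/100/120 °C against 40–100 °C) to 2,176 feasible conditions.

Observation noise is independent Gaussian per objective, clamped to the
objective bounds ([0, 100] for AP-like objectives; auxiliary objectives clamp
at [0, max observed]); σ = 0 returns the truth exactly. The optimizer only
ever sees noisy observations, while HV% is always computed on the noise-free
truth of the selected conditions against the true front, so trajectories are
monotone and reach exactly 100% if the pool is exhausted.

`train_emulator` provides the emulated-virtual-dataset route instead: a
deterministic feed-forward regressor (two hidden layers of 64, L-BFGS,
seeded) per objective is fitted to ≥ 50 seed reactions and its clamped
predictions tabulated over an expanded enumeration.

Benchmark protocol (mirroring plate sizes of HTE decks): Sobol first batch,
then algorithm batches, batch size 24 for 5 iterations, repeated over seeds
1–20, reporting mean ± sd HV% per iteration. The harness uses 32 MC samples
and one GP-fit restart per iteration as its compute budget; per-seed
sub-seeds are derived via `SeedSequence` so every run replays bit-identically.

**What passing these benchmarks shows — and does not.** The synthetic
landscape exercises the loop end to end: combinatorial categorical geometry,
cliffs, trade-offs, clamped noise, feasibility filtering. It does not
emulate real chemistry's heteroscedastic noise, batch effects, drifting
assays, or descriptor quality, so HV% values here say nothing quantitative
about any particular reaction system — only that the optimizer finds known
optima efficiently under the stated conditions.

## Campaign orchestration and analysis

Campaign state is a human-inspectable directory (`space.yaml` + descriptor
CSVs, `pool.csv`, `observations.surf`, `history.json`, `config.yaml`). No
fitted model is serialized: GP fitting is bit-reproducible from the persisted
observations and per-iteration seeds, so loading a state and suggesting the
next batch reproduces exactly what the uninterrupted campaign would have
done. Suggested batches are written both as a SURF skeleton (objective cells
empty, for lab fill-in) and as a ranked CSV with acquisition values.
Iteration 1 is always Sobol, optionally restricted to configured initial
temperatures (e.g. 70/100 °C for an unexplored system); later iterations use
the configured strategy and constraint, with per-iteration seeds derived from
the campaign seed. Ingestion accepts partially completed SURF tables: rows
with empty objective cells stay pending and the state remains
`awaiting_results` until the batch is complete. No automatic stopping rule
is implemented — convergence, stagnation, or budget exhaustion is the
operator's call, and a final exploitative round (`utopia_exploit`) is the
intended closing move.

Post-campaign analysis fits a random forest (200 trees, seeded) to the
encoded features and reports mean-absolute permutation importance per
feature, labelled by parameter/value so one-hot flags read as "this specific
precatalyst". Permutation importance is the package's importance measure;
an exact Shapley-value oracle by brute-force subset enumeration (≤ 12
features) is provided alongside it for verification on small models, where
its values are checked against closed forms (linear models) and the
efficiency property.

## Scaling choices

Test-suite and acceptance-script problem sizes are the package's own
benchmark conditions: the ~2,200-condition default landscape, batch 24 × 5
iterations, seeds 1–20 in the test suite; the acceptance script reports the
same quantities over 10 seeds (5 for the constrained variants) derived from
its `--seed`. Known limitations: exact hypervolume is exponential beyond
d ≈ 4 objectives; joint TS sampling factorizes an n×n posterior covariance,
practical to a few thousand candidates; q-EHVI-style exact joint batch
optimization is out of scope (greedy construction is the documented choice);
the GP kernel settings are this package's own general-purpose defaults, not
a reproduction of any other tool's hyperparameters.
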