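# plateopt

Batch multi-objective Bayesian optimisation of reaction conditions for
high-throughput experimentation (HTE).

## The problem

Process chemists optimising a reaction explore discrete combinations of
categorical parameters — ligands, precatalysts, bases, solvents, co-solvents —
plus temperature, against several objectives at once (typically area-percent
(AP) yield and AP selectivity from LC analysis, both in [0, 100]). Even a
modest parameter list multiplies out to 10⁴–10⁵ candidate conditions, far
beyond what robotic 24/48/96-well plates can screen exhaustively, and the
landscape often hides isolated optima ("reactivity cliffs") that grid-style
fractional-factorial plates miss. `plateopt` drives such campaigns
algorithmically:

1. **Search space** — enumerate the Cartesian product of parameter values,
   drop infeasible conditions (e.g. reaction temperature exceeding the solvent
   boiling point), and encode the survivors as features: one-hot flags,
   numeric temperature, or descriptor tables optionally reduced by PCA.
2. **Initial plate** — scrambled Sobol points in the feature unit hypercube,
   mapped to the nearest un-run candidates, spread the first batch diversely
   across the space.
3. **Surrogates** — one Gaussian process per objective (Matérn-5/2 ARD kernel,
   fitted noise) gives posterior means *μ(x)* and uncertainties *σ(x)* over
   every candidate.
4. **Batch acquisition** — select the next q conditions by
   - **q-NEHVI**: Monte-Carlo noisy expected hypervolume improvement, greedy
     over batch slots with fantasy conditioning on pending picks;
   - **q-NParEgo**: augmented Chebyshev scalarisation
     *s(ỹ) = minᵢ(wᵢỹᵢ) + ρ·Σᵢwᵢỹᵢ* with a fresh simplex weight per slot and
     noisy expected improvement;
   - **TS-HVI**: Thompson sampling — one joint posterior draw per slot, pick
     the candidate with maximal hypervolume improvement over the observed
     Pareto front;
   - **Utopia exploitation** for a final round: rank candidates by Euclidean
     distance of the posterior mean to an ideal point (110, 110 AP).
5. **Constraints** — cap the number of unique temperatures per plate (heating
   decks hold few blocks) with either a *naive* or a *nested* wrapper.
6. **Evaluation** — progress is scored by the hypervolume of the observed
   Pareto front relative to a reference point; on benchmarks, **HV% =
   100 · HV(front found) / HV(true front)**.

A synthetic-landscape module (`plateopt.benchlab`) plays the role of the lab:
seeded categorical main effects, pairwise interactions, sparse reactivity
cliffs, a smooth temperature response, logistic-squashed to AP units, with
clamped Gaussian observation noise — so the whole loop is testable end to end
with no external data. An emulator (`train_emulator`) can instead tabulate a
regressor fitted to real seed data over an expanded grid.

## Worked example

`examples/02_simulated_campaign.py` runs a five-iteration campaign (batch 24,
q-NEHVI, nested cap of 2 unique temperatures per plate, first plate Sobol at
70/100 °C) against the default synthetic landscape of 2,176 feasible
conditions:

```
landscape: 2176 feasible conditions, 21 true Pareto points
iteration 1: cumulative hypervolume =  77.6% of the true front
iteration 2: cumulative hypervolume =  87.3% of the true front
iteration 3: cumulative hypervolume =  90.8% of the true front
iteration 4: cumulative hypervolume =  97.8% of the true front
iteration 5: cumulative hypervolume =  98.6% of the true front
best observed condition: {'ligand': 'ligand_1', 'precatalyst': 'precatalyst_3',
 'base': 'base_4', 'solvent': 'solvent_1', 'temperature': 55.0}
its AP yield / selectivity: [91.7 85.4]
```

After 120 of 2,176 conditions (5.5% of the space) the campaign has recovered
98.6% of the hypervolume of the true Pareto front, and the best single
condition reaches ~92 AP yield at ~85 AP selectivity. The other examples
cover space construction (`01`), strategy benchmarking against the Sobol
baseline (`03`), permutation feature importance (`04`), and temperature-
constrained batches (`05`).

A thin CLI wraps the same functions for shell use:

```bash
plateopt space build space.yaml
plateopt campaign init --space space.yaml --state run1 --q 96 --seed 1 \
    --init-temps 70,100 --constraint nested:2
plateopt campaign ingest --state run1 --results batch_1_filled.surf
plateopt campaign suggest --state run1
plateopt bench run --algos sobol,qnehvi --seeds 1:5 --out bench.csv
plateopt analyze importance --state run1 --objective AP_yield
```

Campaign state persists as a human-readable directory (`space.yaml`,
`pool.csv`, `observations.surf`, `history.json`, `config.yaml`); observation
tables use a flat tab-separated SURF-style dialect.

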