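"""Stand-in for the laboratory: ground-truth oracles and the benchmark harness.

Two ways to obtain a :class:`BenchmarkOracle` (a known objective function over
a full condition space, playing the role of the lab):

* :func:`train_emulator` fits a deterministic feed-forward regressor per
  objective on a seed dataset of measured reactions and tabulates its
  predictions over an expanded enumeration (an "emulated virtual dataset").
* :func:`generate_synthetic_landscape` builds a fully synthetic combinatorial
  landscape with seeded categorical main effects, pairwise interactions, a
  smooth quadratic temperature response and sparse high-magnitude "cliff"
  interactions (isolated optima), squashed to AP-like values in [0, 100].
  The second objective is generated with a controllable trade-off
  correlation so the true Pareto front is non-trivial.

Observations add independent clamped Gaussian noise per objective
(yield-like objectives clamp to [0, 100]).  The benchmark harness runs each
algorithm over repeated seeds — Sobol first plate, then algorithm batches —
and tracks the hypervolume-% of the (noise-free) truth of all selected
conditions against the true Pareto front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from . import acquisition as acq
from . import surrogate as sg
from .pareto import hypervolume_percent, pareto_front, reference_point
from .space import (
    CandidatePool,
    Condition,
    FeasibilityRule,
    ParameterDef,
    SearchSpace,
    apply_feasibility,
    encode_conditions,
    encode_pool,
    enumerate_conditions,
)

__all__ = [
    "BenchmarkOracle",
    "EffectParams",
    "AlgorithmSpec",
    "BenchmarkRunResult",
    "train_emulator",
    "generate_synthetic_landscape",
    "default_landscape",
    "observe",
    "run_benchmark",
    "oracle_to_csv",
    "plot_benchmark",
]

DEFAULT_OBJECTIVES = ("AP_yield", "AP_selectivity")


@dataclass
class BenchmarkOracle:
    """Ground-truth objective function over a full feasible condition space."""

    pool: CandidatePool
    truth: np.ndarray  # (n_conditions, n_objectives), AP units
    objective_names: tuple[str, ...]
    noise_sd: np.ndarray  # per-objective Gaussian sd
    clamp_bounds: tuple[tuple[float, float], ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.truth.shape[0] != len(self.pool):
            raise ValueError("truth must cover every feasible condition")
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)

    @property
    def truth_front(self) -> np.ndarray:
        return pareto_front(self.truth)

    @property
    def truth_front_points(self) -> np.ndarray:
        return self.truth[self.truth_front]

    @property
    def reference_point(self) -> np.ndarray:
        return reference_point(self.truth)


def observe(oracle: BenchmarkOracle, ids, sigma_override=None, seed: int = 0) -> np.ndarray:
    """Noisy objective rows for the requested condition ids.

    Truth plus independent Gaussian noise per objective, clamped to the
    objective's bounds; a zero sd returns the truth exactly.
    """
    ids = np.asarray(ids, dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= len(oracle.pool)):
        raise ValueError("unknown condition id")
    sd = (
        np.broadcast_to(np.asarray(sigma_override, dtype=float), oracle.noise_sd.shape)
        if sigma_override is not None
        else oracle.noise_sd
    )
    Y = oracle.truth[ids].copy()
    if np.any(sd > 0):
        rng = np.random.default_rng(seed)
        Y = Y + rng.standard_normal(Y.shape) * sd[None, :]
    for j, (lo, hi) in enumerate(oracle.clamp_bounds):
        Y[:, j] = np.clip(Y[:, j], lo, hi)
    return Y


# ---------------------------------------------------------------------------
# synthetic landscapes


@dataclass(frozen=True)
class EffectParams:
    """Scales of the latent landscape components (standardized latent units)."""

    main_scale: float = 1.0
    interaction_scale: float = 0.4
    cliff_fraction: float = 0.02
    cliff_scale: float = 3.0
    temperature_curvature: float = 1.5
    tradeoff_correlation: float = -0.5
    min_front_size: int = 3
    squash_width: float = 0.75  # logistic width in latent standard deviations


def _draw_latent(space: SearchSpace, conditions: Sequence[Condition],
                 rng: np.random.Generator, params: EffectParams) -> np.ndarray:
    """One latent landscape: main effects + interactions + temperature
    response + sparse cliffs, evaluated at every condition."""
    n = len(conditions)
    z = np.zeros(n)
    cat_params = [p for p in space.parameters if p.role != "temperature"]
    value_index: dict[str, dict] = {}
    columns: dict[str, np.ndarray] = {}
    for p in cat_params:
        value_index[p.name] = {v: i for i, v in enumerate(p.values)}
        columns[p.name] = np.asarray(
            [value_index[p.name][c.assignment[p.name]] for c in conditions], dtype=int
        )
        effects = rng.normal(0.0, params.main_scale, size=len(p.values))
        z += effects[columns[p.name]]
    # pairwise interactions between categorical parameters
    for a in range(len(cat_params)):
        for b in range(a + 1, len(cat_params)):
            pa, pb = cat_params[a], cat_params[b]
            table = rng.normal(0.0, params.interaction_scale,
                               size=(len(pa.values), len(pb.values)))
            if params.cliff_fraction > 0 and params.cliff_scale > 0:
                mask = rng.random(table.shape) < params.cliff_fraction
                table = table + mask * params.cliff_scale * (
                    1.0 + 0.25 * np.abs(rng.standard_normal(table.shape))
                )
            z += table[columns[pa.name], columns[pb.name]]
    tp = space.temperature_parameter
    if tp is not None:
        temps = np.asarray([float(c.assignment[tp.name]) for c in conditions])
        lo, hi = min(tp.values), max(tp.values)
        span = (hi - lo) or 1.0
        tn = (temps - lo) / span
        t_opt = rng.uniform(0.2, 0.8)
        z += -params.temperature_curvature * (tn - t_opt) ** 2 * 4.0
    return z


def _squash(z: np.ndarray, width: float) -> np.ndarray:
    sd = z.std()
    if sd < 1e-12:
        return np.full_like(z, 50.0)
    return 100.0 / (1.0 + np.exp(-(z - np.median(z)) / (width * sd)))


def generate_synthetic_landscape(
    space_shape: Mapping[str, object] | None = None,
    effect_params: EffectParams | None = None,
    seed: int = 0,
    boiling_points: Sequence[float] | None = None,
    temperature_values: Sequence[float] | None = None,
    objective_names: tuple[str, str] = DEFAULT_OBJECTIVES,
) -> BenchmarkOracle:
    """Fully synthetic combinatorial reaction landscape with a known front.

    ``space_shape`` maps categorical parameter names to level counts (the
    solvent-like parameter must be named ``solvent`` when boiling points are
    given).  Deterministic given the seed.
    """
    params = effect_params or EffectParams()
    shape = dict(space_shape or {"ligand": 8, "precatalyst": 4, "base": 4, "solvent": 5})
    temps = tuple(float(t) for t in (temperature_values or (40.0, 55.0, 70.0, 85.0, 100.0)))
    defs: list[ParameterDef] = []
    rules: list[FeasibilityRule] = []
    for name, count in shape.items():
        values = tuple(f"{name}_{i + 1}" for i in range(int(count)))
        bps = None
        if name == "solvent":
            bp_list = list(boiling_points) if boiling_points is not None else None
            if bp_list is None:
                bp_list = [65.0, 65.0, 80.0, 100.0, 120.0][: len(values)]
                while len(bp_list) < len(values):
                    bp_list.append(120.0)
            bps = {v: float(b) for v, b in zip(values, bp_list)}
        defs.append(ParameterDef(name=name, values=values, boiling_points=bps))
    defs.append(ParameterDef(name="temperature", values=temps, role="temperature"))
    if any(p.boiling_points for p in defs):
        rules.append(FeasibilityRule("max_temperature_le_boiling_point", scope=("solvent",)))
    space = SearchSpace(tuple(defs), tuple(rules))
    conditions = apply_feasibility(enumerate_conditions(space), space)
    pool = encode_pool(space, conditions)

    rng = np.random.default_rng(seed)
    z1 = _draw_latent(space, conditions, rng, params)
    z2_raw = _draw_latent(space, conditions, rng, params)

    def _standardize(z):
        sd = z.std()
        return (z - z.mean()) / (sd if sd > 1e-12 else 1.0)

    rho = float(params.tradeoff_correlation)
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("tradeoff correlation must be in [-1, 1]")
    s1 = _standardize(z1)
    z2 = rho * s1 + np.sqrt(max(0.0, 1.0 - rho**2)) * _standardize(z2_raw)
    y1 = _squash(z1, params.squash_width)
    y2 = _squash(z2, params.squash_width)
    truth = np.column_stack([y1, y2])

    oracle = BenchmarkOracle(
        pool=pool,
        truth=truth,
        objective_names=tuple(objective_names),
        noise_sd=np.zeros(2),
        clamp_bounds=((0.0, 100.0), (0.0, 100.0)),
        provenance={"kind": "synthetic", "seed": int(seed), "params": params.__dict__.copy()},
    )
    if len(oracle.truth_front) < params.min_front_size:
        raise ValueError(
            f"true Pareto front has {len(oracle.truth_front)} points; "
            f"at least {params.min_front_size} requested — adjust the trade-off correlation"
        )
    return oracle


def default_landscape(seed: int = 7) -> BenchmarkOracle:
    """The default synthetic benchmark landscape (~2,200 feasible conditions,
    two AP objectives, reactivity cliffs, known Pareto front)."""
    return generate_synthetic_landscape(seed=seed)


# ---------------------------------------------------------------------------
# emulated virtual datasets


def train_emulator(seed_dataset: pd.DataFrame, expanded_space: SearchSpace,
                   seed: int = 0, objective_bounds: Mapping[str, tuple[float, float]] | None = None,
                   hidden_layer_sizes: tuple[int, ...] = (64, 64)) -> BenchmarkOracle:
    """Fit a deterministic feed-forward regressor per objective on the seed
    data and tabulate its predictions over the expanded enumeration.

    ``seed_dataset`` columns: one per expanded-space parameter plus one per
    objective.  Predictions are clamped to the objective bounds (default
    [0, 100]).
    """
    param_names = list(expanded_space.parameter_names)
    missing = [p for p in param_names if p not in seed_dataset.columns]
    if missing:
        raise ValueError(f"expanded space parameter(s) {missing} missing from seed dataset")
    objective_names = [c for c in seed_dataset.columns if c not in param_names]
    if not objective_names:
        raise ValueError("seed dataset has no objective columns")
    if len(seed_dataset) < 50:
        raise ValueError("seed dataset must have at least 50 rows")

    conditions = apply_feasibility(enumerate_conditions(expanded_space), expanded_space)
    pool = encode_pool(expanded_space, conditions)

    tp = expanded_space.temperature_parameter
    seed_conditions = []
    for i, (_, row) in enumerate(seed_dataset.iterrows()):
        assignment = {}
        for p in expanded_space.parameters:
            v = row[p.name]
            if p.role == "temperature":
                v = float(v)
            if v not in p.values:
                raise ValueError(
                    f"seed dataset row {i}: value {v!r} not in expanded space "
                    f"parameter {p.name!r}"
                )
            assignment[p.name] = v
        seed_conditions.append(Condition(assignment, i))
    X_seed = encode_conditions(pool, seed_conditions)

    bounds = {name: (0.0, 100.0) for name in objective_names}
    if objective_bounds:
        bounds.update(objective_bounds)
    truth = np.empty((len(pool), len(objective_names)))
    models = []
    for j, name in enumerate(objective_names):
        y = seed_dataset[name].to_numpy(dtype=float)
        mlp = MLPRegressor(
            hidden_layer_sizes=hidden_layer_sizes,
            solver="lbfgs",
            max_iter=5000,
            random_state=(int(seed) + j) % (2**31 - 1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlp.fit(X_seed, y)
        lo, hi = bounds[name]
        truth[:, j] = np.clip(mlp.predict(pool.X), lo, hi)
        models.append(mlp)

    return BenchmarkOracle(
        pool=pool,
        truth=truth,
        objective_names=tuple(objective_names),
        noise_sd=np.zeros(len(objective_names)),
        clamp_bounds=tuple(bounds[name] for name in objective_names),
        provenance={"kind": "emulated", "seed": int(seed),
                    "n_seed_rows": int(len(seed_dataset)), "models": models},
    )


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class AlgorithmSpec:
    """How one benchmarked algorithm selects post-initialization batches."""

    strategy: str = "qnehvi"
    constraint: acq.BatchConstraint | None = None
    custom: Callable | None = None  # custom(model, pool, obs, q, rng) -> ids


@dataclass
class BenchmarkRunResult:
    results: pd.DataFrame  # columns: algorithm, seed, iteration, hv_percent

    def aggregate(self) -> pd.DataFrame:
        g = self.results.groupby(["algorithm", "iteration"])["hv_percent"]
        out = g.agg(["mean", "std"]).reset_index()
        return out.rename(columns={"mean": "hv_mean", "std": "hv_sd"})

    def final_means(self) -> pd.Series:
        last = self.results["iteration"].max()
        sub = self.results[self.results["iteration"] == last]
        return sub.groupby("algorithm")["hv_percent"].mean()

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence([int(p) % (2**31 - 1) for p in parts]).generate_state(1)[0] % (2**31 - 1))


def _fresh_pool(pool: CandidatePool) -> CandidatePool:
    return replace(pool, run_mask=np.zeros(len(pool), dtype=bool))


def _normalize_algorithms(algorithms) -> dict[str, AlgorithmSpec]:
    if isinstance(algorithms, Mapping):
        items = list(algorithms.items())
    else:
        items = []
        for entry in algorithms:
            if isinstance(entry, str):
                items.append((entry, AlgorithmSpec(strategy=entry)))
            else:
                items.append(tuple(entry))
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate algorithm labels")
    out = {}
    for label, spec in items:
        if isinstance(spec, str):
            spec = AlgorithmSpec(strategy=spec)
        out[label] = spec
    return out


def _pick_initial_temperatures(pool: CandidatePool, k: int, q: int,
                               rng: np.random.Generator) -> np.ndarray:
    temps = pool.temperature_values()
    levels = np.unique(temps)
    perm = rng.permutation(levels)
    chosen = perm[:k]
    if int(np.isin(temps, chosen).sum()) < q:
        # fall back to the k most populous levels
        counts = [(int((temps == t).sum()), t) for t in levels]
        counts.sort(key=lambda x: -x[0])
        chosen = np.asarray([t for _, t in counts[:k]])
        if int(np.isin(temps, chosen).sum()) < q:
            raise ValueError("cannot fill the initial batch within the temperature constraint")
    return chosen


def run_single_campaign(oracle: BenchmarkOracle, spec: AlgorithmSpec, q: int,
                        n_iterations: int, seed: int, mc_samples: int = 32,
                        noise_sd=None, n_restarts: int = 1) -> tuple[list[float], sg.ObservationSet]:
    """One simulated optimization campaign on the oracle; returns the per-
    iteration HV% trajectory (noise-free truth of everything selected so far
    vs the true front) and the final observation set."""
    pool = _fresh_pool(oracle.pool)
    ref = oracle.reference_point
    truth_front_pts = oracle.truth_front_points
    constraint = spec.constraint

    init_temps = None
    if constraint is not None and constraint.mode != "none":
        rng0 = np.random.default_rng(_derive_seed(seed, 0))
        init_temps = _pick_initial_temperatures(pool, constraint.max_unique, q, rng0)

    observations = sg.ObservationSet(
        condition_ids=np.zeros(0, dtype=int),
        Y=np.zeros((0, len(oracle.objective_names))),
        objective_names=oracle.objective_names,
        iteration_tags=np.zeros(0, dtype=int),
    )
    trajectory: list[float] = []
    model = None
    for it in range(1, n_iterations + 1):
        it_seed = _derive_seed(seed, it)
        if it == 1 or (spec.strategy == "sobol" and spec.custom is None
                       and constraint is None):
            sel = acq.sobol_batch(pool, q, seed=it_seed, allowed_temperatures=init_temps)
        else:
            model = sg.fit(pool, observations, seed=it_seed, n_restarts=n_restarts)
            if spec.custom is not None:
                ids = spec.custom(model, pool, observations, q,
                                  np.random.default_rng(it_seed))
                sel = acq.BatchSelection(list(map(int, ids)), np.zeros(len(ids)), "custom")
            else:
                cfg = acq.AcquisitionConfig(
                    strategy=spec.strategy, q=q, mc_samples=mc_samples, seed=it_seed
                )
                sel = acq.select_batch(spec.strategy, model, pool, cfg, constraint=constraint)
        ids = np.asarray(sel.condition_ids, dtype=int)
        Y = observe(oracle, ids, sigma_override=noise_sd, seed=_derive_seed(seed, it, 1))
        pool.mark_run(ids)
        observations = observations.extended(ids, Y, iteration=it)
        found_truth = oracle.truth[observations.condition_ids]
        trajectory.append(hypervolume_percent(found_truth, truth_front_pts, ref))
    return trajectory, observations


def run_benchmark(oracle: BenchmarkOracle, algorithms, q: int, n_iterations: int,
                  seeds: Sequence[int], mc_samples: int = 32, noise_sd=None,
                  n_restarts: int = 1) -> BenchmarkRunResult:
    """Repeated-seed benchmark: Sobol first plate, then algorithm batches,
    HV% after each iteration, aggregated over seeds."""
    specs = _normalize_algorithms(algorithms)
    if q * n_iterations > len(oracle.pool):
        raise ValueError("q * n_iterations exceeds the feasible pool size")
    rows = []
    for label, spec in specs.items():
        for seed in seeds:
            traj, _ = run_single_campaign(
                oracle, spec, q, n_iterations, int(seed),
                mc_samples=mc_samples, noise_sd=noise_sd, n_restarts=n_restarts,
            )
            for it, hv in enumerate(traj, start=1):
                rows.append({"algorithm": label, "seed": int(seed),
                             "iteration": it, "hv_percent": hv})
    return BenchmarkRunResult(results=pd.DataFrame(rows))


def oracle_to_csv(oracle: BenchmarkOracle, path) -> None:
    data = {"id": [c.id for c in oracle.pool.conditions]}
    for name in oracle.pool.space.parameter_names:
        data[name] = [c.assignment[name] for c in oracle.pool.conditions]
    for j, name in enumerate(oracle.objective_names):
        data[name] = oracle.truth[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def plot_benchmark(result: BenchmarkRunResult, path) -> None:
    """Mean HV% per iteration with a +-1 sd band, one line per algorithm."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = result.aggregate()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in agg.groupby("algorithm"):
        ax.plot(sub["iteration"], sub["hv_mean"], marker="o", label=label)
        sd = sub["hv_sd"].fillna(0.0)
        ax.fill_between(sub["iteration"], sub["hv_mean"] - sd, sub["hv_mean"] + sd, alpha=0.2)
    ax.set_xlabel("iteration")
    ax.set_ylabel("hypervolume (%)")
    ax.set_ylim(None, 101)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
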