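"""Batch selection of the next q reaction conditions from the un-run pool.

Strategies
----------
``sobol``
    scrambled low-discrepancy Sobol points in the feature unit hypercube,
    each mapped to the nearest un-run candidate (initial plate design).
``qnehvi``
    noisy expected hypervolume improvement: Monte-Carlo integration over
    joint posterior realizations that include the observed conditions and
    the pending batch picks (greedy-sequential construction with fantasy
    conditioning); the 2-D non-dominated staircase is rebuilt per sampled
    realization, which plays the role of a cached box decomposition.
``qnparego``
    randomized augmented Chebyshev scalarization
    ``s(y~) = min_i(w_i y~_i) + rho * sum_i(w_i y~_i)`` with a fresh simplex
    weight vector per batch slot and a noisy-expected-improvement estimate
    of the scalarized objective.
``tshvi``
    Thompson sampling: q joint posterior draws over the un-run pool; each
    draw picks the candidate maximizing the hypervolume improvement of its
    sampled objective vector over the observed Pareto front.
``utopia_exploit``
    purely exploitative distance ranking of posterior means to an ideal
    Utopia point (default (110, 110) AP).

Batch constraints on the number of unique temperatures are handled by two
wrappers: *naive* (run the inner strategy until k distinct temperatures
appear among the picks, then restrict the pool to those temperatures) and
*nested* (rank temperature levels by their mean single-point acquisition
value, keep the top k, then run the inner strategy on the restricted pool).

Everywhere: ties are broken by lowest pool id, batches never contain run
conditions or duplicates, and identical (model, pool, config, seed) yield
identical batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import qmc

from .pareto import Staircase2D, ParetoState, hvi, pareto_front, reference_point
from .space import CandidatePool
from .surrogate import SurrogateModel, _jittered_cholesky, sample_posterior

__all__ = [
    "AcquisitionConfig",
    "BatchConstraint",
    "BatchSelection",
    "sobol_batch",
    "qnehvi_batch",
    "qnparego_batch",
    "tshvi_batch",
    "utopia_exploit_batch",
    "constrained_batch",
    "select_batch",
    "score_candidates",
]

STRATEGIES = ("sobol", "qnehvi", "qnparego", "tshvi", "utopia_exploit")


@dataclass
class AcquisitionConfig:
    strategy: str = "qnehvi"
    q: int = 24
    mc_samples: int = 128
    rho: float = 0.05
    utopia_point: tuple[float, ...] = (110.0, 110.0)
    seed: int = 0
    weight_floor: float = 0.01

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.q < 0:
            raise ValueError("q must be nonnegative")


@dataclass
class BatchConstraint:
    parameter: str = "temperature"
    max_unique: int = 2
    mode: str = "nested"  # none | naive | nested

    def __post_init__(self):
        if self.max_unique < 1:
            raise ValueError("max_unique must be >= 1")
        if self.mode not in ("none", "naive", "nested"):
            raise ValueError(f"unknown constraint mode {self.mode!r}")


@dataclass
class BatchSelection:
    condition_ids: list[int]
    values: np.ndarray
    strategy: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.condition_ids)


# ---------------------------------------------------------------------------
# shared machinery


def augmented_chebyshev(y_norm: np.ndarray, weights: np.ndarray, rho: float) -> np.ndarray:
    """Augmented Chebyshev scalarization ``min_i(w_i y_i) + rho * sum_i(w_i y_i)``
    of objectives already normalized to [0, 1] (last axis = objectives)."""
    weighted = np.asarray(y_norm, dtype=float) * np.asarray(weights, dtype=float)
    return weighted.min(axis=-1) + rho * weighted.sum(axis=-1)


def _sorted_unrun(pool: CandidatePool) -> np.ndarray:
    return np.sort(pool.unrun_ids)


def _hvi_of_points(points: np.ndarray, front_points: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """HVI of each row of ``points`` over ``front_points`` (clipped at ref)."""
    if points.shape[1] == 2:
        return Staircase2D(front_points, ref).hvi_many(points)
    state = ParetoState.from_points(np.maximum(front_points, ref), ref)
    return np.asarray([hvi(np.maximum(p, ref), state) for p in points])


class _FantasyEngine:
    """Joint posterior realizations at anchor points with conditional
    candidate samples, per objective, in AP units.

    Anchors are the observed conditions plus pending batch picks; candidate
    values are drawn from the GP posterior conditioned on each sampled
    anchor realization (the "fantasy" in greedy-sequential batch
    construction).
    """

    def __init__(self, model: SurrogateModel, pool: CandidatePool,
                 cand_ids: np.ndarray, anchor_ids: np.ndarray,
                 n_samples: int, rng: np.random.Generator):
        Xc = pool.X[cand_ids]
        Xa = pool.X[anchor_ids]
        m = model.n_objectives
        S = n_samples
        N = len(cand_ids)
        self.anchor_samples = np.empty((S, len(anchor_ids), m))
        self.cand_samples = np.empty((S, N, m))
        for j, post in enumerate(model.posteriors):
            mu_a = post.mu_std(Xa)
            mu_c = post.mu_std(Xc)
            cov_aa = post.cov_std(Xa)
            La = _jittered_cholesky(cov_aa, allow_eigh=False)
            z = rng.standard_normal((S, len(anchor_ids)))
            f_a = mu_a[None, :] + z @ La.T  # (S, na) standardized
            C_ac = post.cov_std(Xa, Xc)  # (na, N)
            W = solve_triangular(La, C_ac, lower=True)  # (na, N)
            var_c = np.clip(
                post.var_std(Xc) - np.einsum("ij,ij->j", W, W), 0.0, None
            )
            U = solve_triangular(La, (f_a - mu_a[None, :]).T, lower=True)  # (na, S)
            cond_mean = mu_c[:, None] + W.T @ U  # (N, S)
            eps = rng.standard_normal((N, S))
            cand = cond_mean + np.sqrt(var_c)[:, None] * eps
            self.anchor_samples[:, :, j] = f_a * post.y_sd + post.y_mean
            self.cand_samples[:, :, j] = cand.T * post.y_sd + post.y_mean


class _StepperBase:
    """One-pick-at-a-time batch construction; ``allowed`` shrinks under
    constraints and always excludes run conditions and previous picks."""

    def __init__(self, model, pool, config: AcquisitionConfig):
        self.model = model
        self.pool = pool
        self.config = config
        self.picks: list[int] = []
        self.provenance: dict = {}

    def score_slot(self, allowed: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def next(self, allowed: np.ndarray) -> tuple[int, float]:
        allowed = np.asarray(allowed, dtype=int)
        if allowed.size == 0:
            raise ValueError("candidate pool exhausted")
        values = self.score_slot(allowed)
        k = int(np.argmax(values))  # first max -> lowest pool id (allowed sorted)
        cid = int(allowed[k])
        self.picks.append(cid)
        return cid, float(values[k])


class _SobolStepper(_StepperBase):
    def __init__(self, model, pool, config):
        super().__init__(model, pool, config)
        d = max(pool.n_features, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler = qmc.Sobol(d, scramble=True, seed=config.seed)
            self.points = sampler.random(config.q) if config.q > 0 else np.zeros((0, d))
        self.provenance["sobol_points"] = self.points.copy()

    def score_slot(self, allowed):
        point = self.points[len(self.picks)]
        X = self.pool.X[allowed]
        dists = np.linalg.norm(X - point[None, : X.shape[1]], axis=1)
        return -dists  # nearest candidate wins


class _UtopiaStepper(_StepperBase):
    def __init__(self, model, pool, config):
        super().__init__(model, pool, config)
        self.u = np.asarray(config.utopia_point, dtype=float)

    def score_slot(self, allowed):
        means = self.model.posterior_mean(self.pool, allowed)
        if means.shape[1] != self.u.shape[0]:
            raise ValueError("utopia point dimension mismatch")
        return -np.linalg.norm(means - self.u[None, :], axis=1)


class _TSHVIStepper(_StepperBase):
    def __init__(self, model, pool, config):
        super().__init__(model, pool, config)
        self.base_ids = _sorted_unrun(pool)
        self.index_of = {int(cid): i for i, cid in enumerate(self.base_ids)}
        self.samples = (
            sample_posterior(model, pool, self.base_ids, config.q, seed=config.seed)
            if config.q > 0
            else np.zeros((0, len(self.base_ids), model.n_objectives))
        )
        Y_obs = model.Y_train
        self.ref = reference_point(Y_obs)
        self.front_points = Y_obs[pareto_front(Y_obs)]
        self.provenance["fallback_slots"] = []

    def score_slot(self, allowed):
        draw = self.samples[len(self.picks)]
        rows = np.asarray([self.index_of[int(c)] for c in allowed])
        pts = draw[rows]
        values = _hvi_of_points(pts, self.front_points, self.ref)
        if values.max() <= 0.0:
            # all sampled points dominated: fall back to max sampled scalar sum
            self.provenance["fallback_slots"].append(len(self.picks))
            values = pts.sum(axis=1)
        return values


class _FantasyStepperBase(_StepperBase):
    """Common anchor bookkeeping for q-NEHVI and q-NParEgo."""

    def __init__(self, model, pool, config):
        super().__init__(model, pool, config)
        if config.mc_samples < 8:
            warnings.warn("mc_samples < 8: acquisition estimator is unusable")
        self.obs_ids = np.unique(model.train_ids)
        self.rng = np.random.default_rng(config.seed)
        Y_obs = model.Y_train
        self.ref = reference_point(Y_obs)
        self.obs_lo = Y_obs.min(axis=0)
        self.obs_hi = Y_obs.max(axis=0)

    def _engine(self, allowed):
        anchors = np.concatenate([self.obs_ids, np.asarray(self.picks, dtype=int)])
        return _FantasyEngine(
            self.model, self.pool, np.asarray(allowed, dtype=int), anchors,
            self.config.mc_samples, self.rng,
        )


class _QNEHVIStepper(_FantasyStepperBase):
    def score_slot(self, allowed):
        eng = self._engine(allowed)
        S = self.config.mc_samples
        total = np.zeros(len(allowed))
        for s in range(S):
            front = eng.anchor_samples[s]
            total += _hvi_of_points(eng.cand_samples[s], front, self.ref)
        return total / S


class _QNParEgoStepper(_FantasyStepperBase):
    def __init__(self, model, pool, config):
        super().__init__(model, pool, config)
        rng_w = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 17]))
        self.weights = []
        m = model.n_objectives
        span = self.obs_hi - self.obs_lo
        if np.any(span <= 0):
            warnings.warn(
                "degenerate observed range for an objective: normalization maps it to 0.5"
            )
        for _ in range(max(config.q, 1)):
            w = rng_w.exponential(size=m)
            w = w / w.sum()
            w = np.maximum(w, config.weight_floor)
            self.weights.append(w / w.sum())
        self.provenance["weights"] = [w.tolist() for w in self.weights]

    def _normalize(self, Y):
        span = self.obs_hi - self.obs_lo
        out = np.empty_like(Y)
        for j in range(Y.shape[-1]):
            if span[j] > 0:
                out[..., j] = (Y[..., j] - self.obs_lo[j]) / span[j]
            else:
                out[..., j] = 0.5
        return out

    def _scalarize(self, Y, w):
        return augmented_chebyshev(self._normalize(Y), w, self.config.rho)

    def score_slot(self, allowed):
        eng = self._engine(allowed)
        w = self.weights[min(len(self.picks), len(self.weights) - 1)]
        s_anchor = self._scalarize(eng.anchor_samples, w)  # (S, na)
        baseline = s_anchor.max(axis=1)  # (S,)
        s_cand = self._scalarize(eng.cand_samples, w)  # (S, N)
        improvement = np.clip(s_cand - baseline[:, None], 0.0, None)
        ei = improvement.mean(axis=0)
        if ei.max() <= 0.0:
            # degenerate (e.g. zero-variance) limit: no candidate improves on
            # the fantasized baseline, so rank by scalarized posterior mean
            self.provenance.setdefault("fallback_slots", []).append(len(self.picks))
            return s_cand.mean(axis=0)
        return ei


_STEPPERS = {
    "sobol": _SobolStepper,
    "qnehvi": _QNEHVIStepper,
    "qnparego": _QNParEgoStepper,
    "tshvi": _TSHVIStepper,
    "utopia_exploit": _UtopiaStepper,
}


def _allowed_ids(pool: CandidatePool, picks: list[int],
                 temp_levels: np.ndarray | None = None) -> np.ndarray:
    ids = _sorted_unrun(pool)
    if picks:
        ids = ids[~np.isin(ids, picks)]
    if temp_levels is not None:
        temps = pool.temperature_values()[ids]
        ids = ids[np.isin(temps, temp_levels)]
    return ids


def _run_unconstrained(stepper: _StepperBase, pool: CandidatePool, q: int,
                       temp_levels: np.ndarray | None = None) -> BatchSelection:
    values = []
    for _ in range(q):
        allowed = _allowed_ids(pool, stepper.picks, temp_levels)
        if allowed.size == 0:
            raise ValueError(
                f"cannot fill batch: {q - len(stepper.picks)} slots remain but no "
                "candidates are available"
            )
        _, val = stepper.next(allowed)
        values.append(val)
    prov = dict(stepper.provenance)
    prov.update({"strategy": stepper.config.strategy, "seed": stepper.config.seed})
    if temp_levels is not None:
        prov["allowed_temperatures"] = np.asarray(temp_levels, dtype=float).tolist()
    return BatchSelection(
        condition_ids=list(stepper.picks),
        values=np.asarray(values),
        strategy=stepper.config.strategy,
        provenance=prov,
    )


def select_batch(strategy: str, model: SurrogateModel | None, pool: CandidatePool,
                 config: AcquisitionConfig, constraint: BatchConstraint | None = None,
                 allowed_temperatures=None) -> BatchSelection:
    """Select the next batch with an optional unique-temperature constraint."""
    cfg = AcquisitionConfig(
        strategy=strategy, q=config.q, mc_samples=config.mc_samples, rho=config.rho,
        utopia_point=config.utopia_point, seed=config.seed,
        weight_floor=config.weight_floor,
    )
    if strategy != "sobol" and model is None:
        raise ValueError(f"strategy {strategy!r} requires a fitted model")
    temp_levels = (
        np.asarray(allowed_temperatures, dtype=float)
        if allowed_temperatures is not None
        else None
    )
    n_available = _allowed_ids(pool, [], temp_levels).size
    if cfg.q > n_available:
        raise ValueError(
            f"batch size {cfg.q} exceeds the {n_available} available candidates"
        )
    if constraint is None or constraint.mode == "none":
        stepper = _STEPPERS[strategy](model, pool, cfg)
        return _run_unconstrained(stepper, pool, cfg.q, temp_levels)
    return constrained_batch(strategy, constraint, model, pool, cfg.q, cfg.seed, config=cfg)


# ---------------------------------------------------------------------------
# public strategy wrappers


def sobol_batch(pool: CandidatePool, q: int, seed: int = 0,
                allowed_temperatures=None) -> BatchSelection:
    """Quasi-random initial plate: scrambled Sobol points mapped to the
    nearest un-run candidates in encoded-feature space."""
    cfg = AcquisitionConfig(strategy="sobol", q=q, seed=seed)
    return select_batch("sobol", None, pool, cfg, allowed_temperatures=allowed_temperatures)


def qnehvi_batch(model: SurrogateModel, pool: CandidatePool, q: int,
                 mc_samples: int = 128, seed: int = 0) -> BatchSelection:
    cfg = AcquisitionConfig(strategy="qnehvi", q=q, mc_samples=mc_samples, seed=seed)
    return select_batch("qnehvi", model, pool, cfg)


def qnparego_batch(model: SurrogateModel, pool: CandidatePool, q: int,
                   rho: float = 0.05, mc_samples: int = 128, seed: int = 0) -> BatchSelection:
    cfg = AcquisitionConfig(strategy="qnparego", q=q, rho=rho, mc_samples=mc_samples, seed=seed)
    return select_batch("qnparego", model, pool, cfg)


def tshvi_batch(model: SurrogateModel, pool: CandidatePool, q: int,
                seed: int = 0) -> BatchSelection:
    cfg = AcquisitionConfig(strategy="tshvi", q=q, seed=seed)
    return select_batch("tshvi", model, pool, cfg)


def utopia_exploit_batch(model: SurrogateModel, pool: CandidatePool, q: int,
                         u=(110.0, 110.0)) -> BatchSelection:
    cfg = AcquisitionConfig(strategy="utopia_exploit", q=q, utopia_point=tuple(u))
    return select_batch("utopia_exploit", model, pool, cfg)


# ---------------------------------------------------------------------------
# constraint handling


def score_candidates(strategy: str, model: SurrogateModel, pool: CandidatePool,
                     ids, config: AcquisitionConfig) -> np.ndarray:
    """Single-point (q=1) acquisition values for the given candidates."""
    ids = np.sort(np.asarray(ids, dtype=int))
    if strategy == "sobol":
        return np.zeros(len(ids))
    stepper = _STEPPERS[strategy](model, pool, config)
    return stepper.score_slot(ids)


def constrained_batch(inner_strategy: str, constraint: BatchConstraint,
                      model: SurrogateModel | None, pool: CandidatePool, q: int,
                      seed: int = 0, config: AcquisitionConfig | None = None) -> BatchSelection:
    """Batch selection with at most ``constraint.max_unique`` distinct values
    of the constrained parameter (typically temperature) per batch."""
    cfg = config or AcquisitionConfig(strategy=inner_strategy, q=q, seed=seed)
    if constraint.parameter != pool.space.temperature_parameter.name:
        # generic parameter constraints reuse the temperature machinery
        raise ValueError(
            f"constraint parameter {constraint.parameter!r} is not the space's "
            "temperature parameter"
        )
    temps = pool.temperature_values()
    k = constraint.max_unique
    unrun = _sorted_unrun(pool)
    level_counts = {t: int((temps[unrun] == t).sum()) for t in np.unique(temps[unrun])}
    levels_with_candidates = [t for t, c in level_counts.items() if c > 0]
    if len(levels_with_candidates) < min(k, len(level_counts)):
        raise ValueError("fewer temperature levels with candidates than the constraint allows")

    if constraint.mode == "nested":
        scores = score_candidates(inner_strategy, model, pool, unrun, cfg)
        order = {int(c): s for c, s in zip(np.sort(unrun), scores)}
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % 2**31, 23]))
        level_scores = []
        for t in sorted(level_counts):
            cand_t = unrun[temps[unrun] == t]
            if len(cand_t) > 5000:
                cand_t = rng.choice(cand_t, size=5000, replace=False)
            level_scores.append((float(np.mean([order[int(c)] for c in cand_t])), t))
        level_scores.sort(key=lambda x: (-x[0], x[1]))
        chosen = [t for _, t in level_scores[:k]]
        # ensure the restricted pool can fill q
        n_avail = int(np.isin(temps[unrun], chosen).sum())
        if n_avail < q:
            raise ValueError(
                f"infeasible fill: only {n_avail} candidates at the {k} selected "
                f"temperatures for a batch of {q} (shortfall {q - n_avail})"
            )
        stepper = _STEPPERS[inner_strategy](model, pool, cfg)
        sel = _run_unconstrained(stepper, pool, q, np.asarray(chosen, dtype=float))
        sel.provenance["constraint"] = {"mode": "nested", "temperatures": list(map(float, chosen))}
        return sel

    # naive: unrestricted picks until k distinct temperatures appear
    stepper = _STEPPERS[inner_strategy](model, pool, cfg)
    values = []
    temp_levels = None
    for _ in range(q):
        allowed = _allowed_ids(pool, stepper.picks, temp_levels)
        if allowed.size == 0:
            raise ValueError(
                f"infeasible fill: {q - len(stepper.picks)} slots remain but no "
                "candidates left at the constrained temperatures"
            )
        _, val = stepper.next(allowed)
        values.append(val)
        seen = np.unique(temps[np.asarray(stepper.picks, dtype=int)])
        if temp_levels is None and len(seen) >= constraint.max_unique:
            temp_levels = seen
    prov = dict(stepper.provenance)
    prov["constraint"] = {
        "mode": "naive",
        "temperatures": np.unique(temps[np.asarray(stepper.picks, dtype=int)]).tolist(),
    }
    prov.update({"strategy": inner_strategy, "seed": cfg.seed})
    return BatchSelection(
        condition_ids=list(stepper.picks),
        values=np.asarray(values),
        strategy=inner_strategy,
        provenance=prov,
    )
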