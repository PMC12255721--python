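"""Campaign orchestration: iterate suggest -> run -> ingest, persist state,
read/write SURF-style tables, and post-campaign feature analysis.

A campaign alternates between the optimizer suggesting a plate of reaction
conditions and the lab (or a benchmark oracle) returning measured AP values.
The first iteration always uses quasi-random Sobol sampling, optionally
restricted to configured initial temperatures (e.g. 70 and 100 degC); later
iterations use the configured acquisition strategy under the configured
batch constraint.  State persists as a human-inspectable directory:
``space.yaml``, ``pool.csv``, ``observations.surf``, ``history.json`` and
``config.yaml``.

The SURF dialect used here is a flat tab-separated table with one column per
reaction parameter, one numeric column per objective (empty cells mean the
reaction is still pending) and optional provenance columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from . import acquisition as acq
from . import surrogate as sg
from .benchlab import BenchmarkOracle, observe
from .pareto import hypervolume_percent
from .space import (
    CandidatePool,
    apply_feasibility,
    encode_pool,
    enumerate_conditions,
    load_space,
    pool_to_csv,
    save_space,
)

__all__ = [
    "CampaignConfig",
    "CampaignState",
    "new_campaign",
    "suggest_next",
    "ingest_values",
    "ingest_surf",
    "run_simulated_campaign",
    "read_surf",
    "write_surf",
    "save_campaign",
    "load_campaign",
    "feature_importance",
    "exact_shapley_values",
]

READY, AWAITING, FINISHED = "ready_to_suggest", "awaiting_results", "finished"


@dataclass
class CampaignConfig:
    objectives: tuple[str, ...] = ("AP_yield", "AP_selectivity")
    q: int = 96
    strategy: str = "qnehvi"
    seed: int = 1
    mc_samples: int = 128
    rho: float = 0.05
    utopia_point: tuple[float, ...] = (110.0, 110.0)
    constraint: acq.BatchConstraint | None = None
    init_temperatures: tuple[float, ...] | None = None
    n_restarts: int = 1


@dataclass
class CampaignState:
    pool: CandidatePool
    config: CampaignConfig
    observations: sg.ObservationSet
    history: list[dict] = field(default_factory=list)
    status: str = READY
    pending_ids: list[int] = field(default_factory=list)

    @property
    def iteration(self) -> int:
        """Number of batches suggested so far."""
        return len(self.history)


def new_campaign(pool: CandidatePool, config: CampaignConfig) -> CampaignState:
    obs = sg.ObservationSet(
        condition_ids=np.zeros(0, dtype=int),
        Y=np.zeros((0, len(config.objectives))),
        objective_names=config.objectives,
        iteration_tags=np.zeros(0, dtype=int),
    )
    return CampaignState(pool=pool, config=config, observations=obs)


def _iteration_seed(config: CampaignConfig, iteration: int) -> int:
    return int(
        np.random.SeedSequence([int(config.seed) % (2**31 - 1), iteration]).generate_state(1)[0]
        % (2**31 - 1)
    )


def suggest_next(state: CampaignState, strategy: str | None = None) -> acq.BatchSelection:
    """Suggest the next batch; iteration 1 uses Sobol, later iterations the
    configured (or overridden) strategy.  Deterministic given state + seed."""
    if state.status == AWAITING:
        raise RuntimeError("cannot suggest: awaiting results for the previous batch")
    if state.status == FINISHED:
        raise RuntimeError("campaign is finished")
    cfg = state.config
    iteration = state.iteration + 1
    it_seed = _iteration_seed(cfg, iteration)
    if iteration == 1:
        sel = acq.sobol_batch(
            state.pool, cfg.q, seed=it_seed, allowed_temperatures=cfg.init_temperatures
        )
        used = "sobol"
    else:
        used = strategy or cfg.strategy
        model = sg.fit(state.pool, state.observations, seed=it_seed, n_restarts=cfg.n_restarts)
        acq_cfg = acq.AcquisitionConfig(
            strategy=used, q=cfg.q, mc_samples=cfg.mc_samples, rho=cfg.rho,
            utopia_point=cfg.utopia_point, seed=it_seed,
        )
        sel = acq.select_batch(used, model, state.pool, acq_cfg, constraint=cfg.constraint)
    state.pool.mark_run(sel.condition_ids)
    state.history.append(
        {
            "iteration": iteration,
            "strategy": used,
            "seed": it_seed,
            "condition_ids": [int(c) for c in sel.condition_ids],
            "values": np.asarray(sel.values, dtype=float).tolist(),
        }
    )
    state.pending_ids = [int(c) for c in sel.condition_ids]
    state.status = AWAITING
    return sel


def ingest_values(state: CampaignState, ids, Y) -> None:
    """Record measured objective vectors for (a subset of) the pending batch."""
    if state.status != AWAITING:
        raise RuntimeError("no batch awaiting results")
    ids = [int(i) for i in np.asarray(ids, dtype=int)]
    unknown = [i for i in ids if i not in state.pending_ids]
    if unknown:
        raise ValueError(f"ids {unknown} are not pending in the current batch")
    state.observations = state.observations.extended(ids, Y, iteration=state.iteration)
    state.pending_ids = [i for i in state.pending_ids if i not in set(ids)]
    if not state.pending_ids:
        state.status = READY


def ingest_surf(state: CampaignState, path) -> int:
    """Ingest completed rows from a SURF results file; returns the number of
    observations added (rows with empty objective cells stay pending)."""
    obs, _ = read_surf(path, state.pool, state.config.objectives)
    mask = np.isin(obs.condition_ids, state.pending_ids)
    ingest_values(state, obs.condition_ids[mask], obs.Y[mask])
    return int(mask.sum())


def finish(state: CampaignState) -> None:
    state.status = FINISHED


# ---------------------------------------------------------------------------
# SURF-style tables


def write_surf(path, pool: CandidatePool, ids, objective_names: Sequence[str],
               Y: np.ndarray | None = None, iterations=None) -> None:
    """Write a SURF-style TSV: reaction_id, parameter columns, objective
    columns (empty when pending), and an iteration provenance column."""
    ids = np.asarray(ids, dtype=int)
    data: dict = {"reaction_id": ids}
    for name in pool.space.parameter_names:
        col = pool.parameter_column(name)[ids]
        data[name] = col
    for j, obj in enumerate(objective_names):
        if Y is None:
            data[obj] = ["" for _ in ids]
        else:
            data[obj] = np.asarray(Y, dtype=float)[:, j]
    if iterations is not None:
        data["iteration"] = np.asarray(iterations, dtype=int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_batch_csv(path, pool: CandidatePool, selection: acq.BatchSelection) -> None:
    """Export a suggested batch as CSV: rank, id, parameter columns,
    acquisition value."""
    ids = np.asarray(selection.condition_ids, dtype=int)
    data: dict = {"rank": np.arange(1, len(ids) + 1), "id": ids}
    for name in pool.space.parameter_names:
        data[name] = pool.parameter_column(name)[ids]
    data["acquisition_value"] = np.asarray(selection.values, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def read_surf(path, pool: CandidatePool,
              objective_names: Sequence[str]) -> tuple[sg.ObservationSet, int]:
    """Read a SURF-style TSV back into an ObservationSet.

    Rows with complete objective cells become observations; incomplete rows
    are counted as pending.  Condition labels (parameter columns) are
    resolved to pool ids; unresolvable rows raise with their row numbers.
    Column order does not matter.
    """
    df = pd.read_csv(path, sep="\t")
    for obj in objective_names:
        if obj not in df.columns:
            raise ValueError(f"missing objective column {obj!r}")
    missing_params = [p for p in pool.space.parameter_names if p not in df.columns]
    if missing_params:
        raise ValueError(f"missing parameter column(s) {missing_params}")
    ids, Y_rows, tags, bad_rows = [], [], [], []
    n_pending = 0
    has_iter = "iteration" in df.columns
    for i, row in df.iterrows():
        yvals = [row[obj] for obj in objective_names]
        if any(pd.isna(v) or (isinstance(v, str) and not v.strip()) for v in yvals):
            n_pending += 1
            continue
        assignment = {name: row[name] for name in pool.space.parameter_names}
        try:
            cid = pool.id_of(assignment)
        except KeyError:
            bad_rows.append(int(i) + 2)  # 1-based line number incl. header
            continue
        ids.append(cid)
        Y_rows.append([float(v) for v in yvals])
        tags.append(int(row["iteration"]) if has_iter else 1)
    if bad_rows:
        raise ValueError(f"unresolvable condition(s) at line(s) {bad_rows}")
    obs = sg.ObservationSet(
        condition_ids=np.asarray(ids, dtype=int),
        Y=np.asarray(Y_rows, dtype=float).reshape(len(ids), len(objective_names)),
        objective_names=tuple(objective_names),
        iteration_tags=np.asarray(tags, dtype=int),
    )
    return obs, n_pending


# ---------------------------------------------------------------------------
# persistence


def save_campaign(state: CampaignState, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_space(state.pool.space, directory)
    pool_to_csv(state.pool, directory / "pool.csv")
    write_surf(
        directory / "observations.surf",
        state.pool,
        state.observations.condition_ids,
        state.config.objectives,
        Y=state.observations.Y,
        iterations=state.observations.iteration_tags,
    )
    cfg = asdict(state.config)
    if state.config.constraint is not None:
        cfg["constraint"] = asdict(state.config.constraint)
    with open(directory / "config.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(cfg, fh, sort_keys=False)
    with open(directory / "history.json", "w") as fh:
        json.dump(
            {
                "history": state.history,
                "status": state.status,
                "pending_ids": state.pending_ids,
            },
            fh,
            indent=1,
        )


def load_campaign(directory) -> CampaignState:
    directory = Path(directory)
    space = load_space(directory / "space.yaml")
    conditions = apply_feasibility(enumerate_conditions(space), space)
    pool = encode_pool(space, conditions)
    import yaml

    with open(directory / "config.yaml") as fh:
        cfg_doc = yaml.safe_load(fh)
    constraint = cfg_doc.pop("constraint", None)
    if constraint:
        constraint = acq.BatchConstraint(**constraint)
    for key in ("objectives", "utopia_point", "init_temperatures"):
        if cfg_doc.get(key) is not None:
            cfg_doc[key] = tuple(cfg_doc[key])
    config = CampaignConfig(constraint=constraint, **cfg_doc)
    with open(directory / "history.json") as fh:
        doc = json.load(fh)
    obs, _ = read_surf(directory / "observations.surf", pool, config.objectives)
    state = CampaignState(
        pool=pool,
        config=config,
        observations=obs,
        history=doc["history"],
        status=doc["status"],
        pending_ids=[int(i) for i in doc["pending_ids"]],
    )
    for entry in state.history:
        pool.mark_run(entry["condition_ids"])
    return state


# ---------------------------------------------------------------------------
# simulated campaigns


def run_simulated_campaign(state: CampaignState, oracle: BenchmarkOracle,
                           n_iterations: int) -> tuple[CampaignState, list[float]]:
    """Alternate suggest_next and oracle observation for ``n_iterations``;
    returns the state and the per-iteration HV% trajectory against the
    oracle's true front."""
    if len(oracle.pool) != len(state.pool):
        raise ValueError("oracle does not cover the campaign pool")
    trajectory = []
    ref = oracle.reference_point
    truth_front_pts = oracle.truth_front_points
    for _ in range(n_iterations):
        sel = suggest_next(state)
        ids = np.asarray(sel.condition_ids, dtype=int)
        obs_seed = _iteration_seed(state.config, state.iteration) ^ 0x5EED
        Y = observe(oracle, ids, seed=obs_seed % (2**31 - 1))
        ingest_values(state, ids, Y)
        found = oracle.truth[state.observations.condition_ids]
        trajectory.append(hypervolume_percent(found, truth_front_pts, ref))
    return state, trajectory


# ---------------------------------------------------------------------------
# feature analysis


def feature_importance(pool: CandidatePool, observations: sg.ObservationSet,
                       target_objective: str, seed: int = 0,
                       n_repeats: int = 10) -> pd.DataFrame:
    """Mean-absolute permutation importance of each encoded feature for one
    objective, from an ensemble-of-trees surrogate; descending.

    Features are labelled by parameter/value (e.g. one-hot precatalyst
    flags), mirroring how influential reaction parameters are read off a
    trained surrogate after a campaign.
    """
    if len(observations) < 50:
        raise ValueError("feature importance requires at least 50 observations")
    j = list(observations.objective_names).index(target_objective)
    X = pool.X[observations.condition_ids]
    y = observations.Y[:, j]
    if y.std() < 1e-12:
        warnings.warn("constant target: all importances are 0")
        return pd.DataFrame(
            {"feature": pool.feature_names, "importance": np.zeros(pool.n_features)}
        )
    rf = RandomForestRegressor(n_estimators=200, random_state=int(seed) % (2**31 - 1))
    rf.fit(X, y)
    r = permutation_importance(
        rf, X, y, n_repeats=n_repeats, random_state=(int(seed) + 1) % (2**31 - 1)
    )
    imp = np.abs(r.importances).mean(axis=1)
    out = pd.DataFrame({"feature": pool.feature_names, "importance": imp})
    return out.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


def exact_shapley_values(predict_fn, X_background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values of one prediction by brute-force subset
    enumeration (test oracle; at most 12 features).

    ``v(S)`` is the mean prediction over the background rows with the
    features in S replaced by the instance's values.
    """
    X_background = np.asarray(X_background, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    p = x.shape[0]
    if p > 12:
        raise ValueError("exact Shapley enumeration is limited to 12 features")
    from math import factorial

    n_masks = 1 << p
    v = np.empty(n_masks)
    for mask in range(n_masks):
        Z = X_background.copy()
        for i in range(p):
            if mask >> i & 1:
                Z[:, i] = x[i]
        v[mask] = float(np.mean(predict_fn(Z)))
    phi = np.zeros(p)
    fact = [factorial(k) for k in range(p + 1)]
    for mask in range(n_masks):
        s = bin(mask).count("1")
        for i in range(p):
            if not (mask >> i & 1):
                w = fact[s] * fact[p - s - 1] / fact[p]
                phi[i] += w * (v[mask | (1 << i)] - v[mask])
    return phi
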