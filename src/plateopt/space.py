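"""Discrete combinatorial reaction-condition search spaces.

A search space is an ordered list of reaction parameters (ligand, precatalyst,
base, solvent, co-solvent, temperature, ...), each with a finite list of
values.  The candidate set is the Cartesian product of those value lists,
optionally filtered by feasibility rules (e.g. the reaction temperature must
not exceed the boiling point of the solvent), and numerically encoded into a
feature matrix on which Gaussian-process surrogates operate.

Featurization choices per parameter:

``one_hot``
    one binary column per value.
``numeric``
    a single numeric column (temperature).
``descriptor``
    the parameter's descriptor vector (e.g. DFT/COSMO descriptors per
    solvent), one column per descriptor dimension.
``descriptor_pca``
    the descriptor vector projected onto the leading principal components
    that reach a configured explained-variance threshold.

All encoded columns are min-max scaled to [0, 1] over the feasible pool;
columns that are constant over the pool are dropped (and recorded).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

__all__ = [
    "ParameterDef",
    "FeasibilityRule",
    "FeaturizationSpec",
    "SearchSpace",
    "Condition",
    "CandidatePool",
    "PCAProjection",
    "enumerate_conditions",
    "apply_feasibility",
    "fit_pca_reduction",
    "encode_pool",
    "encode_conditions",
    "load_space",
    "save_space",
    "pool_to_csv",
]

TEMPERATURE_ROLE = "temperature"
CATEGORICAL_ROLE = "categorical"


@dataclass(frozen=True)
class ParameterDef:
    """One reaction parameter and its admissible values.

    ``boiling_points`` is only meaningful for solvent-like parameters and is
    consulted by the temperature feasibility rule.
    """

    name: str
    values: tuple
    role: str = CATEGORICAL_ROLE
    descriptors: Mapping[str, np.ndarray] | None = None
    boiling_points: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.role not in (CATEGORICAL_ROLE, TEMPERATURE_ROLE):
            raise ValueError(f"unknown parameter role {self.role!r}")
        if len(self.values) == 0:
            raise ValueError(f"parameter {self.name!r} has no values")
        if len(set(self.values)) != len(self.values):
            raise ValueError(f"parameter {self.name!r} has duplicate value labels")
        if self.role == TEMPERATURE_ROLE:
            for v in self.values:
                if not np.isfinite(float(v)):
                    raise ValueError(f"non-finite temperature {v!r} in {self.name!r}")
        if self.descriptors is not None:
            lengths = {len(np.atleast_1d(v)) for v in self.descriptors.values()}
            if len(lengths) > 1:
                raise ValueError(
                    f"descriptor vectors for {self.name!r} have unequal lengths"
                )


@dataclass(frozen=True)
class FeasibilityRule:
    """A pure predicate over a single condition.

    ``max_temperature_le_boiling_point`` keeps a condition iff the assigned
    temperature is <= the boiling point of every in-scope solvent-like value
    (equality kept: only *exceeding* the boiling point is infeasible).

    ``forbidden_combination`` rejects a condition iff it matches the given
    parameter->value assignment exactly on all named parameters (e.g. the
    unsafe NaH + DMSO pairing).
    """

    kind: str
    scope: tuple[str, ...]
    forbidden: Mapping[str, object] | None = None

    def __post_init__(self):
        if self.kind not in ("max_temperature_le_boiling_point", "forbidden_combination"):
            raise ValueError(f"unknown feasibility rule kind {self.kind!r}")
        if self.kind == "forbidden_combination" and not self.forbidden:
            raise ValueError("forbidden_combination rule requires a 'forbidden' mapping")


@dataclass(frozen=True)
class FeaturizationSpec:
    method: str  # one_hot | numeric | descriptor | descriptor_pca
    variance_threshold: float | None = None

    def __post_init__(self):
        if self.method not in ("one_hot", "numeric", "descriptor", "descriptor_pca"):
            raise ValueError(f"unknown featurization method {self.method!r}")
        if self.method == "descriptor_pca":
            t = self.variance_threshold
            if t is None or not (0.0 < t <= 1.0):
                raise ValueError("descriptor_pca requires 0 < variance_threshold <= 1")


@dataclass(frozen=True)
class SearchSpace:
    parameters: tuple[ParameterDef, ...]
    feasibility_rules: tuple[FeasibilityRule, ...] = ()
    featurization: Mapping[str, FeaturizationSpec] | None = None

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        n_temp = sum(p.role == TEMPERATURE_ROLE for p in self.parameters)
        if n_temp > 1:
            raise ValueError("at most one temperature-role parameter is allowed")
        for rule in self.feasibility_rules:
            for pname in rule.scope:
                if pname not in names:
                    raise ValueError(f"feasibility rule references unknown parameter {pname!r}")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def parameter(self, name: str) -> ParameterDef:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def temperature_parameter(self) -> ParameterDef | None:
        for p in self.parameters:
            if p.role == TEMPERATURE_ROLE:
                return p
        return None

    def default_featurization(self) -> dict[str, FeaturizationSpec]:
        plan: dict[str, FeaturizationSpec] = {}
        for p in self.parameters:
            if p.role == TEMPERATURE_ROLE:
                plan[p.name] = FeaturizationSpec("numeric")
            elif p.descriptors is not None:
                plan[p.name] = FeaturizationSpec("descriptor")
            else:
                plan[p.name] = FeaturizationSpec("one_hot")
        return plan

    def resolved_featurization(self) -> dict[str, FeaturizationSpec]:
        plan = self.default_featurization()
        if self.featurization:
            plan.update(self.featurization)
        for p in self.parameters:
            spec = plan[p.name]
            if spec.method in ("descriptor", "descriptor_pca"):
                if p.descriptors is None:
                    raise ValueError(
                        f"parameter {p.name!r} is descriptor-featurized but has no descriptor table"
                    )
                missing = [v for v in p.values if v not in p.descriptors]
                if missing:
                    raise ValueError(
                        f"descriptor table for {p.name!r} is missing values {missing}"
                    )
        return plan


@dataclass(frozen=True)
class Condition:
    """One fully specified combination of reaction-parameter values."""

    assignment: Mapping[str, object]
    id: int

    def __getitem__(self, key):
        return self.assignment[key]


def enumerate_conditions(space: SearchSpace) -> list[Condition]:
    """Full Cartesian product in lexicographic order of parameter definition.

    The count equals the product of per-parameter value counts; ids are
    0-based enumeration indices.
    """
    if len(space.parameters) == 0:
        raise ValueError("empty space")
    names = space.parameter_names
    out = []
    for i, combo in enumerate(itertools.product(*(p.values for p in space.parameters))):
        out.append(Condition(dict(zip(names, combo)), i))
    return out


def _rule_passes(rule: FeasibilityRule, cond: Condition, space: SearchSpace) -> bool:
    if rule.kind == "forbidden_combination":
        return any(cond.assignment[k] != v for k, v in rule.forbidden.items())
    # max_temperature_le_boiling_point
    temp_param = space.temperature_parameter
    if temp_param is None:
        raise ValueError("temperature rule in a space without a temperature parameter")
    temperature = float(cond.assignment[temp_param.name])
    for pname in rule.scope:
        if pname == temp_param.name:
            continue
        param = space.parameter(pname)
        value = cond.assignment[pname]
        bps = param.boiling_points or {}
        if value not in bps:
            raise ValueError(
                f"missing boiling point for value {value!r} of parameter {pname!r}"
            )
        if temperature > float(bps[value]):
            return False
    return True


def apply_feasibility(conditions: Sequence[Condition], space: SearchSpace) -> list[Condition]:
    """Keep a condition iff every feasibility rule passes.

    Order is preserved and ids are re-assigned contiguously from 0.
    """
    kept = []
    for cond in conditions:
        if all(_rule_passes(rule, cond, space) for rule in space.feasibility_rules):
            kept.append(cond)
    return [Condition(c.assignment, i) for i, c in enumerate(kept)]


@dataclass(frozen=True)
class PCAProjection:
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    n_components: int
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"expected {self.mean.shape[0]} descriptor columns, got {X.shape[1]}"
            )
        return (X - self.mean) @ self.components.T


def fit_pca_reduction(descriptor_matrix: np.ndarray, variance_threshold: float) -> PCAProjection:
    """Fit a PCA projection keeping the smallest number of components whose
    cumulative explained-variance ratio reaches ``variance_threshold``."""
    X = np.asarray(descriptor_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("descriptor matrix must have at least 2 rows")
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance threshold must be in (0, 1]")
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("no variance in descriptor matrix")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    ratios = pca.explained_variance_ratio_
    # Drop numerically-zero directions so a rank-k matrix yields k components
    # even at threshold 1.0.
    nonzero = ratios > 1e-12
    ratios = ratios[nonzero]
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    return PCAProjection(
        mean=pca.mean_.copy(),
        components=pca.components_[:k].copy(),
        n_components=k,
        explained_variance_ratio=ratios[:k].copy(),
    )


@dataclass
class CandidatePool:
    """Encoded feature matrix over the enumerated feasible conditions.

    ``X`` rows follow condition ids; every column is min-max scaled to [0, 1]
    over the pool and constant columns are dropped (names in
    ``dropped_features``).  ``run_mask[i]`` is True once condition i has been
    sent to the lab (or oracle).
    """

    space: SearchSpace
    conditions: list[Condition]
    X: np.ndarray
    feature_names: list[str]
    run_mask: np.ndarray
    col_mins: np.ndarray
    col_ranges: np.ndarray
    dropped_features: list[str] = field(default_factory=list)
    _raw_encoder: Callable | None = field(default=None, repr=False)
    _id_lookup: dict | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def unrun_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.run_mask)

    def mark_run(self, ids: Iterable[int]) -> None:
        self.run_mask[np.asarray(list(ids), dtype=int)] = True

    def parameter_column(self, name: str) -> np.ndarray:
        return np.asarray([c.assignment[name] for c in self.conditions], dtype=object)

    def temperature_values(self) -> np.ndarray:
        tp = self.space.temperature_parameter
        if tp is None:
            raise ValueError("pool's space has no temperature parameter")
        return np.asarray([float(c.assignment[tp.name]) for c in self.conditions])

    def _canon(self, name: str, value) -> str:
        param = self.space.parameter(name)
        if param.role == TEMPERATURE_ROLE:
            return f"{float(value):.6g}"
        return str(value)

    def id_of(self, assignment: Mapping[str, object]) -> int:
        """Resolve a full parameter assignment to a pool id."""
        if self._id_lookup is None:
            names = self.space.parameter_names
            self._id_lookup = {
                tuple(self._canon(n, c.assignment[n]) for n in names): c.id
                for c in self.conditions
            }
        key = tuple(self._canon(n, assignment[n]) for n in self.space.parameter_names)
        try:
            return self._id_lookup[key]
        except KeyError:
            raise KeyError(f"no pool condition with assignment {dict(assignment)!r}") from None

    def decode(self, row_index: int) -> dict:
        return dict(self.conditions[row_index].assignment)


def _encode_raw(space: SearchSpace, conditions: Sequence[Condition],
                plan: Mapping[str, FeaturizationSpec],
                projections: Mapping[str, PCAProjection]) -> tuple[np.ndarray, list[str]]:
    columns: list[np.ndarray] = []
    names: list[str] = []
    n = len(conditions)
    for p in space.parameters:
        spec = plan[p.name]
        values = [c.assignment[p.name] for c in conditions]
        if spec.method == "numeric":
            columns.append(np.asarray(values, dtype=float)[:, None])
            names.append(p.name)
        elif spec.method == "one_hot":
            for v in p.values:
                col = np.fromiter((1.0 if x == v else 0.0 for x in values), float, count=n)
                columns.append(col[:, None])
                names.append(f"{p.name}={v}")
        else:
            table = p.descriptors
            missing = sorted({str(v) for v in values if v not in table})
            if missing:
                raise ValueError(
                    f"value(s) {missing} of parameter {p.name!r} absent from descriptor table"
                )
            mat = np.vstack([np.atleast_1d(np.asarray(table[v], dtype=float)) for v in values])
            if spec.method == "descriptor_pca":
                mat = projections[p.name].transform(mat)
                names.extend(f"{p.name}_PC{i + 1}" for i in range(mat.shape[1]))
            else:
                names.extend(f"{p.name}_D{i + 1}" for i in range(mat.shape[1]))
            columns.append(mat)
    X = np.hstack(columns) if columns else np.zeros((n, 0))
    return X, names


def encode_pool(space: SearchSpace, conditions: Sequence[Condition]) -> CandidatePool:
    """Encode feasible conditions into a [0, 1]-scaled feature matrix.

    PCA projections for ``descriptor_pca`` parameters are fitted once on the
    parameter's full descriptor table (all values in the space), keeping
    feature meaning stable across a campaign.  Encoding is deterministic
    given the space and plan.
    """
    plan = space.resolved_featurization()
    projections: dict[str, PCAProjection] = {}
    for p in space.parameters:
        if plan[p.name].method == "descriptor_pca":
            table = np.vstack(
                [np.atleast_1d(np.asarray(p.descriptors[v], dtype=float)) for v in p.values]
            )
            projections[p.name] = fit_pca_reduction(table, plan[p.name].variance_threshold)

    X_raw, names = _encode_raw(space, conditions, plan, projections)
    mins = X_raw.min(axis=0) if len(conditions) else np.zeros(X_raw.shape[1])
    maxs = X_raw.max(axis=0) if len(conditions) else np.ones(X_raw.shape[1])
    ranges = maxs - mins
    keep = ranges > 1e-12
    dropped = [n for n, k in zip(names, keep) if not k]
    X = (X_raw[:, keep] - mins[keep]) / ranges[keep]

    def raw_encoder(conds: Sequence[Condition]) -> np.ndarray:
        Xr, _ = _encode_raw(space, conds, plan, projections)
        return Xr

    return CandidatePool(
        space=space,
        conditions=list(conditions),
        X=X,
        feature_names=[n for n, k in zip(names, keep) if k],
        run_mask=np.zeros(len(conditions), dtype=bool),
        col_mins=mins[keep],
        col_ranges=ranges[keep],
        dropped_features=dropped,
        _raw_encoder=raw_encoder,
    )


def encode_conditions(pool: CandidatePool, conditions: Sequence[Condition]) -> np.ndarray:
    """Encode arbitrary conditions with the pool's featurization and scaling.

    Used to featurize seed observations whose conditions may come from a
    smaller grid than the pool (e.g. fewer temperature levels).
    """
    X_raw = pool._raw_encoder(conditions)
    # _raw_encoder returns the unpruned layout; rebuild the kept-column mask
    # from the recorded dropped names.
    plan = pool.space.resolved_featurization()
    all_names = _encode_raw(pool.space, pool.conditions[:1], plan, _projections_of(pool))[1]
    keep_cols = np.asarray([n not in pool.dropped_features for n in all_names])
    X = X_raw[:, keep_cols]
    return (X - pool.col_mins) / pool.col_ranges


def _projections_of(pool: CandidatePool) -> dict[str, PCAProjection]:
    # Projections are embedded in the raw encoder closure; re-fit deterministically.
    plan = pool.space.resolved_featurization()
    projections = {}
    for p in pool.space.parameters:
        if plan[p.name].method == "descriptor_pca":
            table = np.vstack(
                [np.atleast_1d(np.asarray(p.descriptors[v], dtype=float)) for v in p.values]
            )
            projections[p.name] = fit_pca_reduction(table, plan[p.name].variance_threshold)
    return projections


# ---------------------------------------------------------------------------
# YAML space files


def _parse_rule(entry: Mapping) -> FeasibilityRule:
    return FeasibilityRule(
        kind=entry["kind"],
        scope=tuple(entry.get("scope", ())),
        forbidden=entry.get("forbidden"),
    )


def load_space(path: str | Path) -> SearchSpace:
    """Load a search space from YAML.

    Layout::

        parameters:
          - name: solvent
            role: categorical
            values: [MeOH, THF]
            descriptors: solvents.csv      # optional, path relative to the YAML
            boiling_point: {MeOH: 65, THF: 66}
          - name: temperature
            role: temperature
            values: [40, 55, 70]
        feasibility:
          - kind: max_temperature_le_boiling_point
            scope: [solvent]
        featurization:
          solvent: {method: descriptor_pca, variance_threshold: 0.99}

    Descriptor CSVs have the value label in the first column and numeric
    descriptor columns after it.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = []
    for entry in doc["parameters"]:
        descriptors = None
        if entry.get("descriptors"):
            csv_path = Path(entry["descriptors"])
            if not csv_path.is_absolute():
                csv_path = path.parent / csv_path
            table = pd.read_csv(csv_path)
            label_col = table.columns[0]
            descriptors = {
                str(row[label_col]): row.iloc[1:].to_numpy(dtype=float)
                for _, row in table.iterrows()
            }
        role = entry.get("role", CATEGORICAL_ROLE)
        values = tuple(entry["values"])
        if role == TEMPERATURE_ROLE:
            values = tuple(float(v) for v in values)
        params.append(
            ParameterDef(
                name=entry["name"],
                values=values,
                role=role,
                descriptors=descriptors,
                boiling_points=entry.get("boiling_point"),
            )
        )
    rules = tuple(_parse_rule(r) for r in doc.get("feasibility", ()))
    plan = None
    if doc.get("featurization"):
        plan = {
            name: FeaturizationSpec(
                method=spec["method"] if isinstance(spec, Mapping) else spec,
                variance_threshold=spec.get("variance_threshold")
                if isinstance(spec, Mapping)
                else None,
            )
            for name, spec in doc["featurization"].items()
        }
    return SearchSpace(tuple(params), rules, plan)


def save_space(space: SearchSpace, directory: str | Path) -> Path:
    """Write ``space.yaml`` (plus descriptor CSVs) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc: dict = {"parameters": []}
    for p in space.parameters:
        entry: dict = {"name": p.name, "role": p.role, "values": list(p.values)}
        if p.descriptors is not None:
            csv_name = f"descriptors_{p.name}.csv"
            rows = []
            for v in p.values:
                vec = np.atleast_1d(np.asarray(p.descriptors[v], dtype=float))
                rows.append([v, *vec.tolist()])
            width = len(rows[0]) - 1
            pd.DataFrame(rows, columns=["value", *[f"d{i+1}" for i in range(width)]]).to_csv(
                directory / csv_name, index=False
            )
            entry["descriptors"] = csv_name
        if p.boiling_points is not None:
            entry["boiling_point"] = {str(k): float(v) for k, v in p.boiling_points.items()}
        doc["parameters"].append(entry)
    if space.feasibility_rules:
        doc["feasibility"] = [
            {
                "kind": r.kind,
                "scope": list(r.scope),
                **({"forbidden": dict(r.forbidden)} if r.forbidden else {}),
            }
            for r in space.feasibility_rules
        ]
    if space.featurization:
        doc["featurization"] = {
            name: {
                "method": spec.method,
                **(
                    {"variance_threshold": spec.variance_threshold}
                    if spec.variance_threshold is not None
                    else {}
                ),
            }
            for name, spec in space.featurization.items()
        }
    out = directory / "space.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return out


def pool_to_csv(pool: CandidatePool, path: str | Path) -> None:
    """Export the pool: id, parameter columns, then feature columns."""
    data = {"id": [c.id for c in pool.conditions]}
    for name in pool.space.parameter_names:
        data[name] = [c.assignment[name] for c in pool.conditions]
    for j, fname in enumerate(pool.feature_names):
        data[fname] = pool.X[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
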