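"""Shared fixtures: toy search spaces, tiny benchmark oracles, and
deterministic stub posteriors for exact brute-force comparisons."""

from __future__ import annotations

import numpy as np
import pytest

from plateopt import benchlab
from plateopt.space import (
    FeasibilityRule,
    ParameterDef,
    SearchSpace,
    apply_feasibility,
    encode_pool,
    enumerate_conditions,
)
from plateopt.surrogate import ObservationSet, SurrogateModel


@pytest.fixture
def toy_space() -> SearchSpace:
    """Two categoricals, a solvent with boiling points, and five temperatures."""
    return SearchSpace(
        parameters=(
            ParameterDef("base", ("K3PO4", "KOH", "DBU")),
            ParameterDef("solvent", ("MeOH", "THF"),
                         boiling_points={"MeOH": 65.0, "THF": 120.0}),
            ParameterDef("temperature", (40.0, 55.0, 70.0, 85.0, 100.0), role="temperature"),
        ),
        feasibility_rules=(
            FeasibilityRule("max_temperature_le_boiling_point", scope=("solvent",)),
        ),
    )


@pytest.fixture
def toy_pool(toy_space):
    conditions = apply_feasibility(enumerate_conditions(toy_space), toy_space)
    return encode_pool(toy_space, conditions)


@pytest.fixture(scope="session")
def small_oracle():
    """A small synthetic landscape (3 temps x 3 solvents x 4 ligands x 3 bases)."""
    return benchlab.generate_synthetic_landscape(
        space_shape={"ligand": 4, "base": 3, "solvent": 3},
        temperature_values=(40.0, 70.0, 100.0),
        boiling_points=(65.0, 90.0, 120.0),
        seed=11,
    )


class ZeroVarPosterior:
    """A degenerate (zero-variance) objective posterior with a prescribed
    mean function over feature rows; lets acquisition tests compare against
    exhaustive brute-force selection exactly."""

    def __init__(self, mean_fn, y_mean=0.0, y_sd=1.0):
        self.mean_fn = mean_fn
        self.y_mean = float(y_mean)
        self.y_sd = float(y_sd)
        self.noise_level = 0.0

    def mu_std(self, X):
        return (np.asarray(self.mean_fn(X), dtype=float) - self.y_mean) / self.y_sd

    def var_std(self, X):
        return np.zeros(X.shape[0])

    def cov_std(self, Xa, Xb=None):
        nb = Xa.shape[0] if Xb is None else Xb.shape[0]
        return np.zeros((Xa.shape[0], nb))

    def mean(self, X):
        return np.asarray(self.mean_fn(X), dtype=float)

    def var(self, X):
        return np.zeros(X.shape[0])


def make_stub_model(pool, mean_fns, train_ids, Y_train,
                    objective_names=("AP_yield", "AP_selectivity")) -> SurrogateModel:
    """SurrogateModel whose posteriors are zero-variance stubs."""
    return SurrogateModel(
        objective_names=tuple(objective_names),
        posteriors=[ZeroVarPosterior(f) for f in mean_fns],
        train_ids=np.asarray(train_ids, dtype=int),
        Y_train=np.asarray(Y_train, dtype=float),
        seed=0,
    )


def make_observations(ids, Y, names=("AP_yield", "AP_selectivity")) -> ObservationSet:
    return ObservationSet(
        condition_ids=np.asarray(ids, dtype=int),
        Y=np.asarray(Y, dtype=float),
        objective_names=tuple(names),
    )
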