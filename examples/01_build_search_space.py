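"""Define, filter and encode a combinatorial reaction-condition space.

Builds a cross-coupling search space (ligands, precatalysts, bases, solvents
with boiling points, temperatures), removes conditions whose temperature
exceeds the solvent boiling point, and encodes the survivors into the
[0, 1]-scaled feature matrix the Gaussian-process surrogate operates on.
"""

import numpy as np

from plateopt.space import (
    FeasibilityRule,
    FeaturizationSpec,
    ParameterDef,
    SearchSpace,
    apply_feasibility,
    encode_pool,
    enumerate_conditions,
)

rng = np.random.default_rng(0)

# ligands carry a (here synthetic) quantum-chemical descriptor table that is
# PCA-reduced instead of one-hot encoded
ligands = tuple(f"ligand_{i}" for i in range(12))
descriptors = {name: rng.normal(size=8) for name in ligands}

space = SearchSpace(
    parameters=(
        ParameterDef("ligand", ligands, descriptors=descriptors),
        ParameterDef("precatalyst", ("NiCl2(PPh3)2", "Ni(COD)2", "NiBr2(TMEDA)")),
        ParameterDef("base", ("K3PO4", "K2CO3", "DBU")),
        ParameterDef(
            "solvent",
            ("MeOH", "iPrOH", "PhMe"),
            boiling_points={"MeOH": 65.0, "iPrOH": 82.0, "PhMe": 111.0},
        ),
        ParameterDef("temperature", (40.0, 55.0, 70.0, 85.0, 100.0), role="temperature"),
    ),
    feasibility_rules=(
        FeasibilityRule("max_temperature_le_boiling_point", scope=("solvent",)),
    ),
    featurization={"ligand": FeaturizationSpec("descriptor_pca", variance_threshold=0.95)},
)

conditions = enumerate_conditions(space)
feasible = apply_feasibility(conditions, space)
pool = encode_pool(space, feasible)

print(f"enumerated conditions : {len(conditions)}")   # product of level counts
print(f"feasible conditions   : {len(feasible)}")     # after the boiling-point rule
print(f"encoded features      : {pool.n_features} -> {pool.feature_names[:4]} ...")
print("every feature column spans [0, 1]:",
      bool(np.all(pool.X.min(0) == 0.0) and np.all(pool.X.max(0) == 1.0)))
# The feasible count is smaller than the product because MeOH (bp 65) only
# admits 40/55 degC and iPrOH (bp 82) only 40/55/70 degC.
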