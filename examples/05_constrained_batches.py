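"""Batch selection under equipment constraints on unique temperatures.

HTE decks heat plates in a small number of wells, so a 24-reaction batch may
only span k unique temperatures.  Two wrappers enforce this: *naive* lets
the acquisition run until k distinct temperatures appear and then restricts
the remaining picks; *nested* first ranks temperature levels by their mean
single-point acquisition value and restricts the pool up front.
"""

import numpy as np

from plateopt import acquisition as acq
from plateopt import surrogate as sg
from plateopt.benchlab import default_landscape, observe

oracle = default_landscape()
pool = oracle.pool

sel0 = acq.sobol_batch(pool, 24, seed=1, allowed_temperatures=[70.0, 100.0])
pool.mark_run(sel0.condition_ids)
obs = sg.ObservationSet(
    condition_ids=np.asarray(sel0.condition_ids),
    Y=observe(oracle, sel0.condition_ids, seed=1),
    objective_names=oracle.objective_names,
)
model = sg.fit(pool, obs, seed=1)

for mode in ("naive", "nested"):
    for k in (1, 2):
        constraint = acq.BatchConstraint("temperature", max_unique=k, mode=mode)
        sel = acq.constrained_batch("qnehvi", constraint, model, pool, q=24, seed=2,
                                    config=acq.AcquisitionConfig(q=24, mc_samples=32, seed=2))
        temps = sorted(float(t) for t in set(pool.temperature_values()[sel.condition_ids]))
        print(f"{mode:6s} k={k}: batch uses temperatures {temps}")
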