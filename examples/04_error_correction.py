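"""The core result: place-field input reduces path-integration error.

Runs the same 1000-step exploration with the correction loop on and off,
then repeats the fixed-field density protocol (20 vs 200 random centers).
"""

import numpy as np

from gridplace import ExperimentConfig, run_experiment


def mean_module_errors(res):
    err = np.linalg.norm(res.log.estimates[1:] - res.trajectory.pos[1:, None, :], axis=2)
    return np.nanmean(err, axis=0)


print("-- emergent place fields: correction on vs off --")
for arm, place_input in (("on ", True), ("off", False)):
    cfg = ExperimentConfig.model_validate({
        "seed": 0,
        "trajectory": {"n_steps": 1000},
        "coupling": {"place_input": place_input,
                     "field_mode": "emergent" if place_input else "fixed"},
    })
    res = run_experiment(cfg)
    print(f"place input {arm}: per-module error {np.round(mean_module_errors(res), 2)}"
          + (f"  ({len(res.log.corrections)} corrections, "
             f"{int(res.log.n_fields[-1])} fields)" if place_input else ""))

print("-- fixed random fields: sparse vs dense --")
for n_fields in (20, 200):
    cfg = ExperimentConfig.model_validate({
        "seed": 0,
        "trajectory": {"n_steps": 1000},
        "coupling": {"field_mode": "fixed", "n_fixed_fields": n_fields},
    })
    res = run_experiment(cfg)
    print(f"PF={n_fields:3d}: mean error {mean_module_errors(res).mean():.2f} a.u. "
          f"({len(res.log.corrections)} corrections)")
# denser fields put an anchor within the 2.5 a.u. snap radius more often,
# so corrections fire more frequently and the error stays lower.
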