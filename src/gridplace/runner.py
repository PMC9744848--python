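"""Experiment orchestration: seeding, the coupled loop, outputs, recipes.

A single global seed fans out (via ``numpy.random.SeedSequence``) into named
per-component streams -- trajectory, sensor noise, place-network init, grid
init, fixed-field placement -- so switching one component on or off never
shifts another component's draws.  ``run_experiment`` executes the coupled
loop for a validated :class:`~gridplace.config.ExperimentConfig` and writes
the declared CSV outputs plus a manifest; ``recipe`` provides the canned
comparison protocols (error reduction with/without place input,
field-density 20 vs 200, trajectory-style gridness, entropy dynamics).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arena import Arena, Trajectory, default_landmarks, generate_trajectory, read_trajectory_csv
from .can import ModuleStack, TorusGeometry
from .config import ExperimentConfig
from .coupling import CorrectionPolicy, GridToPlaceMap, Simulation, StepLog
from .metrics import (
    accumulate_rate_maps,
    autocorrelogram,
    error_summaries,
    gridness_hex,
    gridness_square,
)
from .place import PlaceNetwork

__all__ = ["run_experiment", "recipe", "RunResult", "gridness_table", "RECIPES"]

_STREAMS = ("trajectory", "noise", "place_init", "grid_init", "fields", "grid_spikes")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class RunResult:
    config: ExperimentConfig
    trajectory: Trajectory
    log: StepLog
    field_table: pd.DataFrame | None
    ratemap_sums: np.ndarray | None      # (n_modules, N, nb, nb)
    occupancy: np.ndarray | None         # (nb, nb)
    peak_shift_series: np.ndarray | None = None
    gridness: pd.DataFrame | None = None
    activity: np.ndarray | None = None   # (T-1, n_modules, N) when recorded

    def error_tables(self) -> dict[str, pd.DataFrame]:
        return error_summaries(self.log.estimates, self.trajectory.pos)


def _build_arena(cfg: ExperimentConfig) -> Arena:
    lms = default_landmarks(
        cfg.arena.side_length, cfg.arena.landmarks_per_wall, cfg.arena.landmark_seed
    )
    return Arena(side_length=cfg.arena.side_length, landmarks=lms)


def _build_trajectory(cfg: ExperimentConfig, rng_traj) -> Trajectory:
    tc = cfg.trajectory
    if tc.style == "csv":
        return read_trajectory_csv(tc.csv_path)
    seed = int(rng_traj.integers(0, 2**31 - 1))
    return generate_trajectory(
        tc.style, max(tc.n_steps, 1), _build_arena(cfg), seed,
        max_speed=tc.max_speed, mean_speed=tc.mean_speed,
    )


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> RunResult:
    """Execute the coupled loop for one configuration.

    Fully reproducible from (config, seed).  When ``out_dir`` is given, the
    declared CSV outputs and a manifest are written there.
    """
    cfg = config
    rngs = _rng_streams(cfg.seed)
    arena = _build_arena(cfg)

    if cfg.trajectory.n_steps == 0:
        result = RunResult(cfg, Trajectory(np.empty((0, 2)), np.empty(0)),
                           _empty_log(), None, None, None)
        if out_dir is not None:
            _write_outputs(result, Path(out_dir))
        return result

    traj = _build_trajectory(cfg, rngs["trajectory"])

    geo = TorusGeometry(cfg.can.n_x, cfg.can.n_y)
    stack = ModuleStack.build(
        rngs["grid_init"], start_pos=traj.pos[0], gains=tuple(cfg.can.gains),
        geometry=geo, spacing_factor=cfg.can.spacing_factor, n_burn=cfg.can.n_burn,
        beta=cfg.can.beta, i_a=cfg.can.i_a, sigma_w=cfg.can.sigma_w,
        t_shift=cfg.can.t_shift, tau=cfg.can.tau,
    )

    emergent = cfg.coupling.field_mode == "emergent"
    network = gp_map = None
    if emergent:
        pc = cfg.place
        network = PlaceNetwork(
            n_cells=pc.n_cells, n_sensors=pc.n_sensors, r_max=pc.r_max,
            p_thr=pc.p_thr, mu=pc.mu, sigma_f=pc.sigma_f,
            alpha_adapt=pc.alpha_adapt, a_thr=pc.a_thr,
            i_drive=pc.i_drive, i_gate=pc.i_gate, hh_dt=pc.hh_dt,
            hh_substeps=pc.hh_substeps, weight_sigma_init=pc.weight_sigma_init,
        ).init(rngs["place_init"])
        gp_map = GridToPlaceMap(
            n_cells=pc.n_cells, n_modules=len(cfg.can.gains),
            width=cfg.coupling.gp_width, mu=cfg.coupling.gp_mu,
            drive_threshold=cfg.coupling.drive_threshold,
        )

    sim = Simulation(
        arena=arena, trajectory=traj, stack=stack, network=network,
        gp_map=gp_map,
        policy=CorrectionPolicy(cfg.coupling.e_thr, cfg.coupling.snap_radius),
        noise_rng=rngs["noise"], alpha=cfg.place.alpha,
        place_input=cfg.coupling.place_input, field_mode=cfg.coupling.field_mode,
        n_fixed_fields=cfg.coupling.n_fixed_fields, field_rng=rngs["fields"],
        dx_field=cfg.metrics.dx_field, record_activity=cfg.record_activity,
    )

    # occupancy-binned per-neuron activity sums for rate maps
    sums = occ = None
    if cfg.record_ratemaps:
        nb = int(np.ceil(arena.side_length / cfg.metrics.bin_size))
        sums = np.zeros((len(stack.modules), geo.n, nb, nb))
        occ = np.zeros((nb, nb))

    spike_rng = rngs["grid_spikes"]
    scale = cfg.metrics.spike_scale
    for t in range(1, len(traj)):
        sim.step(t)
        if sums is not None:
            ix = min(int(traj.pos[t, 0] / cfg.metrics.bin_size), occ.shape[0] - 1)
            iy = min(int(traj.pos[t, 1] / cfg.metrics.bin_size), occ.shape[1] - 1)
            occ[ix, iy] += 1
            for m, mod in enumerate(stack.modules):
                if scale is None:
                    sums[m, :, ix, iy] += mod.activity
                else:
                    sums[m, :, ix, iy] += spike_rng.poisson(scale * mod.activity)

    field_table = sim.tracker.field_table() if sim.tracker is not None else None
    peak_series = (
        np.asarray(sim.tracker.peak_shift_series) if sim.tracker is not None else None
    )
    result = RunResult(cfg, traj, sim.log, field_table, sums, occ, peak_series)
    if sim._activity_log:
        result.activity = np.stack(sim._activity_log)
    if cfg.record_ratemaps:
        result.gridness = gridness_table(
            sums, occ, cfg.metrics.bin_size, cfg.metrics.smooth_sigma
        )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def gridness_table(
    sums: np.ndarray, occ: np.ndarray, bin_size: float, smooth_sigma: float
) -> pd.DataFrame:
    """Hex and square gridness of every cell from binned activity sums."""
    rows = []
    for m in range(sums.shape[0]):
        maps = accumulate_rate_maps(sums[m], occ, bin_size, smooth_sigma)
        for k, rmap in enumerate(maps):
            ac = autocorrelogram(rmap)
            rows.append(
                {"module": m + 1, "neuron": k,
                 "hex": gridness_hex(ac), "square": gridness_square(ac)}
            )
    return pd.DataFrame(rows)


def _empty_log() -> StepLog:
    return StepLog(
        estimates=np.empty((0, 0, 2)), e_error=np.empty(0), n_fields=np.empty(0),
        decoded=np.empty((0, 3)), entropy=np.empty((0, 7)),
    )


def _write_outputs(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    log = result.log
    t_len = log.estimates.shape[0]
    n_mod = log.estimates.shape[1] if t_len else 0

    est_rows = []
    for t in range(t_len):
        for m in range(n_mod):
            bc = (
                log.bump_centers[t, m]
                if log.bump_centers is not None
                else (np.nan, np.nan)
            )
            est_rows.append(
                (t, m + 1, log.estimates[t, m, 0], log.estimates[t, m, 1],
                 bc[0], bc[1])
            )
    pd.DataFrame(
        est_rows, columns=["t", "module", "pos_x", "pos_y", "bump_cx", "bump_cy"]
    ).to_csv(out / "estimates.csv", index=False)

    if result.activity is not None:
        import h5py

        with h5py.File(out / "activity.h5", "w") as fh:
            fh.create_dataset(
                "activity", data=result.activity, compression="gzip"
            )
            fh["activity"].attrs["dims"] = "step, module, neuron"

    if t_len:
        tables = result.error_tables()
        tables["series"].to_csv(out / "errors.csv", index=False)
        tables["binned"].to_csv(out / "errors_binned.csv", index=False)
    else:
        pd.DataFrame().to_csv(out / "errors.csv", index=False)

    pd.DataFrame(
        [
            (e["t"], m + 1, e["pre_estimates"][m, 0], e["pre_estimates"][m, 1],
             e["center"][0], e["center"][1], e["distance"])
            for e in log.corrections
            for m in range(n_mod)
        ],
        columns=["t", "module", "est_x", "est_y", "center_x", "center_y", "distance"],
    ).to_csv(out / "corrections.csv", index=False)

    if result.field_table is not None:
        result.field_table.to_csv(out / "place_fields.csv", index=False)
        pd.DataFrame(
            {
                "t": np.arange(t_len),
                "loc_x": log.decoded[:, 0],
                "loc_y": log.decoded[:, 1],
                "err_norm": log.decoded[:, 2],
            }
        ).to_csv(out / "decoded.csv", index=False)
        ent = pd.DataFrame(
            log.entropy, columns=["n_fields", "H", "S", "Z", "r", "R", "I"]
        )
        ent.insert(0, "t", np.arange(t_len))
        ent.to_csv(out / "entropy_timeseries.csv", index=False)

    if result.gridness is not None:
        result.gridness.to_csv(out / "gridness.csv", index=False)

    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
    manifest = {
        "config": cfg.model_dump(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "gridplace_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "n_steps_run": int(max(t_len - 1, 0)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------


def _base_config(**overrides) -> ExperimentConfig:
    return ExperimentConfig.model_validate(overrides)


def _mean_module_errors(result: RunResult) -> np.ndarray:
    err = np.linalg.norm(
        result.log.estimates[1:] - result.trajectory.pos[1:, None, :], axis=2
    )
    return np.nanmean(err, axis=0)


def recipe_fig4_error_reduction(
    n_seeds: int = 10, n_steps: int = 1000, base_seed: int = 0, style: str = "center_biased"
) -> pd.DataFrame:
    """Place input ON vs OFF on identical trajectories, per seed and module."""
    rows = []
    for s in range(n_seeds):
        for arm, place_input in (("on", True), ("off", False)):
            cfg = _base_config(
                seed=base_seed + s,
                trajectory={"n_steps": n_steps, "style": style},
                coupling={"place_input": place_input},
            )
            res = run_experiment(cfg)
            for m, err in enumerate(_mean_module_errors(res)):
                rows.append(
                    {"seed": base_seed + s, "arm": arm, "module": m + 1,
                     "mean_error": err,
                     "n_corrections": len(res.log.corrections)}
                )
    return _with_direction(pd.DataFrame(rows), "on", "off")


def recipe_fig5_field_density(
    n_seeds: int = 10, n_steps: int = 1000, base_seed: int = 0,
    n_low: int = 20, n_high: int = 200,
) -> pd.DataFrame:
    """Fixed random place fields: sparse (PF=20) vs dense (PF=200)."""
    rows = []
    for s in range(n_seeds):
        for arm, n_fields in ((f"pf{n_low}", n_low), (f"pf{n_high}", n_high)):
            cfg = _base_config(
                seed=base_seed + s,
                trajectory={"n_steps": n_steps},
                coupling={"field_mode": "fixed", "n_fixed_fields": n_fields},
            )
            res = run_experiment(cfg)
            for m, err in enumerate(_mean_module_errors(res)):
                rows.append(
                    {"seed": base_seed + s, "arm": arm, "module": m + 1,
                     "mean_error": err,
                     "n_corrections": len(res.log.corrections)}
                )
    return _with_direction(pd.DataFrame(rows), f"pf{n_high}", f"pf{n_low}")


def recipe_fig3_gridness(
    n_seeds: int = 5, n_steps: int = 10000, base_seed: int = 0
) -> pd.DataFrame:
    """Mean hex/square gridness for center-biased vs wall-following runs."""
    rows = []
    for s in range(n_seeds):
        for style in ("center_biased", "wall_following"):
            cfg = _base_config(
                seed=base_seed + s,
                trajectory={"n_steps": n_steps, "style": style},
                coupling={"field_mode": "fixed", "place_input": False},
                record_ratemaps=True,
            )
            res = run_experiment(cfg)
            rows.append(
                {"seed": base_seed + s, "style": style,
                 "mean_hex": float(res.gridness["hex"].mean()),
                 "mean_square": float(res.gridness["square"].mean())}
            )
    return pd.DataFrame(rows)


def recipe_fig2_entropy(
    n_seeds: int = 1, n_steps: int = 10000, base_seed: int = 0
) -> pd.DataFrame:
    """Entropy/complexity dynamics of emerging fields for both styles."""
    rows = []
    for s in range(n_seeds):
        for style in ("center_biased", "wall_following"):
            cfg = _base_config(
                seed=base_seed + s, trajectory={"n_steps": n_steps, "style": style}
            )
            res = run_experiment(cfg)
            ent = res.log.entropy
            t = np.arange(ent.shape[0])
            for k in range(1, ent.shape[0]):
                rows.append(
                    {"seed": base_seed + s, "style": style, "t": int(t[k]),
                     "n_fields": ent[k, 0], "H": ent[k, 1], "S": ent[k, 2],
                     "Z": ent[k, 3], "r": ent[k, 4], "R": ent[k, 5],
                     "I": ent[k, 6]}
                )
    return pd.DataFrame(rows)


def _with_direction(df: pd.DataFrame, better: str, worse: str) -> pd.DataFrame:
    """Annotate each (seed, module) pair with the direction of the effect."""
    piv = df.pivot_table(index=["seed", "module"], columns="arm", values="mean_error")
    piv["effect_holds"] = piv[better] < piv[worse]
    return df.merge(piv[["effect_holds"]].reset_index(), on=["seed", "module"])


RECIPES = {
    "fig4_error_reduction": recipe_fig4_error_reduction,
    "fig5_field_density": recipe_fig5_field_density,
    "fig3_gridness": recipe_fig3_gridness,
    "fig2_entropy": recipe_fig2_entropy,
}


def recipe(name: str, out_dir: str | Path | None = None, **kwargs) -> pd.DataFrame:
    """Run a canned comparison protocol and return its report table."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; known: {sorted(RECIPES)}")
    df = RECIPES[name](**kwargs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{name}.csv", index=False)
    return df
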