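"""Experiment configuration: schema-validated parameters with printed defaults.

Defaults reproduce the reference study conditions: arena side L = 100 a.u.,
N_pc = 2000 place cells on N_s = 3 proximity sensors, sensory error rate
alpha = 0.1, learning rates mu = 0.001, R_m = 20 Hz, firing threshold 0.3,
10,000 simulation steps, CAN stabilization tau = 0.95 with module gains
[0.04, 0.05, 0.06, 0.07, 0.08], uncertainty threshold 1.5 a.u., snap radius
2.5 a.u. and grid-drive threshold 1.1 a.u.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class ArenaConfig(BaseModel):
    side_length: float = Field(100.0, gt=0)
    landmarks_per_wall: int = Field(10, ge=0)
    landmark_seed: int = 0


class TrajectoryConfig(BaseModel):
    style: Literal["center_biased", "wall_following", "csv"] = "center_biased"
    n_steps: int = Field(10000, ge=0)
    max_speed: float = Field(1.5, gt=0)
    mean_speed: float = Field(0.8, gt=0)
    csv_path: Optional[str] = None

    @model_validator(mode="after")
    def _csv_needs_path(self):
        if self.style == "csv" and not self.csv_path:
            raise ValueError("trajectory.csv_path required when style='csv'")
        return self


class PlaceConfig(BaseModel):
    n_cells: int = Field(2000, gt=0)
    n_sensors: int = Field(3, gt=0)
    alpha: float = Field(0.1, ge=0)          # sensory error rate
    mu: float = Field(0.001, gt=0)           # sensor-weight learning rate
    r_max: float = Field(20.0, gt=0)         # Hz
    p_thr: float = Field(0.3, gt=0)          # firing-power threshold
    sigma_f: float = Field(0.5, gt=0)        # feature-similarity width
    alpha_adapt: float = Field(0.5, gt=0, le=1)
    a_thr: float = Field(0.3, gt=0)          # feature-match threshold
    weight_sigma_init: float = Field(0.25, gt=0)
    hh_dt: float = Field(0.01, gt=0)
    hh_substeps: int = Field(100, gt=0)
    i_drive: float = Field(10.0, gt=0)
    i_gate: float = Field(2.0, ge=0)


class CanConfig(BaseModel):
    gains: list[float] = Field(default_factory=lambda: [0.04, 0.05, 0.06, 0.07, 0.08])
    n_x: int = Field(20, gt=1)
    n_y: int = Field(20, gt=1)
    i_a: float = Field(0.3, gt=0)
    sigma_w: float = Field(0.24, gt=0)
    t_shift: float = Field(0.035, ge=0)
    tau: float = Field(0.95, ge=0, lt=1)
    beta: float = 0.0
    spacing_factor: float = Field(0.95, gt=0)
    n_burn: int = Field(500, ge=0)

    @model_validator(mode="after")
    def _gains_positive(self):
        if not self.gains or any(g <= 0 for g in self.gains):
            raise ValueError("can.gains must be a nonempty list of positive gains")
        return self


class CouplingConfig(BaseModel):
    place_input: bool = True
    field_mode: Literal["emergent", "fixed"] = "emergent"
    n_fixed_fields: int = Field(20, gt=0)
    e_thr: float = Field(1.5, gt=0)
    snap_radius: float = Field(2.5, gt=0)
    drive_threshold: float = Field(1.1, gt=0)
    gp_width: float = Field(2.5, gt=0)
    gp_mu: float = Field(0.001, gt=0)


class MetricsConfig(BaseModel):
    bin_size: float = Field(2.5, gt=0)
    smooth_sigma: float = Field(1.0, ge=0)
    dx_field: float = Field(20.0, gt=0)   # place-field size for the entropy suite
    # grid-cell rate maps are built from Poisson spikes sampled from the
    # module activity (spikes/step = spike_scale x activity; the bump peak
    # ~17 a.u. then fires ~2 spikes/step); None rate-maps raw activity
    spike_scale: Optional[float] = Field(0.1, gt=0)


class ExperimentConfig(BaseModel):
    seed: int = 0
    arena: ArenaConfig = Field(default_factory=ArenaConfig)
    trajectory: TrajectoryConfig = Field(default_factory=TrajectoryConfig)
    place: PlaceConfig = Field(default_factory=PlaceConfig)
    can: CanConfig = Field(default_factory=CanConfig)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    record_ratemaps: bool = False
    record_activity: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
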