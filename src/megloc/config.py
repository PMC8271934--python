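"""Structured run configuration (YAML) with strict validation.

Unknown keys are rejected and type errors name the offending dotted key
(e.g. ``simulation.snr_db``), so a typo in a config file fails loudly
instead of silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .forward import SensorArray, SphereModel, helmet_array
from .simulate import SourceSpace, build_source_space

__all__ = ["RunConfig", "load_config", "save_config", "build_geometry"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Section):
    sphere_radius_m: float = 0.09
    sphere_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_sensors: int = 306
    cap_half_angle_deg: float = 110.0
    sensor_shell_factor: float = 1.25
    n_grid_points: int = 2000
    shell_radius_fraction: float = 0.8
    sensor_table: str | None = None  # plain-text table overriding the synthetic helmet


class SimulationConfig(_Section):
    q: int = 2
    snr_db: float = 10.0
    rho: float | str = 0.0  # float or "uniform"
    n_times: int = 1
    fs: float = 1000.0


class NetworkConfig(_Section):
    name: str = "mlp-2"  # mlp-{1,2,3} | cnn-{1,2,3}
    width_scale: float = 1.0
    kernel_count: int = 32
    kernel_length: int = 5


class TrainingConfig(_Section):
    learning_rate: float = 0.001
    batch_size: int = 32
    n_steps: int = 1000
    momentum: float = 0.0
    log_every: int = 50
    normalize_input: bool = True


class ExperimentSection(_Section):
    experiment: str = "exp1-mlp-snr"
    snr_db_list: tuple[float, ...] = (-10.0, 0.0, 10.0, 20.0)
    rho_list: tuple[float, ...] = (0.0, 0.3, 0.5, 0.7, 0.9)
    repetitions: int = 200
    methods: tuple[str, ...] = ("network", "rapmusic")
    translation_mm: float = 3.0
    rotation_deg: float = 1.0


class IOConfig(_Section):
    out_dir: str = "."
    checkpoint: str | None = None


class RunConfig(_Section):
    master_seed: int = 0
    geometry: GeometryConfig = GeometryConfig()
    simulation: SimulationConfig = SimulationConfig()
    network: NetworkConfig = NetworkConfig()
    training: TrainingConfig = TrainingConfig()
    experiment: ExperimentSection = ExperimentSection()
    io: IOConfig = IOConfig()


def _humanize(err: ValidationError) -> ValueError:
    lines = []
    for e in err.errors():
        key = ".".join(str(p) for p in e["loc"])
        lines.append(f"{key}: {e['msg']}")
    return ValueError("invalid config: " + "; ".join(lines))


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML config file (or an already-parsed mapping)."""
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**data)
    except ValidationError as err:
        raise _humanize(err) from err


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def build_geometry(config: RunConfig) -> tuple[SphereModel, SensorArray, SourceSpace]:
    """Materialize conductor, sensor array and source grid from a config."""
    g = config.geometry
    sphere = SphereModel(center=np.asarray(g.sphere_center), radius=g.sphere_radius_m)
    if g.sensor_table:
        from .forward import read_sensor_table

        sensors = read_sensor_table(g.sensor_table)
        sensors.validate_against(sphere)
    else:
        sensors = helmet_array(
            m=g.n_sensors,
            sphere=sphere,
            cap_half_angle_deg=g.cap_half_angle_deg,
            shell_radius_factor=g.sensor_shell_factor,
        )
    space = build_source_space(sphere, g.n_grid_points, g.shell_radius_fraction)
    return sphere, sensors, space
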