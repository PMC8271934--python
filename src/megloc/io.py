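"""Dataset and checkpoint containers (HDF5) with full provenance.

Every artifact embeds the metadata needed to regenerate it: scalar
simulation settings and the master seed for datasets; the architecture
spec, target scaler and a config snapshot for model checkpoints.
Round trips are bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from .networks import CoordinateScaler, LayerSpec, NetworkSpec
from .simulate import MEGSample
from .training import TrainedModel

__all__ = [
    "DatasetContainer",
    "FORMAT_VERSION",
    "write_dataset",
    "read_dataset",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1

_REQUIRED_META = ("q", "snr_db", "rho_mode", "fs", "master_seed", "format_version")


@dataclass
class DatasetContainer:
    """In-memory view of a stored dataset: arrays plus scalar metadata."""

    Y: np.ndarray  # (n_samples, M, N)
    labels: np.ndarray  # (n_samples, 3Q) meters
    grid: np.ndarray  # (n_grid, 3)
    orientations: np.ndarray  # (n_grid, 3)
    meta: dict

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]


def write_dataset(
    samples: list[MEGSample],
    grid: np.ndarray,
    orientations: np.ndarray,
    meta: dict,
    path: str | Path,
) -> None:
    """Store simulated samples; shapes must be mutually consistent."""
    if samples:
        Y = np.stack([s.Y for s in samples])
        labels = np.stack([s.true_locations.ravel() for s in samples])
    else:
        Y = np.zeros((0, 0, 0))
        labels = np.zeros((0, 0))
    meta = dict(meta)
    meta["format_version"] = FORMAT_VERSION
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise KeyError(f"dataset metadata missing required key(s): {missing}")
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=Y)
        f.create_dataset("labels", data=labels)
        f.create_dataset("grid", data=np.asarray(grid))
        f.create_dataset("orientations", data=np.asarray(orientations))
        for k, v in meta.items():
            f.attrs[k] = v


def read_dataset(path: str | Path) -> DatasetContainer:
    with h5py.File(path, "r") as f:
        meta = dict(f.attrs)
        for k in _REQUIRED_META:
            if k not in meta:
                raise KeyError(f"dataset at {path} missing metadata key {k!r}")
        version = int(meta["format_version"])
        if version != FORMAT_VERSION:
            raise ValueError(
                f"dataset format version {version} != supported {FORMAT_VERSION}"
            )
        return DatasetContainer(
            Y=f["Y"][...],
            labels=f["labels"][...],
            grid=f["grid"][...],
            orientations=f["orientations"][...],
            meta=meta,
        )


def _spec_to_json(spec: NetworkSpec) -> str:
    return json.dumps(asdict(spec))


def _spec_from_json(payload: str) -> NetworkSpec:
    d = json.loads(payload)
    layers = tuple(LayerSpec(**ld) for ld in d.pop("layers"))
    return NetworkSpec(layers=layers, input_shape=tuple(d.pop("input_shape")), **d)


def save_model(model: TrainedModel, path: str | Path, config_snapshot: dict | None = None) -> None:
    """Checkpoint: per-layer tensors + spec + scaler + config snapshot."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["spec"] = _spec_to_json(model.spec)
        f.attrs["normalize_input"] = model.normalize_input
        f.attrs["scaler_scale"] = model.scaler.scale
        f.attrs["scaler_center"] = model.scaler.center
        f.attrs["config"] = json.dumps(config_snapshot or {})
        for i, layer in enumerate(model.params):
            g = f.create_group(f"layer{i:02d}")
            g.create_dataset("W", data=layer["W"])
            g.create_dataset("b", data=layer["b"])


def load_model(path: str | Path) -> tuple[TrainedModel, dict]:
    """Load a checkpoint; returns the model and the stored config snapshot."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"checkpoint format version {version} != supported {FORMAT_VERSION}")
        spec = _spec_from_json(f.attrs["spec"])
        scaler = CoordinateScaler(
            scale=float(f.attrs["scaler_scale"]), center=np.asarray(f.attrs["scaler_center"])
        )
        params = []
        for i in range(len(spec.layers)):
            g = f[f"layer{i:02d}"]
            params.append({"W": g["W"][...], "b": g["b"][...]})
        model = TrainedModel(
            spec=spec,
            params=params,
            scaler=scaler,
            normalize_input=bool(f.attrs["normalize_input"]),
        )
        return model, json.loads(f.attrs["config"])
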