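"""HDF5 persistence for parameters, datasets and trajectories.

Every container embeds a versioned schema string (``dpcnet-1``); loading a
file with a different schema raises an explicit version error.  Arrays are
round-tripped bit-exactly; labels and scalar metadata are stored as
datasets / attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .datasets import SequenceBatch
from .inference import Trajectory
from .model import DPCParameters
from .threelevel import ThreeLevelParameters

__all__ = [
    "SCHEMA",
    "SchemaError",
    "save_parameters",
    "load_parameters",
    "save_three_level",
    "load_three_level",
    "save_dataset",
    "load_dataset",
    "save_trajectory",
    "load_trajectory",
]

SCHEMA = "dpcnet-1"


class SchemaError(RuntimeError):
    """Raised when an HDF5 file carries an incompatible schema version."""


def _check_schema(f: h5py.File, kind: str) -> None:
    schema = f.attrs.get("schema")
    if schema != SCHEMA:
        raise SchemaError(f"expected schema {SCHEMA!r}, file has {schema!r}")
    if f.attrs.get("kind") != kind:
        raise SchemaError(f"expected a {kind!r} file, got {f.attrs.get('kind')!r}")


def _write_theta(grp: h5py.Group, theta) -> None:
    grp.attrs["n_layers"] = len(theta)
    for i, (W, b) in enumerate(theta):
        grp.create_dataset(f"W{i}", data=W)
        grp.create_dataset(f"b{i}", data=b)


def _read_theta(grp: h5py.Group):
    n = int(grp.attrs["n_layers"])
    return [(grp[f"W{i}"][()], grp[f"b{i}"][()]) for i in range(n)]


def save_parameters(params: DPCParameters, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["kind"] = "parameters"
        f.create_dataset("U", data=params.U)
        for k in range(params.V.shape[0]):
            f.create_dataset(f"V_{k}", data=params.V[k])
        f.attrs["K"] = params.V.shape[0]
        _write_theta(f.create_group("theta"), params.theta)


def load_parameters(path) -> DPCParameters:
    with h5py.File(path, "r") as f:
        _check_schema(f, "parameters")
        K = int(f.attrs["K"])
        V = np.stack([f[f"V_{k}"][()] for k in range(K)])
        return DPCParameters(U=f["U"][()], V=V, theta=_read_theta(f["theta"]))


def save_three_level(params: ThreeLevelParameters, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["kind"] = "three_level"
        f.attrs["rho"] = params.rho
        f.attrs["sigma_r2_level2"] = params.sigma_r2_level2
        f.attrs["K2"] = params.K2
        base = f.create_group("base")
        base.create_dataset("U", data=params.base.U)
        base.create_dataset("V", data=params.base.V)
        _write_theta(base.create_group("theta"), params.base.theta)
        f.create_dataset("V2", data=params.V2)
        _write_theta(f.create_group("theta2"), params.theta2)


def load_three_level(path) -> ThreeLevelParameters:
    with h5py.File(path, "r") as f:
        _check_schema(f, "three_level")
        base = DPCParameters(
            U=f["base/U"][()], V=f["base/V"][()], theta=_read_theta(f["base/theta"])
        )
        return ThreeLevelParameters(
            base=base,
            V2=f["V2"][()],
            theta2=_read_theta(f["theta2"]),
            rho=float(f.attrs["rho"]),
            sigma_r2_level2=float(f.attrs["sigma_r2_level2"]),
        )


def save_dataset(batch: SequenceBatch, path) -> None:
    if len(batch) == 0:
        raise ValueError("refusing to save an empty dataset")
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["kind"] = "dataset"
        if batch.frame_shape is not None:
            B, T, _ = batch.frames.shape
            f.create_dataset("frames", data=batch.frames.reshape(B, T, *batch.frame_shape))
            f.attrs["frame_shape"] = batch.frame_shape
        else:
            f.create_dataset("frames", data=batch.frames)
        lab = f.create_group("labels")
        for k, v in batch.labels.items():
            lab.create_dataset(k, data=np.asarray(v))
        f.attrs["metadata"] = json.dumps(batch.metadata, default=str)


def load_dataset(path) -> SequenceBatch:
    with h5py.File(path, "r") as f:
        _check_schema(f, "dataset")
        frames = f["frames"][()]
        frame_shape = tuple(int(x) for x in f.attrs["frame_shape"]) if "frame_shape" in f.attrs else None
        if frames.ndim == 4:
            B, T, H, W = frames.shape
            frames = frames.reshape(B, T, H * W)
        labels = {k: f["labels"][k][()] for k in f["labels"]}
        metadata = json.loads(f.attrs.get("metadata", "{}"))
        return SequenceBatch(frames=frames, frame_shape=frame_shape, labels=labels, metadata=metadata)


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["kind"] = "trajectory"
        for name in ("r_hat", "r_bar", "r_h_hat", "w", "pred_err", "final_loss"):
            f.create_dataset(name, data=getattr(traj, name))


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        _check_schema(f, "trajectory")
        return Trajectory(
            r_hat=f["r_hat"][()],
            r_bar=f["r_bar"][()],
            r_h_hat=f["r_h_hat"][()],
            w=f["w"][()],
            pred_err=f["pred_err"][()],
            final_loss=f["final_loss"][()],
        )
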