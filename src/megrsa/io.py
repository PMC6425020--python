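"""HDF5 / CSV persistence for epochs, RDM series and tidy result tables."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .core import Epochs, ModelRDM, RDMSeries

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_rdms",
    "load_rdms",
    "save_model_rdm",
    "load_model_rdm",
    "rsa_timecourses_to_frame",
]


def save_epochs(path, epochs: Epochs, design_json: str = None, seed: int = None) -> None:
    """Write epochs to an HDF5 container.

    Datasets: ``data`` [trials, channels, timepoints], ``times`` (ms),
    ``condition_id``, ``valid``; attributes: optional design JSON and seed.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("condition_id", data=np.asarray(epochs.condition_id, dtype=np.int64))
        f.create_dataset("valid", data=epochs.valid.astype(np.uint8))
        if design_json is not None:
            f.attrs["design"] = design_json
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_epochs(path) -> Epochs:
    with h5py.File(path, "r") as f:
        return Epochs(
            data=f["data"][()],
            times=f["times"][()],
            condition_id=f["condition_id"][()],
            valid=f["valid"][()].astype(bool),
        )


def save_rdms(path, rdms: RDMSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rdm", data=rdms.values, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=rdms.times)
        f.create_dataset("condition_id", data=np.asarray(rdms.condition_ids, dtype=np.int64))


def load_rdms(path) -> RDMSeries:
    with h5py.File(path, "r") as f:
        return RDMSeries(
            values=f["rdm"][()],
            times=f["times"][()],
            condition_ids=f["condition_id"][()],
        )


def save_model_rdm(path, model: ModelRDM) -> None:
    """Model RDM as CSV with condition ids as header and index."""
    frame = pd.DataFrame(model.values, index=model.condition_ids, columns=model.condition_ids)
    frame.to_csv(path, index_label="condition_id")


def load_model_rdm(path, name: str = None) -> ModelRDM:
    frame = pd.read_csv(path, index_col="condition_id")
    return ModelRDM(
        frame.to_numpy(dtype=float),
        name=name or "model",
        condition_ids=frame.index.to_numpy(),
    )


def rsa_timecourses_to_frame(group_timecourses: dict) -> pd.DataFrame:
    """Tidy frame (subject, time_ms, model, rho) from group time courses."""
    rows = []
    for model, tc in group_timecourses.items():
        for s in range(tc.n_subjects):
            for t, rho in zip(tc.times, tc.data[s]):
                rows.append(dict(subject=s, time_ms=float(t), model=model, rho=float(rho)))
    return pd.DataFrame(rows)
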