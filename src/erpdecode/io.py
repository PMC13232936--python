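"""Persistence for the epoch container and simulation configs.

Epochs live in an HDF5 file with datasets ``/data`` (μV), ``/times`` (ms),
``/labels``, ``/keep`` and montage/provenance attributes; per-epoch metadata
can additionally be exported as CSV.  Simulation configs round-trip through
YAML."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import EpochSet, Montage, SimulationConfig

__all__ = [
    "save_epochs",
    "load_epochs",
    "epoch_metadata",
    "save_simulation_config",
    "load_simulation_config",
]


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("keep", data=epochs.keep)
        f.create_dataset("positions", data=epochs.montage.positions)
        f.attrs["srate"] = epochs.srate
        f.attrs["M"] = epochs.M
        f.attrs["participant_id"] = epochs.participant_id
        f.attrs["channel_names"] = list(epochs.montage.channel_names)
        f.attrs["n_scalp"] = epochs.montage.n_scalp
        f.attrs["eog_lower"] = epochs.montage.eog_lower
        f.attrs["veog_upper"] = epochs.montage.veog_upper
        f.attrs["log"] = list(epochs.log)


def load_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` back from HDF5."""
    with h5py.File(path, "r") as f:
        montage = Montage(
            channel_names=tuple(str(n) for n in f.attrs["channel_names"]),
            n_scalp=int(f.attrs["n_scalp"]),
            eog_lower=str(f.attrs["eog_lower"]),
            veog_upper=str(f.attrs["veog_upper"]),
            positions=f["positions"][()],
        )
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            srate=float(f.attrs["srate"]),
            labels=f["labels"][()],
            M=int(f.attrs["M"]),
            montage=montage,
            keep=f["keep"][()],
            participant_id=str(f.attrs["participant_id"]),
            log=[str(s) for s in f.attrs["log"]],
        )


def epoch_metadata(epochs: EpochSet) -> pd.DataFrame:
    """Per-epoch metadata table (epoch index, class label, keep flag)."""
    return pd.DataFrame(
        {
            "epoch": np.arange(epochs.n_epochs),
            "label": epochs.labels,
            "keep": epochs.keep,
            "participant_id": epochs.participant_id,
        }
    )


def save_simulation_config(cfg: SimulationConfig, path: str | Path) -> None:
    d = asdict(cfg)
    for key in ("blink_prob_per_class", "artifact_amplitude_range"):
        if d[key] is not None:
            d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_simulation_config(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("blink_prob_per_class", "artifact_amplitude_range"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
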