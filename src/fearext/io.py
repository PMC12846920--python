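"""HDF5 / TSV / JSON serialization of the pipeline's containers."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .preprocess import ChannelInfo, Epochs, Recording
from .spectral import FrequencyGrid, TimeFrequencyTensor

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "save_tensor",
    "load_tensor",
    "mask_to_json",
    "mask_from_json",
    "metric_frame",
]


def _write_frame(group, name, df: pd.DataFrame):
    group.attrs[name] = df.to_json(orient="split")


def _read_frame(group, name) -> pd.DataFrame:
    from io import StringIO

    return pd.read_json(StringIO(group.attrs[name]), orient="split")


def _write_channels(group, channels):
    group.attrs["channels"] = json.dumps(
        [{"name": c.name, "shaft": c.shaft, "contact": c.contact, "roi": c.roi}
         for c in channels]
    )


def _read_channels(group):
    return [ChannelInfo(**d) for d in json.loads(group.attrs["channels"])]


def save_recording(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip", compression_opts=1)
        f.attrs["sampling_rate"] = recording.sampling_rate
        _write_channels(f, recording.channels)
        _write_frame(f, "events", recording.events)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            channels=_read_channels(f),
            events=_read_frame(f, "events"),
        )


def save_epochs(epochs: Epochs, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        _write_channels(f, epochs.channels)
        _write_frame(f, "metadata", epochs.metadata)
        _write_frame(f, "rejected", epochs.rejected)


def load_epochs(path) -> Epochs:
    with h5py.File(path, "r") as f:
        return Epochs(
            data=f["data"][()],
            times=f["times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            channels=_read_channels(f),
            metadata=_read_frame(f, "metadata"),
            rejected=_read_frame(f, "rejected"),
        )


def save_tensor(tft: TimeFrequencyTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tft.power, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=tft.times)
        f.create_dataset("frequencies", data=tft.grid.frequencies)
        f.create_dataset("cycles", data=tft.grid.cycles)
        if tft.valid is not None:
            f.create_dataset("valid", data=tft.valid)
        f.attrs["sampling_rate"] = tft.sampling_rate
        f.attrs["normalization"] = tft.normalization
        f.attrs["reference"] = tft.reference
        _write_frame(f, "metadata", tft.metadata)


def load_tensor(path) -> TimeFrequencyTensor:
    with h5py.File(path, "r") as f:
        return TimeFrequencyTensor(
            power=f["power"][()],
            times=f["times"][()],
            grid=FrequencyGrid(f["frequencies"][()], f["cycles"][()]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            metadata=_read_frame(f, "metadata"),
            normalization=str(f.attrs["normalization"]),
            reference=str(f.attrs["reference"]),
            valid=f["valid"][()] if "valid" in f else None,
        )


def mask_to_json(mask, path=None) -> dict:
    """Run-length-encoded artifact mask (per channel: [start, stop) sample runs)."""
    runs = {}
    for i, row in enumerate(mask.mask):
        edges = np.diff(row.astype(np.int8))
        starts = (np.flatnonzero(edges == 1) + 1).tolist()
        ends = (np.flatnonzero(edges == -1) + 1).tolist()
        if row[0]:
            starts.insert(0, 0)
        if row[-1]:
            ends.append(int(row.size))
        runs[str(i)] = list(map(list, zip(starts, ends)))
    obj = {
        "n_samples": int(mask.mask.shape[1]),
        "padding_ms": mask.padding_ms,
        "thresholds": mask.thresholds,
        "runs": runs,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh)
    return obj


def mask_from_json(obj_or_path):
    from .preprocess import ArtifactMask

    obj = obj_or_path
    if not isinstance(obj, dict):
        with open(obj_or_path) as fh:
            obj = json.load(fh)
    n_ch = len(obj["runs"])
    mask = np.zeros((n_ch, obj["n_samples"]), bool)
    for ch, runs in obj["runs"].items():
        for s, e in runs:
            mask[int(ch), s:e] = True
    return ArtifactMask(mask=mask, thresholds=obj["thresholds"], padding_ms=obj["padding_ms"])


def metric_frame(values, centers, participant, roi, condition) -> pd.DataFrame:
    """Tidy long-format frame for a per-window metric series."""
    return pd.DataFrame(
        {
            "participant": participant,
            "roi": roi,
            "condition": condition,
            "time": np.asarray(centers),
            "value": np.asarray(values),
        }
    )
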