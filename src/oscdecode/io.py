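"""HDF5 containers for epochs, time-frequency data and decoding results.

Epoch container layout (one file or group per task recording):

    /data            trial x channel x time, float, microvolt
    /times           ms axis
    /channels        channel names (UTF-8)
    /labels/task     per-trial task label
    /labels/object   per-trial object id (int)
    attrs: sampling_rate (Hz), units

Missing groups or mismatched trial counts raise ``SchemaError`` naming the
violation.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .epochs import EpochSet
from .simulate import GroundTruth
from .timefreq import FrequencyGrid, TFEpochs


class SchemaError(ValueError):
    """The HDF5 file does not follow the epoch container schema."""


def write_epochs(epochs: EpochSet, path: str | Path | h5py.Group) -> None:
    """Write an EpochSet to the HDF5 epoch container."""
    if isinstance(path, h5py.Group):
        _write_epochs_group(epochs, path)
        return
    with h5py.File(path, "w") as f:
        _write_epochs_group(epochs, f)


def _write_epochs_group(epochs: EpochSet, g: h5py.Group) -> None:
    g.create_dataset("data", data=epochs.data)
    g.create_dataset("times", data=epochs.times)
    g.create_dataset("channels", data=np.array(epochs.channels, dtype="S"))
    labels = g.create_group("labels")
    labels.create_dataset("task", data=np.array(epochs.task, dtype="S"))
    labels.create_dataset("object", data=epochs.object_id)
    g.attrs["sampling_rate"] = epochs.sampling_rate
    g.attrs["units"] = "uV"


def read_epochs(path: str | Path | h5py.Group) -> EpochSet:
    """Read an EpochSet, validating the container schema."""
    if isinstance(path, h5py.Group):
        return _read_epochs_group(path)
    with h5py.File(path, "r") as f:
        return _read_epochs_group(f)


def _read_epochs_group(g: h5py.Group) -> EpochSet:
    for name in ("data", "times", "channels", "labels/task", "labels/object"):
        if name not in g:
            raise SchemaError(f"missing dataset /{name}")
    if "sampling_rate" not in g.attrs:
        raise SchemaError("missing attribute sampling_rate")
    data = g["data"][()]
    task = g["labels/task"].asstr()[()]
    obj = g["labels/object"][()]
    if data.shape[0] != len(task) or data.shape[0] != len(obj):
        raise SchemaError("trial count mismatch between /data and /labels")
    try:
        return EpochSet(
            data=data,
            task=task,
            object_id=obj,
            times=g["times"][()],
            channels=list(g["channels"].asstr()[()]),
            sampling_rate=float(g.attrs["sampling_rate"]),
        )
    except ValueError as e:
        raise SchemaError(str(e)) from e


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar with the planted parameters (phases omitted)."""
    payload = {
        "object_patterns": truth.object_patterns.tolist(),
        "signal_channels": truth.signal_channels,
        "shared_band": list(truth.shared_band),
        "latency_windows": {k: list(v) for k, v in truth.latency_windows.items()},
        "carrier_freq": truth.carrier_freq,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_tfr(tf: TFEpochs, path: str | Path) -> None:
    """Persist TFEpochs under a /tf group with dimension labels."""
    with h5py.File(path, "w") as f:
        g = f.create_group("tf")
        g.create_dataset("power", data=tf.power)
        g.create_dataset("times", data=tf.times)
        g.create_dataset("freqs", data=np.asarray(tf.grid.centers))
        g.create_dataset("channels", data=np.array(tf.channels, dtype="S"))
        labels = g.create_group("labels")
        labels.create_dataset("task", data=np.array(tf.task, dtype="S"))
        labels.create_dataset("object", data=tf.object_id)
        g.attrs["dims"] = "trial x channel x frequency x time"
        g.attrs["sampling_rate"] = tf.sampling_rate
        g.attrs["normalized"] = tf.normalized
        if tf.baseline_window is not None:
            g.attrs["baseline_window"] = list(tf.baseline_window)


def read_tfr(path: str | Path) -> TFEpochs:
    with h5py.File(path, "r") as f:
        if "tf" not in f:
            raise SchemaError("missing group /tf")
        g = f["tf"]
        baseline = g.attrs.get("baseline_window")
        return TFEpochs(
            power=g["power"][()],
            times=g["times"][()],
            grid=FrequencyGrid(tuple(g["freqs"][()])),
            channels=list(g["channels"].asstr()[()]),
            task=g["labels/task"].asstr()[()],
            object_id=g["labels/object"][()],
            sampling_rate=float(g.attrs["sampling_rate"]),
            normalized=bool(g.attrs["normalized"]),
            baseline_window=tuple(baseline) if baseline is not None else None,
        )


def write_timegen(result, path: str | Path, band: str | None = None) -> None:
    """Store a TimeGenMatrix under /decoding/<band>/."""
    band = band or result.band
    with h5py.File(path, "a") as f:
        g = f.require_group(f"decoding/{band}")
        for name in ("timegen", "per_pair", "perception_times", "imagery_times"):
            if name in g:
                del g[name]
        g.create_dataset("timegen", data=result.accuracy)
        g.create_dataset("per_pair", data=result.per_pair)
        g.create_dataset("perception_times", data=result.perception_times)
        g.create_dataset("imagery_times", data=result.imagery_times)
        g.attrs["n_repeats"] = result.n_repeats
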