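"""Epoch containers: sensor layout and the trials x sensors x time array.

``EpochsData`` is the single interchange container of the pipeline: a dense
float array of shape (n_trials, n_sensors, n_times) with a millisecond time
axis, a sensor layout (magnetometers in fT, planar gradiometers in fT/cm),
a per-trial metadata table (stimulus, position_in_train, train_index) and a
normalization-state flag that lets downstream stages enforce the
reject -> filter -> baseline-z-normalize ordering.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["SensorLayout", "EpochsData", "default_layout"]

MAG = "mag"
GRAD = "grad"
UNITS = {MAG: "fT", GRAD: "fT/cm"}


@dataclass(frozen=True)
class SensorLayout:
    """Sensor types of an MEG array (magnetometers and planar gradiometers)."""

    sensor_type: np.ndarray  # array of "mag" / "grad", one entry per sensor

    def __post_init__(self) -> None:
        st = np.asarray(self.sensor_type, dtype=object)
        if st.size < 2:
            raise ValueError("need at least 2 sensors")
        if not set(np.unique(st)) <= {MAG, GRAD}:
            raise ValueError("sensor types must be 'mag' or 'grad'")
        object.__setattr__(self, "sensor_type", st)

    @property
    def n_sensors(self) -> int:
        return int(self.sensor_type.size)

    @property
    def units(self) -> dict[str, str]:
        return dict(UNITS)

    def type_mask(self, kind: str) -> np.ndarray:
        return self.sensor_type == kind


def default_layout(n_sensors: int = 306) -> SensorLayout:
    """A 1:2 magnetometer:gradiometer split (102/204 at the full 306)."""
    types = np.array([MAG if i % 3 == 0 else GRAD for i in range(n_sensors)], dtype=object)
    return SensorLayout(sensor_type=types)


@dataclass
class EpochsData:
    data: np.ndarray  # (n_trials, n_sensors, n_times)
    times: np.ndarray  # ms
    sfreq: float  # Hz
    layout: SensorLayout
    trials: pd.DataFrame
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_times)")
        n, p, t = self.data.shape
        if p != self.layout.n_sensors:
            raise ValueError("sensor dimension does not match layout")
        if t != self.times.size:
            raise ValueError("time dimension does not match times")
        if len(self.trials) != n:
            raise ValueError("trial metadata length does not match data")
        dt = np.diff(self.times)
        if t > 1 and not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if self.normalization_state not in ("raw", "z-normalized"):
            raise ValueError(f"unknown normalization_state {self.normalization_state!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochsData":
        return EpochsData(
            data=self.data.copy(),
            times=self.times.copy(),
            sfreq=self.sfreq,
            layout=self.layout,
            trials=self.trials.copy(),
            normalization_state=self.normalization_state,
        )

    def select_trials(self, indices: np.ndarray) -> "EpochsData":
        """Subset trials by positional index, preserving order of `indices`."""
        indices = np.asarray(indices)
        return EpochsData(
            data=self.data[indices],
            times=self.times,
            sfreq=self.sfreq,
            layout=self.layout,
            trials=self.trials.iloc[indices].reset_index(drop=True),
            normalization_state=self.normalization_state,
        )

    def decimate(self, factor: int) -> "EpochsData":
        """Keep every `factor`-th sample (used for temporal generalization)."""
        if factor < 1:
            raise ValueError("decimation factor must be >= 1")
        return EpochsData(
            data=self.data[:, :, ::factor],
            times=self.times[::factor],
            sfreq=self.sfreq / factor,
            layout=self.layout,
            trials=self.trials.copy(),
            normalization_state=self.normalization_state,
        )

    # -- disk round trip ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """HDF5 schema: datasets /data and /times, JSON-encoded attributes."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["normalization_state"] = self.normalization_state
            f.attrs["sensor_type"] = json.dumps(list(self.layout.sensor_type))
            f.attrs["trials"] = self.trials.to_json(orient="split")

    def save_npz(self, path: str | Path) -> None:
        """Plain ``.npz`` fallback with the same logical schema as the HDF5."""
        np.savez(
            path,
            data=self.data,
            times=self.times,
            sfreq=np.array(self.sfreq),
            normalization_state=np.array(self.normalization_state),
            sensor_type=np.array(list(self.layout.sensor_type)),
            trials=np.array(self.trials.to_json(orient="split")),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "EpochsData":
        with np.load(path, allow_pickle=False) as f:
            layout = SensorLayout(f["sensor_type"].astype(object))
            return cls(
                data=f["data"],
                times=f["times"],
                sfreq=float(f["sfreq"]),
                layout=layout,
                trials=pd.read_json(io.StringIO(str(f["trials"])), orient="split"),
                normalization_state=str(f["normalization_state"]),
            )

    @classmethod
    def load(cls, path: str | Path) -> "EpochsData":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            layout = SensorLayout(np.array(json.loads(f.attrs["sensor_type"]), dtype=object))
            trials = pd.read_json(io.StringIO(f.attrs["trials"]), orient="split")
            return cls(
                data=data,
                times=times,
                sfreq=float(f.attrs["sfreq"]),
                layout=layout,
                trials=trials,
                normalization_state=str(f.attrs["normalization_state"]),
            )
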