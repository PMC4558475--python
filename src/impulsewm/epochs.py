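"""Epoched multichannel EEG container and its HDF5 on-disk layout.

The :class:`EpochSet` is the currency of the whole pipeline: a dense
``trials x channels x time`` tensor of voltages (microvolts) on a regular
time axis (milliseconds relative to the locking event), together with a
per-trial metadata table.

On disk an EpochSet is a single HDF5 file with datasets ``/data``
(float32, trials x channels x time), ``/time_ms`` (float64),
``/channels`` (variable-length UTF-8 strings) and a ``/trials`` group
holding one dataset per metadata column; a companion ``<stem>.trials.csv``
mirrors the trial table for tools that cannot read HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet", "SAMPLE_STEP_MS", "round_to_sample_grid"]

#: Sample spacing in milliseconds implied by the 250 Hz sampling rate.
SAMPLE_STEP_MS = 4.0


def round_to_sample_grid(t_ms: float, step_ms: float = SAMPLE_STEP_MS) -> float:
    """Round a latency to the nearest sample, halves away from zero.

    The scheduled impulse onsets (1170/1230 ms) fall exactly between
    250 Hz samples; rounding halves away from zero maps them to
    1172/1232 ms, preserving the designed 60 ms onset difference.
    """
    return float(np.floor(abs(t_ms) / step_ms + 0.5) * step_ms * np.sign(t_ms))


@dataclass
class EpochSet:
    """Epoched data: ``data[trial, channel, sample]`` in microvolts.

    Parameters
    ----------
    data:
        Voltage tensor, shape ``(n_trials, n_channels, n_times)``.
    time_ms:
        Strictly increasing sample times in ms relative to the locking
        event, spaced by 4 ms (250 Hz).
    channel_names:
        One label per channel row.
    trials:
        Trial metadata; ``len(trials) == n_trials``. Must contain a
        ``trial_id`` column (unique).
    """

    data: np.ndarray
    time_ms: np.ndarray
    channel_names: list[str]
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.channel_names = [str(c) for c in self.channel_names]
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_trials, n_channels, n_times = self.data.shape
        if n_channels != len(self.channel_names):
            raise ValueError(
                f"{n_channels} channel rows but {len(self.channel_names)} names"
            )
        if n_times != self.time_ms.size:
            raise ValueError("time axis length mismatch")
        if n_times > 1:
            steps = np.diff(self.time_ms)
            if not np.all(steps > 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(steps, SAMPLE_STEP_MS):
                raise ValueError("time axis must be sampled at 4 ms (250 Hz)")
        if len(self.trials) != n_trials:
            raise ValueError("trial table length does not match data")
        if "trial_id" not in self.trials.columns:
            raise ValueError("trial table must have a trial_id column")

    # -- basic introspection -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample at exactly ``t_ms`` (must lie on the grid)."""
        idx = int(np.argmin(np.abs(self.time_ms - t_ms)))
        if abs(self.time_ms[idx] - t_ms) > 1e-6:
            raise ValueError(f"{t_ms} ms is not on the sample grid")
        return idx

    # -- selection -----------------------------------------------------------
    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            time_ms=self.time_ms.copy(),
            channel_names=list(self.channel_names),
            trials=self.trials.copy(),
        )

    def select_trials(self, mask) -> "EpochSet":
        """Subset trials by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.size != self.n_trials:
            raise ValueError("boolean mask length mismatch")
        return replace(
            self,
            data=self.data[mask],
            trials=self.trials.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            .reset_index(drop=True),
        )

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochSet":
        """Restrict the time axis to ``[tmin_ms, tmax_ms]`` (inclusive)."""
        keep = (self.time_ms >= tmin_ms - 1e-9) & (self.time_ms <= tmax_ms + 1e-9)
        if not keep.any():
            raise ValueError("crop window does not intersect the epoch")
        return replace(self, data=self.data[:, :, keep], time_ms=self.time_ms[keep])

    # -- I/O -----------------------------------------------------------------
    def to_hdf5(self, path: str | Path, write_csv: bool = True) -> Path:
        """Write the HDF5 layout (and the companion trial-table CSV)."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset(
                "channels",
                data=np.array(self.channel_names, dtype=h5py.string_dtype("utf-8")),
            )
            g = f.create_group("trials")
            for col in self.trials.columns:
                values = self.trials[col].to_numpy()
                if values.dtype == object:
                    values = values.astype(str).astype(h5py.string_dtype("utf-8"))
                g.create_dataset(col, data=values)
            g.attrs["columns"] = [str(c) for c in self.trials.columns]
        if write_csv:
            self.trials.to_csv(path.with_suffix(path.suffix + ".trials.csv"), index=False)
        return path

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()].astype(np.float64)
            time_ms = f["time_ms"][()]
            channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
            g = f["trials"]
            cols = list(g.attrs["columns"]) if "columns" in g.attrs else sorted(g.keys())
            table = {}
            for col in cols:
                v = g[col][()]
                if v.dtype.kind in ("S", "O"):
                    v = np.array([x.decode() if isinstance(x, bytes) else str(x) for x in v])
                table[col] = v
            trials = pd.DataFrame(table, columns=cols)
        return cls(data=data, time_ms=time_ms, channel_names=channels, trials=trials)
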