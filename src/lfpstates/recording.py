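"""Multichannel LFP recording container and HDF5 I/O.

The on-disk layout is a plain HDF5 file with datasets ``/lfp`` (channels x
samples, float32, microvolts), ``/fs_hz``, ``/channel_depth_um``, ``/region``
(UTF-8 strings), ``/probe_id``, ``/artifact_mask`` and ``/excluded_channels``,
plus a ``schema_version`` attribute. Times are in seconds with sample 0 at
t = 0; channel indices are 0-based; depths are positive downward from the pia.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1


@dataclass
class Recording:
    """A block of simultaneously recorded LFP channels.

    Attributes
    ----------
    lfp : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    fs_hz : float
        Sampling rate.
    channel_depth_um : ndarray, shape (n_channels,)
        Depth of each contact below the pial surface (positive downward).
    region : ndarray of str, shape (n_channels,)
        Anatomical region label per channel (e.g. "M1", "V1L", "V1R").
    probe_id : ndarray of int, shape (n_channels,)
        Probe grouping used for per-probe rereferencing.
    artifact_mask : ndarray of bool, shape (n_samples,)
        True marks samples to exclude from analysis.
    excluded_channels : list of int
        Channels kept in the container but flagged as unusable.
    """

    lfp: np.ndarray
    fs_hz: float
    channel_depth_um: np.ndarray
    region: np.ndarray
    probe_id: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    excluded_channels: list = field(default_factory=list)

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be 2-D (channels x samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        n_ch, n_samp = self.lfp.shape
        self.channel_depth_um = np.asarray(self.channel_depth_um, dtype=float)
        if self.channel_depth_um.shape != (n_ch,):
            raise ValueError("channel_depth_um length must match channel count")
        if np.any(self.channel_depth_um < 0):
            raise ValueError("depths must be nonnegative")
        self.region = np.asarray(self.region, dtype=object)
        self.probe_id = np.asarray(self.probe_id, dtype=int)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n_samp, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (n_samp,):
            raise ValueError("artifact_mask length must match sample count")
        self.excluded_channels = sorted(int(c) for c in self.excluded_channels)

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def clean_channels(self) -> np.ndarray:
        """Indices of channels not on the exclusion list."""
        bad = set(self.excluded_channels)
        return np.array([c for c in range(self.n_channels) if c not in bad], dtype=int)

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)

    def channel_table(self) -> pd.DataFrame:
        """Per-channel metadata as a DataFrame (CSV-exportable)."""
        return pd.DataFrame(
            {
                "channel": np.arange(self.n_channels),
                "depth_um": self.channel_depth_um,
                "region": [str(r) for r in self.region],
                "probe_id": self.probe_id,
                "excluded": [c in set(self.excluded_channels) for c in range(self.n_channels)],
            }
        )


def save_recording(path, rec: Recording, **attrs) -> None:
    """Write a Recording to the HDF5 container format."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.lfp.astype(np.float32))
        f.create_dataset("fs_hz", data=float(rec.fs_hz))
        f.create_dataset("channel_depth_um", data=rec.channel_depth_um)
        f.create_dataset(
            "region", data=np.array([str(r) for r in rec.region], dtype=h5py.string_dtype())
        )
        f.create_dataset("probe_id", data=rec.probe_id)
        f.create_dataset("artifact_mask", data=rec.artifact_mask)
        f.create_dataset("excluded_channels", data=np.array(rec.excluded_channels, dtype=int))
        f.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in attrs.items():
            f.attrs[k] = v


def load_recording(path) -> Recording:
    """Read a Recording from the HDF5 container format."""
    with h5py.File(path, "r") as f:
        return Recording(
            lfp=f["lfp"][...].astype(float),
            fs_hz=float(f["fs_hz"][()]),
            channel_depth_um=f["channel_depth_um"][...],
            region=np.array([s.decode() if isinstance(s, bytes) else str(s) for s in f["region"][...]], dtype=object),
            probe_id=f["probe_id"][...],
            artifact_mask=f["artifact_mask"][...].astype(bool),
            excluded_channels=list(f["excluded_channels"][...]),
        )
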