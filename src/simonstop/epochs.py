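"""Epoched-EEG container: trials x channels x samples with condition labels."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EEGEpochs"]


@dataclass
class EEGEpochs:
    """Epoched EEG in microvolts.

    data: (n_trials, n_channels, n_samples); times in ms relative to target
    onset; metadata holds one row per trial (at least ``trial_index``,
    ``response`` in {go, stop} and ``congruency``); kept_mask flags trials that
    survived artifact rejection (rejection never drops data, only flags it).
    """

    data: np.ndarray
    srate: float
    times: np.ndarray  # ms
    channel_labels: list
    metadata: pd.DataFrame
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match data")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata must have one row per trial")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EEGEpochs":
        return EEGEpochs(
            data=self.data.copy(),
            srate=self.srate,
            times=self.times.copy(),
            channel_labels=list(self.channel_labels),
            metadata=self.metadata.copy(),
            kept_mask=self.kept_mask.copy(),
        )

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present (have {self.channel_labels})")

    def time_indices(self, window_ms: tuple) -> np.ndarray:
        """Sample indices with window_ms[0] <= t <= window_ms[1]."""
        lo, hi = window_ms
        return np.flatnonzero((self.times >= lo) & (self.times <= hi))

    def select(self, mask: np.ndarray) -> "EEGEpochs":
        """Subset trials by boolean mask or integer index."""
        mask = np.asarray(mask)
        return EEGEpochs(
            data=self.data[mask],
            srate=self.srate,
            times=self.times.copy(),
            channel_labels=list(self.channel_labels),
            metadata=self.metadata.iloc[mask].reset_index(drop=True),
            kept_mask=self.kept_mask[mask],
        )

    def kept(self) -> "EEGEpochs":
        return self.select(self.kept_mask)

    # -- persistence (HDF5 data cube + JSON-encoded metadata) ----------------

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=1)
            f.create_dataset("times", data=self.times)
            f.create_dataset("kept_mask", data=self.kept_mask)
            f.attrs["srate"] = self.srate
            f.attrs["channel_labels"] = json.dumps(list(self.channel_labels))
            f.attrs["metadata"] = self.metadata.to_json(orient="records")

    @classmethod
    def load_h5(cls, path) -> "EEGEpochs":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                srate=float(f.attrs["srate"]),
                times=f["times"][()],
                channel_labels=json.loads(f.attrs["channel_labels"]),
                metadata=pd.read_json(__import__("io").StringIO(f.attrs["metadata"]), orient="records"),
                kept_mask=f["kept_mask"][()],
            )

    def to_long_frame(self) -> pd.DataFrame:
        """Per-sample long table (only sensible for tiny fixtures)."""
        n, c, s = self.data.shape
        idx = pd.MultiIndex.from_product(
            [range(n), self.channel_labels, self.times], names=["trial", "channel", "time_ms"]
        )
        return pd.DataFrame({"uV": self.data.ravel()}, index=idx).reset_index()
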