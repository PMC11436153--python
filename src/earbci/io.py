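"""Containers and text I/O for continuous recordings and event tables.

A recording is an ``n_channels x n_samples`` array in microvolts with a
sampling rate and channel labels.  Recordings round-trip through a plain
TSV layout (first column ``time_s``, one column per channel, header row
with labels); EDF files can additionally be *read* when :mod:`mne` is
installed (the ``edf`` extra).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: EEG montage used throughout: three around-ear electrodes plus the vertex.
EEG_CHANNELS: tuple[str, ...] = ("Front", "Over", "Back", "Cz")
#: Single bipolar EMG channel over the wrist extensors.
EMG_CHANNEL: str = "EMG"
ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + (EMG_CHANNEL,)


@dataclass
class ContinuousRecording:
    """Multichannel time series (microvolts) with sampling metadata."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.data[idx]

    def select(self, names: tuple[str, ...] | list[str]) -> "ContinuousRecording":
        """Sub-recording restricted to ``names`` (order preserved as given)."""
        idx = [self.channel_names.index(n) for n in names]
        return ContinuousRecording(self.data[idx].copy(), self.fs, tuple(names))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data.T, columns=list(self.channel_names))
        df.insert(0, "time_s", self.times)
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContinuousRecording":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "time_s":
            raise ValueError("first column must be time_s")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("need at least two samples to infer the sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
        names = tuple(df.columns[1:])
        return cls(df[list(names)].to_numpy().T, fs, names)

    @classmethod
    def from_edf(cls, path: str | Path) -> "ContinuousRecording":
        """Read an EDF file (requires mne, the ``edf`` extra)."""
        import mne  # deferred: heavy import, optional dependency

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne stores volts
        return cls(data, float(raw.info["sfreq"]), tuple(raw.ch_names))


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write the cue table (columns onset_s, type, block) as TSV."""
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "type", "block"} - set(ev.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return ev
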