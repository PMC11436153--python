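"""Per-epoch features: interval means, template correlation, Welch band power.

Three families are computed per channel:

* ``temporal_mean`` — the average of consecutive non-overlapping
  half-second intervals of the epoch;
* ``template_xcorr`` — the zero-lag correlation between the epoch and a
  template (the mean of the training folds' movement epochs), normalized
  to [-1, 1] by default;
* ``band_power`` — mean Welch power spectral density in the delta
  (0.5-4 Hz), theta (4-8), alpha (8-13) and beta (13-30 Hz) bands.

The "temporal" feature subset comprises the interval means and the
template correlation; "spectral" the band powers; "all" both.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochSet


class BandDefinition(NamedTuple):
    name: str
    lo: float
    hi: float


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

FEATURE_SUBSETS = ("all", "temporal", "spectral")


@dataclass(frozen=True)
class FeatureName:
    channel: str
    family: str  # temporal_mean | template_xcorr | band_power
    detail: str  # interval index or band name

    def __str__(self) -> str:
        return f"{self.channel}|{self.family}|{self.detail}"


@dataclass
class FeatureMatrix:
    """n x d feature table with per-column provenance."""

    values: np.ndarray
    names: tuple[FeatureName, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be n x len(names)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[str(nm) for nm in self.names])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class Template:
    """Per-channel mean movement epoch, computed from training folds only."""

    waveform: np.ndarray  # channels x samples, uV
    channel_names: tuple[str, ...]
    fs: float
    source_indices: tuple[int, ...] = ()


def temporal_means(epochs: EpochSet, interval: float = 0.5) -> FeatureMatrix:
    """Means of non-overlapping ``interval``-second windows, per channel.

    The epoch length must divide evenly into intervals (a 3 s control
    epoch gives 6 per channel, a 2 s rehabilitation epoch 4).
    """
    n_int_samp = int(round(interval * epochs.fs))
    n, c, s = epochs.data.shape
    if n_int_samp <= 0 or s % n_int_samp:
        raise ValueError(
            f"epoch of {s} samples is not divisible into {interval} s intervals"
        )
    w = s // n_int_samp
    means = epochs.data.reshape(n, c, w, n_int_samp).mean(axis=3)
    names = tuple(
        FeatureName(ch, "temporal_mean", str(i))
        for ch in epochs.channel_names
        for i in range(w)
    )
    return FeatureMatrix(means.reshape(n, c * w), names)


def build_template(epochs: EpochSet, indices: Iterable[int] | None = None) -> Template:
    """Pointwise mean of (training-fold) movement epochs."""
    data = epochs.data if indices is None else epochs.data[np.asarray(list(indices))]
    if data.shape[0] == 0:
        raise ValueError("cannot build a template from zero epochs")
    return Template(
        data.mean(axis=0),
        epochs.channel_names,
        epochs.fs,
        tuple() if indices is None else tuple(int(i) for i in indices),
    )


def template_xcorr(
    epochs: EpochSet, template: Template, normalized: bool = True
) -> FeatureMatrix:
    """Channel-wise zero-lag correlation between each epoch and the template.

    Normalized: sum(e*t) / sqrt(sum(e^2) * sum(t^2)) in [-1, 1]; a
    zero-energy epoch or template yields 0.  ``normalized=False`` returns
    the raw zero-lag inner product.
    """
    if template.waveform.shape != epochs.data.shape[1:]:
        raise ValueError("template shape does not match the epochs")
    dot = np.einsum("ncs,cs->nc", epochs.data, template.waveform)
    if normalized:
        e_energy = np.einsum("ncs,ncs->nc", epochs.data, epochs.data)
        t_energy = np.einsum("cs,cs->c", template.waveform, template.waveform)
        denom = np.sqrt(e_energy * t_energy[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            dot = np.where(denom > 0, dot / denom, 0.0)
    names = tuple(
        FeatureName(ch, "template_xcorr", "0") for ch in epochs.channel_names
    )
    return FeatureMatrix(dot, names)


def band_power(
    epochs: EpochSet,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    segment_s: float = 1.0,
    overlap: float = 0.5,
) -> FeatureMatrix:
    """Mean Welch PSD per channel and band (Hann windows, 50% overlap).

    A frequency bin belongs to the band whose half-open [lo, hi) interval
    contains its center.  Bands reaching past the Nyquist frequency are
    rejected.
    """
    fs = epochs.fs
    nyq = fs / 2.0
    for b in bands:
        if not 0 < b.lo < b.hi:
            raise ValueError(f"degenerate band {b}")
        if b.hi > nyq:
            raise ValueError(f"band {b.name} ({b.lo}-{b.hi} Hz) exceeds Nyquist {nyq}")
    nperseg = int(round(segment_s * fs))
    if epochs.data.shape[2] < nperseg:
        raise ValueError("epoch shorter than one Welch segment")
    freqs, psd = sps.welch(
        epochs.data,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        axis=-1,
    )
    cols = []
    for b in bands:
        sel = (freqs >= b.lo) & (freqs < b.hi)
        cols.append(psd[:, :, sel].mean(axis=-1))
    values = np.stack(cols, axis=-1)  # n x c x bands
    n, c, nb = values.shape
    names = tuple(
        FeatureName(ch, "band_power", b.name)
        for ch in epochs.channel_names
        for b in bands
    )
    return FeatureMatrix(values.reshape(n, c * nb), names)


def assemble_features(subset: str, parts: Iterable[FeatureMatrix]) -> FeatureMatrix:
    """Column-concatenate feature blocks, filtered to a subset.

    Order is fixed: temporal means, template correlations, band powers.
    ``temporal`` keeps the first two families, ``spectral`` the band
    powers, ``all`` everything.
    """
    if subset not in FEATURE_SUBSETS:
        raise ValueError(f"subset must be one of {FEATURE_SUBSETS}")
    family_order = {"temporal_mean": 0, "template_xcorr": 1, "band_power": 2}
    keep_families = {
        "all": set(family_order),
        "temporal": {"temporal_mean", "template_xcorr"},
        "spectral": {"band_power"},
    }[subset]
    parts = list(parts)
    ns = {p.n for p in parts}
    if len(ns) > 1:
        raise ValueError(f"inconsistent epoch counts across feature parts: {ns}")
    parts.sort(key=lambda p: min(family_order[nm.family] for nm in p.names))
    blocks, names = [], []
    for p in parts:
        sel = [j for j, nm in enumerate(p.names) if nm.family in keep_families]
        if sel:
            blocks.append(p.values[:, sel])
            names.extend(p.names[j] for j in sel)
    if not blocks:
        raise ValueError(f"no features left for subset {subset!r}")
    return FeatureMatrix(np.hstack(blocks), tuple(names))
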