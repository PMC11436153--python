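"""Zero-phase filtering and EMG enveloping.

EEG chain: fifth-order Butterworth band-pass 0.1-30 Hz, then a 50 Hz
notch of quality 30, both applied forward-backward (zero phase; the
effective order doubles).  EMG chain: sixth-order Butterworth band-pass
20-100 Hz, the same notch, then the magnitude of the analytic (Hilbert)
signal as envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import EEG_CHANNELS, EMG_CHANNEL, ContinuousRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Design parameters for one zero-phase IIR stage.

    ``order`` is the design order before bidirectional application (the
    effective attenuation order is twice that).
    """

    kind: str  # "bandpass" | "notch"
    order: int = 5
    low: float = 0.1
    high: float = 30.0
    notch_freq: float = 50.0
    quality: float = 30.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.kind == "bandpass":
            if not (0.0 < self.low < self.high):
                raise ValueError("need 0 < low < high")
            if self.high >= nyq:
                raise ValueError(f"high cutoff {self.high} Hz >= Nyquist {nyq} Hz")
            if self.order < 1:
                raise ValueError("order must be >= 1")
        elif self.kind == "notch":
            if self.notch_freq >= nyq:
                raise ValueError(f"notch {self.notch_freq} Hz >= Nyquist {nyq} Hz")
            if self.quality <= 0:
                raise ValueError("quality must be positive")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


EEG_BANDPASS = FilterSpec("bandpass", order=5, low=0.1, high=30.0)
EMG_BANDPASS = FilterSpec("bandpass", order=6, low=20.0, high=100.0)
LINE_NOTCH = FilterSpec("notch", notch_freq=50.0, quality=30.0)


def _check_length(n: int, padlen: int) -> None:
    if n <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering: {n} samples, "
            f"need more than {padlen} (edge padding of the slowest transient)"
        )


def apply_zero_phase_bandpass(
    x: np.ndarray, spec: FilterSpec = EEG_BANDPASS, fs: float = 250.0
) -> np.ndarray:
    """Forward-backward Butterworth band-pass along the last axis.

    Output has the input's length and zero net phase delay; edges are
    handled by odd-symmetric padding sized to the filter's slowest
    transient (about 3 periods of the low cutoff — the scipy default is
    far too short for a 0.1 Hz edge and would leak transients seconds
    into the record).
    """
    spec.validate(fs)
    sos = sps.butter(
        spec.order, [spec.low, spec.high], btype="bandpass", fs=fs, output="sos"
    )
    padlen = max(6 * sos.shape[0] + 1, int(3.0 * fs / spec.low))
    _check_length(np.asarray(x).shape[-1], padlen)
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def apply_notch(
    x: np.ndarray,
    notch_freq: float = 50.0,
    quality: float = 30.0,
    fs: float = 250.0,
) -> np.ndarray:
    """Forward-backward IIR notch (quality Q) along the last axis.

    Edge padding covers the notch's ring-down (~3 / bandwidth seconds).
    """
    FilterSpec("notch", notch_freq=notch_freq, quality=quality).validate(fs)
    b, a = sps.iirnotch(notch_freq, quality, fs=fs)
    padlen = max(9, int(3.0 * fs * quality / notch_freq))
    _check_length(np.asarray(x).shape[-1], padlen)
    return sps.filtfilt(b, a, x, axis=-1, padtype="odd", padlen=padlen)


def emg_envelope(x: np.ndarray, method: str = "analytic") -> np.ndarray:
    """Envelope of an already band-passed EMG trace.

    ``method="analytic"`` (default) returns the magnitude of the analytic
    signal, ``|x + i*H(x)|``, which is non-negative and bounds the
    rectified signal.  ``method="real"`` keeps the literal real part of
    the analytic signal — i.e. the unmodified input — purely as an audit
    switch; it is not a usable envelope.
    """
    if method == "analytic":
        return np.abs(sps.hilbert(x, axis=-1))
    if method == "real":
        return np.asarray(x, dtype=float)
    raise ValueError(f"unknown envelope method {method!r}")


@dataclass
class PreprocessedRecording:
    """Filtered EEG, filtered EMG and its envelope, on a shared clock."""

    eeg: ContinuousRecording
    emg: np.ndarray
    envelope: np.ndarray
    fs: float


def preprocess_recording(
    rec: ContinuousRecording,
    eeg_spec: FilterSpec = EEG_BANDPASS,
    emg_spec: FilterSpec = EMG_BANDPASS,
    notch: FilterSpec = LINE_NOTCH,
    envelope_method: str = "analytic",
) -> PreprocessedRecording:
    """Run the full per-stream filtering chain on a raw recording.

    The first and last 0.5 s remain edge-contaminated by the bidirectional
    filtering; they are logged, not trimmed.
    """
    eeg_names = tuple(ch for ch in rec.channel_names if ch in EEG_CHANNELS)
    eeg_raw = rec.select(eeg_names)
    eeg = apply_zero_phase_bandpass(eeg_raw.data, eeg_spec, rec.fs)
    eeg = apply_notch(eeg, notch.notch_freq, notch.quality, rec.fs)

    if EMG_CHANNEL in rec.channel_names:
        emg = apply_zero_phase_bandpass(rec.channel(EMG_CHANNEL), emg_spec, rec.fs)
        emg = apply_notch(emg, notch.notch_freq, notch.quality, rec.fs)
        env = emg_envelope(emg, envelope_method)
    else:
        emg = np.zeros(rec.n_samples)
        env = np.zeros(rec.n_samples)
    logger.info(
        "preprocessed %d EEG channels, %.0f s; first/last 0.5 s edge-contaminated",
        len(eeg_names),
        rec.duration,
    )
    return PreprocessedRecording(
        ContinuousRecording(eeg, rec.fs, eeg_names), emg, env, rec.fs
    )
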