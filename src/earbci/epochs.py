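"""EMG-onset detection, epoch extraction, artifact rejection, grand averages.

Movement epochs are aligned either to the EMG-detected movement onset
(hand) or to the cue (tongue); idle epochs start at seeded random points
of the idle recording, at least one second apart.  Two window regimes are
used: (-2 s, 1 s) around t0 for control applications and (-2 s, 0 s) for
rehabilitation (no post-onset information).  Epochs exceeding +-100 uV on
any analyzed EEG channel are rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EEG_CHANNELS, ContinuousRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochWindow:
    """Half-open window [t0+start, t0+end) in seconds relative to t0."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    @property
    def length(self) -> float:
        return self.end - self.start

    def n_samples(self, fs: float) -> int:
        return int(round(self.length * fs))


CONTROL_WINDOW = EpochWindow(-2.0, 1.0)
REHAB_WINDOW = EpochWindow(-2.0, 0.0)


@dataclass
class EpochSet:
    """n x channels x samples epochs with labels and alignment metadata."""

    data: np.ndarray
    labels: np.ndarray  # "movement" | "idle" per epoch
    alignment: str  # "emg_onset" | "cue" | "idle_random"
    window: EpochWindow
    channel_names: tuple[str, ...]
    fs: float
    t0s: np.ndarray = field(default=None)  # type: ignore[assignment]
    excluded_t0s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be n x channels x samples")
        n, c, s = self.data.shape
        if c != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if s != self.window.n_samples(self.fs):
            raise ValueError(
                f"{s} samples but window implies {self.window.n_samples(self.fs)}"
            )
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise ValueError("one label per epoch required")
        if self.t0s is None:
            self.t0s = np.full(n, np.nan)
        if self.excluded_t0s is None:
            self.excluded_t0s = np.empty(0)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds relative to t0."""
        return self.window.start + np.arange(self.data.shape[2]) / self.fs

    def select_channels(self, names: tuple[str, ...] | list[str]) -> "EpochSet":
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(
            self.data[:, idx, :].copy(),
            self.labels.copy(),
            self.alignment,
            self.window,
            tuple(names),
            self.fs,
            self.t0s.copy(),
            self.excluded_t0s.copy(),
        )

    def subset(self, indices: np.ndarray) -> "EpochSet":
        indices = np.asarray(indices)
        return EpochSet(
            self.data[indices].copy(),
            self.labels[indices].copy(),
            self.alignment,
            self.window,
            self.channel_names,
            self.fs,
            self.t0s[indices].copy(),
            self.excluded_t0s.copy(),
        )


@dataclass(frozen=True)
class RejectionSpec:
    """Amplitude rejection rule: drop an epoch if any sample of any checked
    channel falls strictly outside [-limit, +limit] microvolts."""

    limit: float = 100.0
    channels: tuple[str, ...] | None = None  # None -> all EEG channels present

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("rejection limit must be positive")


# ---------------------------------------------------------------------------
# Onset detection
# ---------------------------------------------------------------------------


@dataclass
class OnsetResult:
    """Detected movement onsets, one per cue (NaN where the trial was skipped)."""

    onsets: np.ndarray
    fallback: np.ndarray  # True where no threshold crossing -> cue used
    skipped: np.ndarray  # True where the cue lacked margin in the recording
    thresholds: dict[int, float]  # per-block derivative threshold (uV/s)


def _smoothed_derivative(
    envelope: np.ndarray, fs: float, smooth_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-average smoothing and first difference (units/s) of an envelope.

    A causal moving average over ``smooth_s`` seconds suppresses the
    band-rate flutter of the analytic envelope so the mean+3SD threshold
    tracks bursts, not carrier fluctuations, without anticipating the
    burst; ``smooth_s=0`` differentiates the raw envelope.  Returns
    ``(smoothed_envelope, derivative)``.
    """
    env = np.asarray(envelope, dtype=float)
    w = int(round(smooth_s * fs))
    if w > 1:
        kernel = np.ones(w) / w
        env = np.convolve(env, kernel)[: len(env)]
    d = np.empty_like(env)
    d[1:] = np.diff(env) * fs
    d[0] = d[1]
    return env, d


def detect_onsets(
    envelope: np.ndarray,
    cue_times: np.ndarray,
    fs: float,
    threshold: float | dict[int, float] | None = None,
    search: tuple[float, float] = (-1.0, 1.0),
    blocks: np.ndarray | None = None,
    smooth_s: float = 0.1,
    baseline: tuple[float, float] = (-2.0, -1.0),
    confirm_s: float = 0.2,
) -> OnsetResult:
    """Movement onset = first derivative threshold crossing near each cue.

    Per cue, the earliest sample in ``[cue+search[0], cue+search[1])``
    where the envelope derivative strictly exceeds the block's threshold;
    if none crosses, the cue itself becomes the onset (fallback flag).

    ``threshold=None`` auto-sets each block's threshold to mean + 3 SD of
    the derivative over that block's baseline segments (the preparation
    second preceding every search window); a scalar or a per-block dict
    overrides it.

    A crossing only counts if the smoothed envelope rises above its own
    baseline mean + 6 SD within the following ``confirm_s`` seconds — the
    automated stand-in for inspecting each detected onset, which discards
    derivative flutter that is not followed by an actual burst
    (``confirm_s=0`` disables the check).
    """
    if np.any(np.asarray(envelope) < 0):
        raise ValueError("envelope must be non-negative")
    cue_times = np.asarray(cue_times, dtype=float)
    n = len(envelope)
    if blocks is None:
        blocks = np.zeros(cue_times.size, dtype=int)
    blocks = np.asarray(blocks, dtype=int)
    env_s, d = _smoothed_derivative(envelope, fs, smooth_s)

    # margins: baseline and search window must fit inside the recording
    lo_need = min(search[0], baseline[0])
    skipped = (cue_times + lo_need < 0) | (cue_times + search[1] > n / fs)
    for ct in cue_times[skipped]:
        warnings.warn(f"cue at {ct:.2f} s too close to a recording boundary; skipped")

    thresholds: dict[int, float] = {}
    env_levels: dict[int, float] = {}
    for b in np.unique(blocks):
        segs_d, segs_e = [], []
        for ct in cue_times[(blocks == b) & ~skipped]:
            i0 = int(round((ct + baseline[0]) * fs))
            i1 = int(round((ct + baseline[1]) * fs))
            segs_d.append(d[i0:i1])
            segs_e.append(env_s[i0:i1])
        cat_d = np.concatenate(segs_d) if segs_d else np.zeros(1)
        cat_e = np.concatenate(segs_e) if segs_e else np.zeros(1)
        env_levels[int(b)] = float(cat_e.mean() + 6.0 * cat_e.std())
        if isinstance(threshold, dict):
            thresholds[int(b)] = float(threshold[int(b)])
        elif threshold is not None:
            thresholds[int(b)] = float(threshold)
        else:
            thresholds[int(b)] = float(cat_d.mean() + 3.0 * cat_d.std())

    n_confirm = int(round(confirm_s * fs))
    onsets = np.full(cue_times.size, np.nan)
    fallback = np.zeros(cue_times.size, dtype=bool)
    for k, (ct, b) in enumerate(zip(cue_times, blocks)):
        if skipped[k]:
            continue
        i0 = int(round((ct + search[0]) * fs))
        i1 = int(round((ct + search[1]) * fs))
        crossings = np.flatnonzero(d[i0:i1] > thresholds[int(b)])
        hit = None
        for c in crossings:
            j = i0 + c
            if n_confirm == 0 or env_s[j : j + n_confirm + 1].max() > env_levels[int(b)]:
                hit = j
                break
        if hit is not None:
            onsets[k] = hit / fs
        else:
            onsets[k] = ct
            fallback[k] = True
    n_fb = int(fallback.sum())
    if n_fb:
        logger.info("onset detection: %d/%d cue fallbacks", n_fb, cue_times.size)
    return OnsetResult(onsets, fallback, skipped, thresholds)


# ---------------------------------------------------------------------------
# Extraction / idle sampling / rejection / averaging
# ---------------------------------------------------------------------------


def extract_epochs(
    recording: ContinuousRecording,
    t0_list: np.ndarray,
    window: EpochWindow,
    channels: tuple[str, ...] | None = None,
    label: str = "movement",
    alignment: str = "emg_onset",
) -> EpochSet:
    """Slice half-open windows around each t0 (snapped to the nearest sample).

    A t0 whose full window does not fit inside the recording (or is NaN)
    is excluded and logged, not raised.
    """
    names = channels if channels is not None else recording.channel_names
    sub = recording.select(names)
    fs = recording.fs
    n_samp = window.n_samples(fs)
    kept, excluded, slices = [], [], []
    for t0 in np.asarray(t0_list, dtype=float):
        if not np.isfinite(t0):
            excluded.append(t0)
            continue
        i0 = int(round((t0 + window.start) * fs))
        if i0 < 0 or i0 + n_samp > sub.n_samples:
            excluded.append(t0)
            continue
        kept.append(t0)
        slices.append(sub.data[:, i0 : i0 + n_samp])
    if excluded:
        logger.info(
            "extract_epochs: excluded %d/%d t0s without full window support",
            len(excluded),
            len(t0_list),
        )
    data = (
        np.stack(slices)
        if slices
        else np.empty((0, len(names), n_samp))
    )
    return EpochSet(
        data,
        np.full(len(kept), label, dtype=object),
        alignment,
        window,
        tuple(names),
        fs,
        np.asarray(kept),
        np.asarray(excluded),
    )


def sample_idle_starts(
    idle_duration: float,
    n: int,
    epoch_len: float,
    min_gap: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """n sorted start times in [0, duration - epoch_len], pairwise >= min_gap apart.

    Starts need only be a second apart, not an epoch apart, so epochs may
    overlap.  Raises when the request cannot fit, reporting the maximum
    feasible n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    room = idle_duration - epoch_len
    if room < 0:
        raise ValueError(f"epoch ({epoch_len} s) longer than idle record")
    slack = room - (n - 1) * min_gap
    if n > 1 and slack <= 0:
        n_max = max(1, int(np.ceil(room / min_gap - 1e-12)))
        raise ValueError(
            f"cannot place {n} starts with >= {min_gap} s gaps in "
            f"[0, {room:.3f}] s; at most {n_max} fit"
        )
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(0.0, slack if n > 1 else room, size=n))
    return u + np.arange(n) * min_gap if n > 1 else u


def reject_artifacts(
    epochs: EpochSet, spec: RejectionSpec = RejectionSpec()
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs exceeding the amplitude limit on any checked channel.

    Surviving epochs keep their order.  The log lists each rejected
    epoch's index, the offending channel and its extremum.  A sample
    exactly at the limit is kept (only strictly outside rejects).
    """
    checked = spec.channels
    if checked is None:
        checked = tuple(ch for ch in epochs.channel_names if ch in EEG_CHANNELS)
    idx = [epochs.channel_names.index(ch) for ch in checked]
    rows = []
    keep = np.ones(epochs.n_epochs, dtype=bool)
    for i in range(epochs.n_epochs):
        seg = epochs.data[i][idx]
        peaks = np.abs(seg).max(axis=1)
        worst = int(np.argmax(peaks))
        if peaks[worst] > spec.limit:
            keep[i] = False
            ext = seg[worst][np.argmax(np.abs(seg[worst]))]
            rows.append(
                {"epoch": i, "channel": checked[worst], "extremum_uv": float(ext)}
            )
    log = pd.DataFrame(rows, columns=["epoch", "channel", "extremum_uv"])
    if len(rows):
        logger.info("rejected %d/%d epochs (+-%g uV)", len(rows), epochs.n_epochs,
                    spec.limit)
    return epochs.subset(np.flatnonzero(keep)), log


def grand_average(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean across epochs and the negative-peak latency per channel.

    Returns ``(mean_waveform: channels x samples, peak_latency_s: channels)``
    with latencies in seconds relative to t0 (argmin of the mean trace).
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot average an empty epoch set")
    mean = epochs.data.mean(axis=0)
    latencies = epochs.window.start + np.argmin(mean, axis=1) / epochs.fs
    return mean, latencies
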