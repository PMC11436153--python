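"""Synthetic cued-movement EEG/EMG sessions with ground-truth onsets.

The generator emulates the statistical structure a movement-vs-idle
analysis relies on:

* a cued block design (movement blocks of repeated
  preparation / movement / relax trials, plus separate idle blocks);
* a movement-related cortical potential (MRCP): a slow negativity that
  builds up before the movement onset, peaks near it (about -10 uV at the
  vertex) and rebounds back to baseline — projected onto the around-ear
  channels with per-channel gains < 1;
* event-related desynchronization / synchronization (ERD/ERS): an
  amplitude dip of the alpha/beta background oscillation around movement
  followed by a rebound above baseline;
* a 1/f ("pink") background, white sensor noise and 50 Hz line noise;
* EMG bursts on a separate channel, jittered uniformly around the cue
  (the jitter defines the ground-truth movement onset);
* occasional large-amplitude artifacts (> 100 uV) in a configurable
  fraction of trials, to exercise epoch rejection.

All randomness flows from one seeded generator per recording, so a
``(schedule, model, seed)`` triple is fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ALL_CHANNELS, EEG_CHANNELS, EMG_CHANNEL, ContinuousRecording

logger = logging.getLogger(__name__)

MOVEMENT_CONDITIONS = ("hand", "tongue")


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    condition: str  # "hand" | "tongue"
    n_trials: int
    start_s: float


@dataclass(frozen=True)
class TrialSchedule:
    """Absolute timing of movement blocks, trials and idle blocks.

    Each movement trial is preparation -> movement -> relax; the cue (t=0
    of a trial) falls at the start of the movement phase, i.e. trial ``i``
    of a block is cued at ``block.start_s + i * trial_duration + prep``.
    """

    blocks: tuple[Block, ...]
    phase_durations: tuple[float, float, float] = (2.0, 2.0, 4.0)
    idle_block_duration: float = 180.0
    n_idle_blocks: int = 3
    fs: float = 250.0
    inter_block_gap: float = 10.0

    @property
    def trial_duration(self) -> float:
        return float(sum(self.phase_durations))

    @property
    def preparation(self) -> float:
        return float(self.phase_durations[0])

    def cue_times(self, condition: str | None = None) -> np.ndarray:
        """Absolute cue times, optionally restricted to one condition."""
        cues = []
        for b in self.blocks:
            if condition is not None and b.condition != condition:
                continue
            cues.extend(
                b.start_s + i * self.trial_duration + self.preparation
                for i in range(b.n_trials)
            )
        return np.asarray(cues, dtype=float)

    def block_ids(self, condition: str | None = None) -> np.ndarray:
        """Block index (into ``self.blocks``) of each cue, same order as cue_times."""
        ids = []
        for k, b in enumerate(self.blocks):
            if condition is not None and b.condition != condition:
                continue
            ids.extend([k] * b.n_trials)
        return np.asarray(ids, dtype=int)

    @property
    def session_duration(self) -> float:
        """End of the last movement block plus one trailing gap."""
        last = max(b.start_s + b.n_trials * self.trial_duration for b in self.blocks)
        return last + self.inter_block_gap

    @property
    def total_idle_duration(self) -> float:
        return self.n_idle_blocks * self.idle_block_duration

    def n_trials(self, condition: str) -> int:
        return sum(b.n_trials for b in self.blocks if b.condition == condition)


def build_schedule(
    blocks_per_condition: int = 4,
    trials_per_block: int = 25,
    conditions: tuple[str, ...] = MOVEMENT_CONDITIONS,
    phase_durations: tuple[float, float, float] = (2.0, 2.0, 4.0),
    idle_block_duration: float = 180.0,
    n_idle_blocks: int = 3,
    fs: float = 250.0,
    inter_block_gap: float = 10.0,
    lead_in: float = 5.0,
) -> TrialSchedule:
    """Deterministic session layout.

    Default: 4 blocks x 25 trials per movement condition (100 trials each),
    conditions alternating every two blocks, and three 3-minute idle
    blocks (recorded separately, see :func:`synthesize_idle`).  The first
    block starts after ``lead_in`` seconds of plain recording so every
    trial's pre-cue window has full support.
    """
    if blocks_per_condition <= 0 or trials_per_block <= 0:
        raise ValueError("block and trial counts must be positive")
    if min(phase_durations) <= 0 or idle_block_duration <= 0 or fs <= 0:
        raise ValueError("durations and sampling rate must be positive")
    if n_idle_blocks < 0 or inter_block_gap < 0 or lead_in < 0:
        raise ValueError("idle block count, gap and lead-in must be non-negative")
    for c in conditions:
        if c not in MOVEMENT_CONDITIONS:
            raise ValueError(f"unknown condition {c!r}")

    # condition changes after every 2 blocks (i.e. every 50 trials at defaults)
    order: list[str] = []
    remaining = {c: blocks_per_condition for c in conditions}
    while any(remaining.values()):
        for c in conditions:
            take = min(2, remaining[c])
            order.extend([c] * take)
            remaining[c] -= take

    trial_dur = float(sum(phase_durations))
    blocks = []
    t = float(lead_in)
    for c in order:
        blocks.append(Block(c, trials_per_block, t))
        t += trials_per_block * trial_dur + inter_block_gap
    return TrialSchedule(
        tuple(blocks),
        tuple(float(p) for p in phase_durations),
        float(idle_block_duration),
        int(n_idle_blocks),
        float(fs),
        float(inter_block_gap),
    )


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MRCPParams:
    """Slow pre-movement negativity: raised-cosine descent to the negative
    peak, exponentially decaying rebound tapered to exactly zero."""

    lead_time: float = 2.0  # s before onset when the negativity begins
    peak_latency: float = 0.1  # s relative to onset
    peak_amplitude: float = 10.0  # uV, at unit channel gain (Cz)
    rebound_duration: float = 1.0  # s from the peak back to baseline


@dataclass(frozen=True)
class OscillationParams:
    bands: tuple[tuple[float, float], ...] = ((8.0, 13.0), (13.0, 30.0))
    base_amplitude: float = 5.0  # uV RMS per band
    erd_depth: float = 0.4  # fractional amplitude suppression in [0, 1]
    ers_gain: float = 1.3  # amplitude factor >= 1 in the rebound window
    erd_window: tuple[float, float] = (-1.0, 1.0)  # s relative to onset
    ers_window: tuple[float, float] = (1.0, 2.5)
    ramp: float = 0.25  # s cosine transition at window edges


@dataclass(frozen=True)
class NoiseParams:
    one_over_f_exponent: float = 1.0  # PSD ~ f**-exponent
    pink_sd: float = 4.0  # uV RMS of the 1/f component
    white_sd: float = 1.0  # uV RMS of the flat component
    line_amplitude: float = 2.0  # uV peak of the 50 Hz sinusoid
    line_freq: float = 50.0


@dataclass(frozen=True)
class EMGParams:
    onset_jitter: float = 0.5  # true onset ~ cue + U(-jitter, jitter)
    burst_amplitude: float = 20.0  # uV RMS of the burst plateau
    burst_band: tuple[float, float] = (20.0, 100.0)
    burst_duration: float = 2.0  # s, movement held for the whole phase
    rise_time: float = 0.05  # s ramp from rest to the plateau
    baseline_sd: float = 1.0  # uV RMS of resting EMG


@dataclass(frozen=True)
class ArtifactParams:
    rate: float = 0.02  # fraction of movement trials affected
    amplitude: float = 150.0  # uV, must exceed the +-100 uV rejection limit
    duration: float = 0.2  # s square pulse
    window: tuple[float, float] = (-1.5, -0.5)  # pulse start, s rel. onset


@dataclass(frozen=True)
class SignalModel:
    """Full parameterization of one condition's synthetic signals.

    ``mrcp_gains`` / ``erd_gains`` project the vertex-referenced MRCP and
    the ERD/ERS modulation onto each EEG channel; around-ear gains below 1
    are what makes ear-channel detection hard but possible.
    """

    mrcp: MRCPParams = MRCPParams()
    oscillation: OscillationParams = OscillationParams()
    noise: NoiseParams = NoiseParams()
    emg: EMGParams = EMGParams()
    artifacts: ArtifactParams = ArtifactParams()
    mrcp_gains: tuple[float, ...] = (0.3, 0.3, 0.3, 1.0)  # Front, Over, Back, Cz
    erd_gains: tuple[float, ...] = (0.3, 0.3, 0.3, 1.0)
    carrier: str = "noise"  # "noise" (band-limited) or "sinusoid"

    def __post_init__(self) -> None:
        if self.mrcp.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if not 0.0 <= self.oscillation.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.oscillation.ers_gain < 1.0:
            raise ValueError("ers_gain must be >= 1")
        if self.oscillation.erd_window[1] > self.oscillation.ers_window[0]:
            raise ValueError("ERD window must end before the ERS window begins")
        if self.oscillation.erd_window[0] >= self.oscillation.erd_window[1]:
            raise ValueError("erd_window must be increasing")
        if self.emg.onset_jitter < 0 or self.emg.onset_jitter > 1.0:
            # onsets must stay inside the (-1 s, 1 s) detection window
            raise ValueError("onset_jitter must lie in [0, 1] s")
        if not 0.0 <= self.artifacts.rate <= 1.0:
            raise ValueError("artifact rate must lie in [0, 1]")
        if len(self.mrcp_gains) != len(EEG_CHANNELS) or len(self.erd_gains) != len(
            EEG_CHANNELS
        ):
            raise ValueError(f"need one gain per EEG channel {EEG_CHANNELS}")
        if self.carrier not in ("noise", "sinusoid"):
            raise ValueError("carrier must be 'noise' or 'sinusoid'")


def default_models() -> dict[str, SignalModel]:
    """Per-condition defaults.

    Hand: clear vertex MRCP/ERD, heavily attenuated around the ear.
    Tongue: weaker vertex response but stronger around-ear oscillatory
    modulation, reflecting the tongue's motor representation lying closer
    to the ear electrodes.
    """
    hand = SignalModel()
    tongue = replace(
        hand,
        mrcp=replace(hand.mrcp, peak_amplitude=8.0),
        mrcp_gains=(0.3, 0.3, 0.3, 0.8),
        erd_gains=(0.6, 0.6, 0.6, 0.6),
    )
    return {"hand": hand, "tongue": tongue}


def high_snr_model() -> SignalModel:
    """Strong, barely-noisy signals on every channel (sanity-check regime)."""
    return SignalModel(
        oscillation=OscillationParams(erd_depth=0.8),
        noise=NoiseParams(pink_sd=1.0, white_sd=0.3, line_amplitude=0.5),
        artifacts=ArtifactParams(rate=0.0),
        mrcp_gains=(1.0, 1.0, 1.0, 1.0),
        erd_gains=(1.0, 1.0, 1.0, 1.0),
    )


def zero_signal_model() -> SignalModel:
    """Background and EMG only: no MRCP, no ERD/ERS (null regime)."""
    return SignalModel(
        mrcp=MRCPParams(peak_amplitude=0.0),
        oscillation=OscillationParams(erd_depth=0.0, ers_gain=1.0),
        artifacts=ArtifactParams(rate=0.0),
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-trial bookkeeping: cue, true movement onset and artifact flag."""

    trials: pd.DataFrame  # trial, condition, block, cue_s, true_onset_s, artifact

    def onsets(self, condition: str | None = None) -> np.ndarray:
        df = self.trials if condition is None else self.trials[
            self.trials.condition == condition
        ]
        return df.true_onset_s.to_numpy()

    def cues(self, condition: str | None = None) -> np.ndarray:
        df = self.trials if condition is None else self.trials[
            self.trials.condition == condition
        ]
        return df.cue_s.to_numpy()

    def artifact_indices(self, condition: str | None = None) -> np.ndarray:
        df = self.trials if condition is None else self.trials[
            self.trials.condition == condition
        ].reset_index(drop=True)
        return np.flatnonzero(df.artifact.to_numpy())

    def artifact_flags_for(
        self, t0s: np.ndarray, condition: str | None = None, tol: float = 1e-6
    ) -> np.ndarray:
        """Artifact flag per t0, matched to trials by their true onset.

        Robust to epochs that were excluded upstream (the match is by
        onset time, not position).
        """
        onsets = self.onsets(condition)
        flags = self.trials.artifact.to_numpy() if condition is None else (
            self.trials[self.trials.condition == condition].artifact.to_numpy()
        )
        out = np.zeros(len(t0s), dtype=bool)
        for i, t0 in enumerate(np.asarray(t0s, dtype=float)):
            j = np.argmin(np.abs(onsets - t0))
            if abs(onsets[j] - t0) > tol:
                raise ValueError(f"t0 {t0} matches no trial onset")
            out[i] = flags[j]
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Deterministic waveform components
# ---------------------------------------------------------------------------


def _mrcp_base(t: np.ndarray, p: MRCPParams) -> np.ndarray:
    """Unit-gain MRCP on a time grid relative to the movement onset."""
    t = np.asarray(t, dtype=float)
    y = np.zeros_like(t)
    lead, pl, amp, rd = p.lead_time, p.peak_latency, p.peak_amplitude, p.rebound_duration
    ramp = (t >= -lead) & (t <= pl)
    y[ramp] = -amp * 0.5 * (1.0 - np.cos(np.pi * (t[ramp] + lead) / (lead + pl)))
    reb = (t > pl) & (t <= pl + rd)
    u = (t[reb] - pl) / rd
    y[reb] = -amp * np.exp(-3.0 * u) * 0.5 * (1.0 + np.cos(np.pi * u))
    return y


def mrcp_waveform(
    model: SignalModel, t: np.ndarray, channels: tuple[str, ...] = EEG_CHANNELS
) -> np.ndarray:
    """Per-channel MRCP waveform (``len(channels) x len(t)``, uV).

    Zero outside ``[-lead_time, peak_latency + rebound_duration]``, reaches
    exactly ``-peak_amplitude`` at ``t = peak_latency`` on a unit-gain
    channel; other channels are scaled by their ``mrcp_gains`` entry.
    """
    base = _mrcp_base(t, model.mrcp)
    gains = dict(zip(EEG_CHANNELS, model.mrcp_gains))
    return np.stack([gains[ch] * base for ch in channels])


def _tapered_box(t: np.ndarray, a: float, b: float, ramp: float) -> np.ndarray:
    """Cosine-tapered indicator of [a, b]: 0 outside (a-ramp, b+ramp)."""
    w = np.zeros_like(t)
    if ramp > 0:
        rise = (t > a - ramp) & (t < a)
        w[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - (a - ramp)) / ramp))
        fall = (t > b) & (t < b + ramp)
        w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - b) / ramp))
    w[(t >= a) & (t <= b)] = 1.0
    return w


def _unit_modulation(model: SignalModel, t: np.ndarray, gain: float) -> np.ndarray:
    """ERD/ERS multiplier around one onset, baseline 1."""
    t = np.asarray(t, dtype=float)
    osc = model.oscillation
    m = np.ones_like(t)
    erd_factor = 1.0 - gain * osc.erd_depth
    ers_factor = 1.0 + gain * (osc.ers_gain - 1.0)
    m *= 1.0 + (erd_factor - 1.0) * _tapered_box(t, *osc.erd_window, osc.ramp)
    m *= 1.0 + (ers_factor - 1.0) * _tapered_box(t, *osc.ers_window, osc.ramp)
    return m


def oscillatory_modulation(
    model: SignalModel, t: np.ndarray, gain: float = 1.0
) -> np.ndarray:
    """Amplitude envelope of the background oscillation around one onset.

    ``base_amplitude * (1 - gain*erd_depth)`` inside the ERD window,
    ``base_amplitude * (1 + gain*(ers_gain - 1))`` inside the ERS window,
    ``base_amplitude`` elsewhere, with cosine ramps at the edges.  ``gain``
    scales the modulation depth per channel (not the baseline amplitude).
    """
    return model.oscillation.base_amplitude * _unit_modulation(model, t, gain)


def _modulation_track(
    model: SignalModel, t: np.ndarray, onsets: np.ndarray, gain: float
) -> np.ndarray:
    """Multiplicative ERD/ERS envelope over a whole recording (unit baseline)."""
    m = np.ones_like(t)
    osc = model.oscillation
    lo = osc.erd_window[0] - osc.ramp - 0.5
    hi = osc.ers_window[1] + osc.ramp + 0.5
    for onset in onsets:
        sl = slice(
            max(0, int((onset + lo) * _fs_of(t))),
            min(t.size, int((onset + hi) * _fs_of(t)) + 1),
        )
        m[sl] *= _unit_modulation(model, t[sl] - onset, gain)
    return m


def _fs_of(t: np.ndarray) -> float:
    return 1.0 / (t[1] - t[0])


# ---------------------------------------------------------------------------
# Stochastic components
# ---------------------------------------------------------------------------


def _normalize_rms(x: np.ndarray, rms: float) -> np.ndarray:
    s = np.sqrt(np.mean(x**2))
    return x * (rms / s) if s > 0 else x


def _pink_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f noise by spectral shaping of white noise; PSD ~ f**-exponent.

    The shaping is clamped below 0.1 Hz so the slow tail does not dominate
    the variance (the analysis high-passes at 0.1 Hz anyway).
    """
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f_eff = np.maximum(f, 0.1)
    shape = f_eff ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * shape, n)
    return _normalize_rms(x, rms)


def _band_noise(
    n: int, fs: float, band: tuple[float, float], rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-structure band-limited Gaussian noise at a given RMS."""
    if rms == 0:
        return np.zeros(n)
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return _normalize_rms(x, rms)


def _carrier(
    model: SignalModel,
    band: tuple[float, float],
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS oscillation carrier for one band."""
    if model.carrier == "sinusoid":
        fc = 0.5 * (band[0] + band[1])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / fs
        return np.sqrt(2.0) * np.cos(2.0 * np.pi * fc * t + phase)
    return _band_noise(n, fs, band, 1.0, rng)


def _background(
    model: SignalModel, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Pink + white + line noise for one channel."""
    nz = model.noise
    x = _pink_noise(n, fs, nz.one_over_f_exponent, nz.pink_sd, rng)
    if nz.white_sd > 0:
        x = x + nz.white_sd * rng.standard_normal(n)
    if nz.line_amplitude > 0:
        t = np.arange(n) / fs
        x = x + nz.line_amplitude * np.sin(
            2.0 * np.pi * nz.line_freq * t + rng.uniform(0, 2 * np.pi)
        )
    return x


def _burst_envelope(t: np.ndarray, p: EMGParams) -> np.ndarray:
    """EMG burst envelope: cosine rise, plateau, cosine fall (unit height)."""
    env = np.zeros_like(t)
    r = p.rise_time
    rise = (t >= 0) & (t < r)
    env[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / r))
    plateau = (t >= r) & (t <= p.burst_duration - r)
    env[plateau] = 1.0
    fall = (t > p.burst_duration - r) & (t <= p.burst_duration)
    env[fall] = 0.5 * (1.0 - np.cos(np.pi * (p.burst_duration - t[fall]) / r))
    return env


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------


def _resolve_models(
    model: SignalModel | Mapping[str, SignalModel] | None,
) -> dict[str, SignalModel]:
    if model is None:
        return default_models()
    if isinstance(model, SignalModel):
        return {c: model for c in MOVEMENT_CONDITIONS}
    return dict(model)


def synthesize_recording(
    schedule: TrialSchedule,
    model: SignalModel | Mapping[str, SignalModel] | None = None,
    seed: int = 0,
    return_components: bool = False,
):
    """Render a full movement session (all movement blocks on one timeline).

    Returns ``(recording, ground_truth)`` — channels Front/Over/Back/Cz/EMG
    at ``schedule.fs`` — or ``(recording, ground_truth, components)`` with
    per-track arrays (background, oscillation, mrcp, artifact, emg) when
    ``return_components`` is set.  EMG bursts are injected for hand trials
    only (the recorded muscle is the wrist extensor); tongue trials still
    receive MRCP/ERD locked to their jittered true onset.
    """
    models = _resolve_models(model)
    fs = schedule.fs
    n = int(round(schedule.session_duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    logger.info("synthesize_recording: seed=%d, %d samples at %g Hz", seed, n, fs)

    # --- ground truth -----------------------------------------------------
    rows = []
    trial_no = 0
    for bi, block in enumerate(schedule.blocks):
        m = models[block.condition]
        for i in range(block.n_trials):
            cue = block.start_s + i * schedule.trial_duration + schedule.preparation
            jitter = rng.uniform(-m.emg.onset_jitter, m.emg.onset_jitter)
            rows.append(
                {
                    "trial": trial_no,
                    "condition": block.condition,
                    "block": bi,
                    "cue_s": cue,
                    "true_onset_s": cue + jitter,
                    "artifact": False,
                }
            )
            trial_no += 1
    trials = pd.DataFrame(rows)

    # artifact trials: an exact, seeded fraction per condition
    for cond, m in models.items():
        idx = trials.index[trials.condition == cond].to_numpy()
        k = int(round(m.artifacts.rate * idx.size))
        if k > 0:
            chosen = rng.choice(idx, size=k, replace=False)
            trials.loc[chosen, "artifact"] = True
    gt = GroundTruth(trials)

    # --- component tracks --------------------------------------------------
    n_eeg = len(EEG_CHANNELS)
    background = np.zeros((n_eeg, n))
    oscillation = np.zeros((n_eeg, n))
    mrcp = np.zeros((n_eeg, n))
    artifact = np.zeros((n_eeg, n))

    any_model = next(iter(models.values()))
    for c in range(n_eeg):
        background[c] = _background(any_model, n, fs, rng)

    # one carrier per channel and band, multiplied by the product of all
    # trials' ERD/ERS envelopes (movement-locked, per-condition gains)
    for c, ch in enumerate(EEG_CHANNELS):
        mod = np.ones(n)
        for cond, m in models.items():
            gain = dict(zip(EEG_CHANNELS, m.erd_gains))[ch]
            mod *= _modulation_track(m, t, gt.onsets(cond), gain)
        for band in any_model.oscillation.bands:
            carrier = _carrier(any_model, band, n, fs, rng)
            oscillation[c] += any_model.oscillation.base_amplitude * carrier * mod

    # movement-locked MRCPs
    for _, tr in trials.iterrows():
        m = models[tr.condition]
        lo = int((tr.true_onset_s - m.mrcp.lead_time) * fs)
        hi = int(
            (tr.true_onset_s + m.mrcp.peak_latency + m.mrcp.rebound_duration) * fs
        ) + 1
        sl = slice(max(0, lo), min(n, hi))
        wave = mrcp_waveform(m, t[sl] - tr.true_onset_s)
        mrcp[:, sl] += wave

    # artifacts: square pulses on every EEG channel (gross motion)
    for _, tr in trials[trials.artifact].iterrows():
        m = models[tr.condition]
        start = tr.true_onset_s + rng.uniform(*m.artifacts.window)
        sign = rng.choice([-1.0, 1.0])
        sl = slice(int(start * fs), int((start + m.artifacts.duration) * fs))
        artifact[:, sl] += sign * m.artifacts.amplitude

    # --- EMG ---------------------------------------------------------------
    emg_model = models.get("hand", any_model)
    emg = _band_noise(n, fs, emg_model.emg.burst_band, emg_model.emg.baseline_sd, rng)
    for _, tr in trials[trials.condition == "hand"].iterrows():
        p = models["hand"].emg
        sl = slice(
            int(tr.true_onset_s * fs),
            min(n, int((tr.true_onset_s + p.burst_duration) * fs) + 1),
        )
        env = _burst_envelope(t[sl] - tr.true_onset_s, p)
        burst = _band_noise(sl.stop - sl.start, fs, p.burst_band, 1.0, rng)
        emg[sl] += p.burst_amplitude * env * burst

    eeg = background + oscillation + mrcp + artifact
    data = np.vstack([eeg, emg[None, :]])
    rec = ContinuousRecording(data, fs, ALL_CHANNELS)
    if return_components:
        components = {
            "background": background,
            "oscillation": oscillation,
            "mrcp": mrcp,
            "artifact": artifact,
            "emg": emg,
        }
        return rec, gt, components
    return rec, gt


def synthesize_idle(
    model: SignalModel | Mapping[str, SignalModel] | None,
    duration: float,
    seed: int = 0,
    fs: float = 250.0,
) -> ContinuousRecording:
    """Background-only recording: unmodulated oscillation + noise, resting EMG.

    No MRCP, no ERD/ERS, no EMG bursts — the no-movement class.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    m = next(iter(_resolve_models(model).values()))
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    eeg = np.zeros((len(EEG_CHANNELS), n))
    for c in range(len(EEG_CHANNELS)):
        eeg[c] = _background(m, n, fs, rng)
        for band in m.oscillation.bands:
            eeg[c] += m.oscillation.base_amplitude * _carrier(m, band, n, fs, rng)
    emg = _band_noise(n, fs, m.emg.burst_band, m.emg.baseline_sd, rng)
    return ContinuousRecording(np.vstack([eeg, emg[None, :]]), fs, ALL_CHANNELS)


def events_table(schedule: TrialSchedule) -> pd.DataFrame:
    """Cue table (onset_s, type, block) for a schedule."""
    rows = []
    for bi, b in enumerate(schedule.blocks):
        for i in range(b.n_trials):
            rows.append(
                {
                    "onset_s": b.start_s + i * schedule.trial_duration
                    + schedule.preparation,
                    "type": f"cue_{b.condition}",
                    "block": bi,
                }
            )
    return pd.DataFrame(rows)
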