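"""Generator contracts: schedule layout, waveform shapes, determinism,
superposition, ground-truth bookkeeping, idle statistics."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from earbci.io import EEG_CHANNELS
from earbci.simulate import (
    ArtifactParams,
    NoiseParams,
    OscillationParams,
    SignalModel,
    build_schedule,
    mrcp_waveform,
    oscillatory_modulation,
    synthesize_idle,
    synthesize_recording,
)


class TestSchedule:
    def test_default_yields_100_trials_per_condition(self):
        s = build_schedule()
        assert len(s.cue_times("hand")) == 100
        assert len(s.cue_times("tongue")) == 100

    def test_default_idle_time_is_three_three_minute_blocks(self):
        assert build_schedule().total_idle_duration == 3 * 180.0

    def test_cue_times_follow_phase_layout(self):
        s = build_schedule(blocks_per_condition=1, trials_per_block=2,
                           conditions=("hand",))
        start = s.blocks[0].start_s
        np.testing.assert_allclose(s.cue_times("hand"), [start + 2.0, start + 10.0])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"blocks_per_condition": 0},
            {"trials_per_block": -1},
            {"phase_durations": (0.0, 2.0, 4.0)},
            {"idle_block_duration": -5.0},
            {"fs": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_schedule(**kwargs)

    def test_condition_alternates_every_two_blocks(self):
        s = build_schedule()
        conds = [b.condition for b in s.blocks]
        assert conds == ["hand", "hand", "tongue", "tongue"] * 2


class TestMRCPWaveform:
    def test_peak_value_at_peak_latency(self):
        m = SignalModel()
        t = np.array([m.mrcp.peak_latency])
        w = mrcp_waveform(m, t)
        cz = EEG_CHANNELS.index("Cz")
        assert w[cz, 0] == pytest.approx(-m.mrcp.peak_amplitude)

    def test_zero_outside_support(self):
        m = SignalModel()
        t = np.array([-m.mrcp.lead_time - 0.01, m.mrcp.peak_latency
                      + m.mrcp.rebound_duration + 0.01])
        assert np.all(mrcp_waveform(m, t) == 0.0)

    def test_grid_minimum_equals_negative_peak(self):
        # brute-force scan over a dense grid that contains the peak latency
        m = SignalModel()
        t = np.arange(-3.0, 2.0, 1e-3)
        t = np.union1d(t, [m.mrcp.peak_latency])
        w = mrcp_waveform(m, t)
        cz = EEG_CHANNELS.index("Cz")
        assert abs(w[cz].min() + m.mrcp.peak_amplitude) < 1e-9
        assert np.all(w >= -m.mrcp.peak_amplitude - 1e-12)

    def test_ear_channels_scaled_by_gain(self):
        m = SignalModel()
        t = np.linspace(-2, 1, 500)
        w = mrcp_waveform(m, t)
        cz = EEG_CHANNELS.index("Cz")
        for i, g in enumerate(m.mrcp_gains):
            np.testing.assert_allclose(w[i], g * w[cz] / m.mrcp_gains[cz])


class TestOscillatoryModulation:
    def test_identity_when_unmodulated(self):
        m = dataclasses.replace(
            SignalModel(), oscillation=OscillationParams(erd_depth=0.0, ers_gain=1.0)
        )
        t = np.linspace(-3, 4, 1000)
        np.testing.assert_allclose(
            oscillatory_modulation(m, t), m.oscillation.base_amplitude
        )

    def test_full_suppression_inside_erd_window(self):
        m = dataclasses.replace(
            SignalModel(), oscillation=OscillationParams(erd_depth=1.0)
        )
        t = np.linspace(*m.oscillation.erd_window, 200)
        np.testing.assert_allclose(oscillatory_modulation(m, t), 0.0, atol=1e-12)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(
                SignalModel(),
                oscillation=OscillationParams(
                    erd_window=(-1.0, 1.5), ers_window=(1.0, 2.5)
                ),
            )

    @pytest.mark.parametrize("depth", np.round(np.arange(0.0, 1.01, 0.1), 1))
    def test_erd_power_ratio_matches_squared_depth(self, depth):
        # oracle: direct variance ratio of a synthesized modulated sinusoid
        m = dataclasses.replace(
            SignalModel(), oscillation=OscillationParams(erd_depth=float(depth))
        )
        t = np.arange(-4.0, 4.0, 1 / 250)
        x = oscillatory_modulation(m, t) * np.cos(2 * np.pi * 10.0 * t)
        erd = (t >= -1.0) & (t < 1.0)
        baseline = (t >= -4.0) & (t < -2.0)
        ratio = np.var(x[erd]) / np.var(x[baseline])
        assert ratio == pytest.approx((1 - depth) ** 2, abs=0.03, rel=0.1)


class TestSynthesizeRecording:
    def test_same_seed_bitwise_identical(self, small_schedule, clean_model):
        rec1, gt1 = synthesize_recording(small_schedule, clean_model, seed=5)
        rec2, gt2 = synthesize_recording(small_schedule, clean_model, seed=5)
        assert np.array_equal(rec1.data, rec2.data)
        assert gt1.trials.equals(gt2.trials)

    def test_different_seed_differs(self, small_schedule, clean_model):
        rec1, _ = synthesize_recording(small_schedule, clean_model, seed=5)
        rec2, _ = synthesize_recording(small_schedule, clean_model, seed=6)
        assert not np.array_equal(rec1.data, rec2.data)

    def test_noise_free_epoch_is_mrcp_plus_oscillation(
        self, small_schedule, noise_free_model
    ):
        rec, gt, comp = synthesize_recording(
            small_schedule, noise_free_model, seed=3, return_components=True
        )
        np.testing.assert_allclose(
            rec.data[:4], comp["mrcp"] + comp["oscillation"], atol=1e-12
        )
        # second trial: full window support guaranteed
        onset = gt.onsets("hand")[1]
        fs = small_schedule.fs
        i0 = int(round((onset - 2.0) * fs))
        t = np.arange(i0, i0 + 750) / fs - onset
        expected = mrcp_waveform(noise_free_model, t) + comp["oscillation"][:, i0:i0 + 750]
        np.testing.assert_allclose(rec.data[:4, i0:i0 + 750], expected, atol=1e-9)

    def test_artifact_count_matches_ground_truth(self, small_schedule):
        m = dataclasses.replace(
            SignalModel(), artifacts=ArtifactParams(rate=0.2, amplitude=150.0)
        )
        rec, gt = synthesize_recording(small_schedule, m, seed=9)
        assert len(gt.artifact_indices("hand")) == round(0.2 * 10)

    def test_onsets_within_jitter_of_cues(self, hand_session, hand_schedule):
        _, gt = hand_session
        jitter = SignalModel().emg.onset_jitter
        assert np.all(np.abs(gt.onsets("hand") - gt.cues("hand")) <= jitter)
        np.testing.assert_allclose(gt.cues("hand"), hand_schedule.cue_times("hand"))


class TestSynthesizeIdle:
    def test_duration_and_channels(self):
        rec = synthesize_idle(SignalModel(), 180.0, seed=0)
        assert rec.n_samples == 45_000
        assert rec.n_channels == 5

    def test_positive_duration_required(self):
        with pytest.raises(ValueError):
            synthesize_idle(SignalModel(), 0.0)

    def test_zero_mean_background(self):
        # Monte-Carlo: channel means over independent seeds scatter around 0
        means = np.array(
            [synthesize_idle(SignalModel(), 60.0, seed=s).data[:4].mean(axis=1)
             for s in range(12)]
        )
        grand = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        assert np.all(np.abs(grand) <= 3 * se + 1e-9)

    def test_one_over_f_slope_recovered(self):
        # periodogram log-log regression oracle on the pink component alone
        for exponent in (0.8, 1.0, 1.4):
            m = dataclasses.replace(
                SignalModel(),
                noise=NoiseParams(
                    one_over_f_exponent=exponent, pink_sd=4.0, white_sd=0.0,
                    line_amplitude=0.0,
                ),
                oscillation=dataclasses.replace(
                    SignalModel().oscillation, base_amplitude=0.0
                ),
            )
            rec = synthesize_idle(m, 180.0, seed=11)
            f, p = sps.welch(rec.data[0], fs=250.0, nperseg=4096)
            sel = (f >= 1.0) & (f <= 30.0)
            slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
            assert slope == pytest.approx(-exponent, abs=0.3)


class TestModelValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("erd_depth", -0.1),
            ("erd_depth", 1.2),
            ("ers_gain", 0.5),
        ],
    )
    def test_oscillation_bounds(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(
                SignalModel(), oscillation=dataclasses.replace(
                    SignalModel().oscillation, **{field: value}
                )
            )

    def test_negative_mrcp_amplitude_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(
                SignalModel(),
                mrcp=dataclasses.replace(SignalModel().mrcp, peak_amplitude=-1.0),
            )

    def test_excessive_jitter_rejected(self):
        # jitter must keep true onsets inside the (-1, 1) s detection window
        with pytest.raises(ValueError):
            dataclasses.replace(
                SignalModel(),
                emg=dataclasses.replace(SignalModel().emg, onset_jitter=1.5),
            )
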