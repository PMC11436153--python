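"""Feature contracts: interval means, template correlation, band power,
subset assembly dimensions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earbci.epochs import CONTROL_WINDOW, REHAB_WINDOW, EpochSet, EpochWindow
from earbci.features import (
    DEFAULT_BANDS,
    BandDefinition,
    assemble_features,
    band_power,
    build_template,
    template_xcorr,
    temporal_means,
)
from earbci.io import EEG_CHANNELS

FS = 250.0
EAR = ("Front", "Over", "Back")


def make_epochs(data, window=CONTROL_WINDOW, channels=None):
    n, c, _ = data.shape
    channels = channels or EEG_CHANNELS[:c]
    return EpochSet(
        data, np.full(n, "movement", dtype=object), "emg_onset", window,
        tuple(channels), FS,
    )


class TestTemporalMeans:
    def test_constant_epoch_gives_constant_means(self):
        eps = make_epochs(np.full((2, 3, 750), 7.5))
        fm = temporal_means(eps)
        np.testing.assert_allclose(fm.values, 7.5)

    @pytest.mark.parametrize("window,n_int", [(CONTROL_WINDOW, 6), (REHAB_WINDOW, 4)])
    def test_interval_counts(self, window, n_int):
        eps = make_epochs(np.zeros((1, 3, window.n_samples(FS))), window)
        assert temporal_means(eps).d == 3 * n_int

    def test_ramp_means_match_direct_summation(self):
        # oracle: brute-force sample means of each half of a 1 s ramp
        ramp = np.linspace(0.0, 1.0, 250, endpoint=False)
        eps = make_epochs(ramp[None, None, :], EpochWindow(0.0, 1.0), channels=("Cz",))
        fm = temporal_means(eps)
        expected = [ramp[:125].mean(), ramp[125:].mean()]
        np.testing.assert_allclose(fm.values[0], expected)

    def test_indivisible_window_rejected(self):
        eps = make_epochs(np.zeros((1, 3, 750)))
        with pytest.raises(ValueError, match="divisible"):
            temporal_means(eps, interval=0.7)


class TestTemplate:
    def test_single_epoch_template_is_that_epoch(self, rng):
        data = rng.standard_normal((1, 4, 750))
        tpl = build_template(make_epochs(data))
        np.testing.assert_allclose(tpl.waveform, data[0])

    def test_opposite_epochs_yield_zero_template(self, rng):
        x = rng.standard_normal((1, 4, 750))
        tpl = build_template(make_epochs(np.concatenate([x, -x])))
        np.testing.assert_allclose(tpl.waveform, 0.0, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_template(make_epochs(np.empty((0, 4, 750))))

    def test_noise_free_template_equals_mrcp_component(
        self, small_schedule, noise_free_model
    ):
        from earbci.epochs import extract_epochs
        from earbci.simulate import OscillationParams, mrcp_waveform, synthesize_recording

        m = dataclasses.replace(
            noise_free_model, oscillation=OscillationParams(base_amplitude=0.0)
        )
        rec, gt = synthesize_recording(small_schedule, m, seed=2)
        eps = extract_epochs(rec, gt.onsets("hand")[1:], CONTROL_WINDOW, EEG_CHANNELS)
        tpl = build_template(eps)
        # each epoch is the deterministic MRCP sampled on its own snapped grid
        fs = small_schedule.fs
        waves = []
        for onset in gt.onsets("hand")[1:]:
            i0 = int(round((onset - 2.0) * fs))
            t = np.arange(i0, i0 + 750) / fs - onset
            waves.append(mrcp_waveform(m, t))
        np.testing.assert_allclose(tpl.waveform, np.mean(waves, axis=0), atol=1e-9)


class TestTemplateXcorr:
    def test_self_correlation_is_one(self, rng):
        data = rng.standard_normal((1, 4, 750))
        tpl = build_template(make_epochs(data))
        fm = template_xcorr(make_epochs(data), tpl)
        np.testing.assert_allclose(fm.values, 1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        data = rng.standard_normal((1, 4, 750))
        tpl = build_template(make_epochs(data))
        fm = template_xcorr(make_epochs(-data), tpl)
        np.testing.assert_allclose(fm.values, -1.0)

    def test_orthogonal_signals_give_zero(self):
        t = np.arange(750) / FS
        epoch = np.sin(2 * np.pi * 4.0 * t)[None, None, :].repeat(4, axis=1)
        templ = np.cos(2 * np.pi * 4.0 * t)[None, :].repeat(4, axis=0)
        tpl = build_template(make_epochs(templ[None]))
        fm = template_xcorr(make_epochs(epoch), tpl)
        np.testing.assert_allclose(fm.values, 0.0, atol=1e-6)

    def test_zero_epoch_or_template_defined_as_zero(self, rng):
        data = rng.standard_normal((1, 4, 750))
        zero = np.zeros((1, 4, 750))
        tpl = build_template(make_epochs(data))
        np.testing.assert_allclose(template_xcorr(make_epochs(zero), tpl).values, 0.0)
        tpl0 = build_template(make_epochs(zero))
        np.testing.assert_allclose(template_xcorr(make_epochs(data), tpl0).values, 0.0)

    def test_shape_mismatch_rejected(self, rng):
        tpl = build_template(make_epochs(rng.standard_normal((1, 4, 750))))
        with pytest.raises(ValueError):
            template_xcorr(make_epochs(rng.standard_normal((1, 4, 500)),
                                       REHAB_WINDOW), tpl)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(42)
        data = rng.standard_normal((2, 4, 750))
        tpl = build_template(make_epochs(data))
        base = template_xcorr(make_epochs(data), tpl).values
        scaled = template_xcorr(make_epochs(scale * data), tpl).values
        np.testing.assert_allclose(scaled, base, rtol=1e-9)

    def test_raw_mode_scales_with_amplitude(self, rng):
        data = rng.standard_normal((1, 4, 750))
        tpl = build_template(make_epochs(data))
        raw = template_xcorr(make_epochs(data), tpl, normalized=False).values
        raw2 = template_xcorr(make_epochs(2 * data), tpl, normalized=False).values
        np.testing.assert_allclose(raw2, 2 * raw, rtol=1e-9)


class TestBandPower:
    def test_zero_epoch_zero_power(self):
        fm = band_power(make_epochs(np.zeros((1, 3, 750))))
        np.testing.assert_allclose(fm.values, 0.0)

    def test_alpha_sine_concentrates_in_alpha_band(self):
        t = np.arange(750) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        fm = band_power(make_epochs(x[None, None, :], channels=("Cz",)))
        total = fm.values[0].sum()
        alpha = fm.values[0][[b.name for b in DEFAULT_BANDS].index("alpha")]
        assert alpha / total > 0.90

    def test_white_noise_power_flat_per_hz(self, rng):
        # flat-spectrum oracle: mean band power is bandwidth-independent
        data = rng.standard_normal((200, 1, 750))
        fm = band_power(make_epochs(data, channels=("Cz",)))
        per_band = fm.values.mean(axis=0)
        assert np.all(np.abs(per_band / per_band.mean() - 1.0) < 0.15)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(
                make_epochs(np.zeros((1, 3, 750))),
                bands=(BandDefinition("hf", 100.0, 130.0),),
            )

    def test_nonnegative(self, rng):
        fm = band_power(make_epochs(rng.standard_normal((5, 3, 750))))
        assert np.all(fm.values >= 0.0)


class TestAssembleFeatures:
    def _parts(self, n_ch, window):
        n = 4
        data = np.random.default_rng(0).standard_normal(
            (n, n_ch, window.n_samples(FS))
        )
        eps = make_epochs(data, window, channels=EEG_CHANNELS[:n_ch])
        tpl = build_template(eps)
        return [temporal_means(eps), template_xcorr(eps, tpl), band_power(eps)]

    @pytest.mark.parametrize(
        "n_ch,window,subset,expected_d",
        [
            (3, CONTROL_WINDOW, "all", 33),
            (3, CONTROL_WINDOW, "spectral", 12),
            (3, CONTROL_WINDOW, "temporal", 21),
            (1, REHAB_WINDOW, "temporal", 5),
        ],
    )
    def test_dimensions(self, n_ch, window, subset, expected_d):
        fm = assemble_features(subset, self._parts(n_ch, window))
        assert fm.d == expected_d

    def test_inconsistent_counts_rejected(self):
        parts = self._parts(3, CONTROL_WINDOW)
        small = make_epochs(np.zeros((2, 3, 750)))
        parts[2] = band_power(small)
        with pytest.raises(ValueError, match="inconsistent"):
            assemble_features("all", parts)

    def test_column_order_temporal_then_xcorr_then_spectral(self):
        fm = assemble_features("all", self._parts(1, REHAB_WINDOW))
        fams = [nm.family for nm in fm.names]
        assert fams == ["temporal_mean"] * 4 + ["template_xcorr"] + ["band_power"] * 4

    def test_bitwise_reproducible(self):
        a = assemble_features("all", self._parts(3, CONTROL_WINDOW))
        b = assemble_features("all", self._parts(3, CONTROL_WINDOW))
        np.testing.assert_array_equal(a.values, b.values)
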