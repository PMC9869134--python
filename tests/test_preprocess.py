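"""Preprocessing primitives against independent signal-processing oracles."""

import numpy as np
import pytest
from scipy import signal

from bifuse.containers import ChromophoreEpoch, Epoch
from bifuse.preprocess import (
    BeerLambertParams,
    bandpass,
    baseline_correct,
    beer_lambert,
    beer_lambert_forward,
    common_average_reference,
    compute_coe,
    normalize_amplitude,
    resample,
)


def make_epoch(data, rate=200.0, t_start=0.0, modality="eeg"):
    return Epoch(modality=modality, data=np.atleast_2d(data), sample_rate_hz=rate,
                 t_start_s=t_start, label="left", parent_trial_id="t0")


class TestResample:
    def test_200_to_128_sample_count(self, rng):
        out = resample(make_epoch(rng.standard_normal((3, 1000))), 128.0)
        assert out.data.shape == (3, 640)
        assert out.sample_rate_hz == 128.0

    def test_10_to_128_sample_count(self, rng):
        out = resample(make_epoch(rng.standard_normal((2, 100)), rate=10.0), 128.0)
        assert out.data.shape == (2, 1280)

    def test_tone_survives_resampling(self):
        """Periodogram oracle: a 5 Hz tone stays the dominant peak."""
        t = np.arange(2000) / 200.0
        out = resample(make_epoch(np.sin(2 * np.pi * 5 * t)), 128.0)
        f, p = signal.periodogram(out.data[0], fs=128.0)
        assert abs(f[np.argmax(p)] - 5.0) < 0.2

    def test_nonpositive_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            resample(make_epoch(rng.standard_normal((1, 100))), 0.0)


class TestCommonAverageReference:
    def test_balanced_pair_unchanged(self):
        e = make_epoch(np.array([[1.0] * 10, [-1.0] * 10]))
        np.testing.assert_allclose(common_average_reference(e).data, e.data)

    def test_identical_channels_zeroed(self):
        e = make_epoch(np.ones((4, 10)))
        np.testing.assert_allclose(common_average_reference(e).data, 0.0)

    def test_channel_mean_is_zero(self, rng):
        e = make_epoch(rng.standard_normal((6, 50)))
        out = common_average_reference(e)
        np.testing.assert_allclose(out.data.sum(axis=0), 0.0, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            common_average_reference(make_epoch(np.ones((1, 10))))


class TestBandpass:
    @pytest.mark.parametrize("freq,lo,hi", [(12.0, 0.9, 1.1), (50.0, 0.0, 0.1)])
    def test_amplitude_ratio(self, freq, lo, hi):
        """Filter frequency-response oracle on pure tones (8-25 Hz band)."""
        t = np.arange(4000) / 200.0
        e = make_epoch(np.sin(2 * np.pi * freq * t))
        out = bandpass(e, 8.0, 25.0)
        mid = slice(1000, 3000)  # avoid filter edges
        ratio = out.data[0, mid].std() / e.data[0, mid].std()
        assert lo <= ratio <= hi

    def test_dc_removed(self):
        e = make_epoch(np.full((2, 2000), 3.0))
        out = bandpass(e, 8.0, 25.0)
        assert np.abs(out.data).max() < 1e-6

    def test_band_outside_nyquist_rejected(self, rng):
        e = make_epoch(rng.standard_normal((1, 100)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(e, 8.0, 150.0)
        with pytest.raises(ValueError):
            bandpass(e, -1.0, 25.0)

    def test_linearity(self, rng):
        x = rng.standard_normal((3, 500))
        a = bandpass(make_epoch(3.0 * x), 8.0, 25.0).data
        b = 3.0 * bandpass(make_epoch(x), 8.0, 25.0).data
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestBeerLambert:
    BASE_N = 5  # leading samples at baseline intensity

    def _intensity_epoch(self, dod, baseline=1.0):
        """Two-wavelength intensity epoch realizing a given ΔOD, preceded by
        BASE_N samples at the baseline intensity."""
        dod = np.asarray(dod)
        intensity = baseline * 10.0 ** (-dod)
        lead = np.full(dod.shape[:-1] + (self.BASE_N,), baseline)
        intensity = np.concatenate([lead, intensity], axis=-1)
        names = [f"c{i}_wl1" for i in range(dod.shape[1])] + [
            f"c{i}_wl2" for i in range(dod.shape[1])]
        return make_epoch(intensity.reshape(-1, intensity.shape[-1]), rate=10.0).replace(
            channel_names=names)

    def _convert(self, dod, params=None):
        ce = beer_lambert(self._intensity_epoch(dod), params,
                          baseline_window=(0, self.BASE_N))
        crop = lambda e: e.replace(data=e.data[:, self.BASE_N:])
        return ChromophoreEpoch(hbo=crop(ce.hbo), hbr=crop(ce.hbr))

    def test_constant_intensity_gives_zero(self):
        dod = np.zeros((2, 3, 20))
        ce = self._convert(dod)
        np.testing.assert_allclose(ce.hbo.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(ce.hbr.data, 0.0, atol=1e-12)

    def test_identity_system_passes_od_through(self, rng):
        dod = rng.uniform(0.0, 0.5, size=(2, 2, 15))
        params = BeerLambertParams(extinction_matrix=np.eye(2), dpf=(1.0, 1.0),
                                   separation_cm=1.0)
        ce = self._convert(dod, params)
        np.testing.assert_allclose(ce.hbo.data, dod[0], atol=1e-10)
        np.testing.assert_allclose(ce.hbr.data, dod[1], atol=1e-10)

    def test_hand_solved_linear_system(self):
        """E = [[2,1],[1,2]], ΔOD = [3,3], pathlength 1 -> Δc = [1,1]."""
        dod = np.array([[[3.0]], [[3.0]]])
        params = BeerLambertParams(extinction_matrix=np.array([[2.0, 1.0], [1.0, 2.0]]),
                                   dpf=(1.0, 1.0), separation_cm=1.0)
        ce = self._convert(dod, params)
        np.testing.assert_allclose(ce.hbo.data, 1.0, atol=1e-10)
        np.testing.assert_allclose(ce.hbr.data, 1.0, atol=1e-10)

    def test_forward_model_inverts(self, rng):
        dod = rng.uniform(0.01, 0.4, size=(2, 4, 30))
        ce = self._convert(dod)
        np.testing.assert_allclose(beer_lambert_forward(ce), dod, atol=1e-8)

    def test_nonpositive_intensity_rejected(self):
        e = make_epoch(np.array([[1.0, -0.5], [1.0, 1.0]]), rate=10.0)
        with pytest.raises(ValueError, match="positive"):
            beer_lambert(e)

    def test_singular_extinction_rejected(self):
        params = BeerLambertParams(extinction_matrix=np.ones((2, 2)))
        with pytest.raises(ValueError, match="singular"):
            params.system_matrix()


class TestBaselineCorrect:
    def test_constant_zeroed(self):
        e = make_epoch(np.full((2, 128 * 15), 4.0), rate=128.0, t_start=-5.0)
        out = baseline_correct(e)
        np.testing.assert_allclose(out.data, 0.0)

    def test_arithmetic_example(self):
        rate = 10.0
        data = np.full((1, 150), 2.0)
        data[0, 50:] = 5.0  # baseline window [-5,-2] maps to samples 0..30
        e = make_epoch(data, rate=rate, t_start=-5.0)
        out = baseline_correct(e)
        assert out.data[0, 100] == pytest.approx(3.0)

    def test_window_outside_context_rejected(self):
        e = make_epoch(np.zeros((1, 100)), rate=10.0, t_start=0.0)
        with pytest.raises(ValueError, match="outside"):
            baseline_correct(e, (-5.0, -2.0))

    def test_baseline_mean_zero_for_random_input(self, rng):
        e = make_epoch(rng.standard_normal((3, 150)), rate=10.0, t_start=-5.0)
        out = baseline_correct(e)
        seg = out.data[:, :30]
        np.testing.assert_allclose(seg.mean(axis=1), 0.0, atol=1e-12)


class TestNormalize:
    def test_extremes(self):
        e = make_epoch(np.array([[-5.0, 3.0, 0.0]]))
        out = normalize_amplitude(e)
        np.testing.assert_allclose(out.data, [[-1.0, 0.6, 0.0]])

    def test_idempotent(self, rng):
        e = normalize_amplitude(make_epoch(rng.standard_normal((3, 40))))
        again = normalize_amplitude(e)
        np.testing.assert_allclose(again.data, e.data)

    def test_all_zero_warns_and_passes_through(self):
        e = make_epoch(np.zeros((2, 10)))
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_amplitude(e)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_trial_scope_preserves_relative_channel_scale(self):
        e = make_epoch(np.array([[2.0, -2.0], [1.0, -1.0]]))
        out = normalize_amplitude(e, scope="trial")
        np.testing.assert_allclose(out.data, [[1.0, -1.0], [0.5, -0.5]])


class TestCoe:
    def _pair(self, hbo, hbr):
        a = make_epoch(hbo, rate=128.0, modality="hbo")
        b = make_epoch(hbr, rate=128.0, modality="hbr")
        return ChromophoreEpoch(hbo=a, hbr=b)

    def test_equal_planes_zero(self, rng):
        x = rng.standard_normal((2, 20))
        np.testing.assert_allclose(compute_coe(self._pair(x, x)).data, 0.0)

    def test_constants(self):
        out = compute_coe(self._pair(np.full((1, 5), 2.0), np.full((1, 5), 0.5)))
        np.testing.assert_allclose(out.data, 1.5)

    def test_linearity(self, rng):
        h1, r1 = rng.standard_normal((2, 2, 20))
        h2, r2 = rng.standard_normal((2, 2, 20))
        lhs = compute_coe(self._pair(h1 + h2, r1 + r2)).data
        rhs = compute_coe(self._pair(h1, r1)).data + compute_coe(self._pair(h2, r2)).data
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestChains:
    def test_eeg_chain_shapes_and_labels(self, small_dataset, small_pairs):
        eeg_rec, _ = small_dataset
        epochs = [e for e, _ in small_pairs]
        assert len(epochs) == len(eeg_rec.events)
        for ep, (_, label) in zip(epochs, eeg_rec.events):
            assert ep.data.shape == (8, 1280)  # 8 channels x 10 s x 128 Hz
            assert ep.sample_rate_hz == 128.0
            assert ep.label == label
            assert np.abs(ep.data).max() <= 1.0 + 1e-9

    def test_fnirs_chain_shapes(self, small_pairs):
        for _, ce in small_pairs:
            assert ce.hbo.data.shape == (8, 1280)
            assert ce.hbr.data.shape == (8, 1280)
            assert np.abs(ce.hbo.data).max() <= 1.0 + 1e-9

    def test_cardiac_band_attenuated(self):
        """A 1 Hz oscillation must be suppressed >= 10x by the 0.01-0.1 Hz
        band-pass (frequency-response oracle)."""
        from bifuse.preprocess import _bandpass_array

        t = np.arange(3000) / 10.0
        cardiac = np.sin(2 * np.pi * 1.0 * t)[None, :]
        out = _bandpass_array(cardiac, 0.01, 0.1, 10.0, 4)
        mid = slice(500, 2500)
        assert out[0, mid].std() <= cardiac[0, mid].std() / 10.0

    def test_missing_channels_listed(self, small_dataset):
        from bifuse.preprocess import preprocess_eeg

        eeg_rec, _ = small_dataset
        with pytest.raises(KeyError, match="Oz"):
            preprocess_eeg(eeg_rec, montage=["Oz", "FCC5h"])
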