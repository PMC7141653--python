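"""Binary rasterization, the 1/N spectrum, best-beat selection and GOF/nGOF."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhythmkit import (
    ConfigurationError,
    ValidationError,
    binarize_onsets,
    fft_best_beat,
    frequency_resolution,
    gen_jittered_comb,
    goodness_of_fit,
    species_standin,
)
from rhythmkit.fourier import BinarySequence


def direct_dft_magnitudes(x):
    """O(N^2) direct-sum transform with the 1/N convention (oracle)."""
    N = len(x)
    n = np.arange(N)
    k = n[: N // 2 + 1]
    W = np.exp(-2j * np.pi * np.outer(k, n) / N)
    return np.abs(W @ np.asarray(x, dtype=float)) / N


onset_sets = st.lists(
    st.floats(min_value=0, max_value=5, allow_nan=False), min_size=2, max_size=40,
    unique=True,
)


class TestBinarize:
    def test_comb_indices(self):
        b = binarize_onsets([0.0, 0.1, 0.2], dt=0.005)
        assert b.n_samples == 41
        assert np.flatnonzero(b.values).tolist() == [0, 20, 40]

    def test_first_onset_shifts_to_sample_zero(self):
        b = binarize_onsets([0.05, 0.15], dt=0.005)
        assert b.n_samples == 21
        assert np.flatnonzero(b.values).tolist() == [0, 20]

    def test_collision_collapses_with_count(self):
        with pytest.warns(UserWarning, match="coarser"):
            b = binarize_onsets([0.0, 0.001, 0.1], dt=0.005)
        assert np.flatnonzero(b.values).tolist() == [0, 20]
        assert b.n_collisions == 1

    def test_starts_and_ends_with_event(self):
        b = binarize_onsets([0.3, 0.45, 0.91], dt=0.005)
        assert b.values[0] == 1 and b.values[-1] == 1

    def test_rejects_single_onset(self):
        with pytest.raises(ValidationError):
            binarize_onsets([0.1])

    @given(onset_sets)
    def test_zero_bin_equals_time_domain_mean(self, onsets):
        b = binarize_onsets(onsets, dt=0.01)
        spec = fft_best_beat(b, f_max=50.0) if b.n_samples >= 4 else None
        if spec is not None:
            assert spec.p0 == pytest.approx(b.n_events / b.n_samples, rel=1e-12)


class TestSpectrum:
    def test_agrees_with_direct_dft_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(8, 512))
            x = np.zeros(n)
            ones = rng.choice(n, size=int(rng.integers(2, max(3, n // 4))), replace=False)
            x[ones] = 1
            x[0] = x[-1] = 1
            b = BinarySequence(values=x, dt=0.005)
            spec = fft_best_beat(b)
            expected = direct_dft_magnitudes(x)
            np.testing.assert_allclose(spec.amplitudes, expected, rtol=1e-9, atol=1e-12)

    def test_comb_beat_within_one_bin_of_truth(self):
        onsets = np.arange(21) * 0.1
        spec = fft_best_beat(binarize_onsets(onsets, 0.005))
        assert spec.p0 == pytest.approx(21 / 401, rel=1e-12)
        assert abs(spec.best_frequency - 10.0) <= spec.freq_resolution

    def test_dc_dominates_all_bins(self, rng):
        for _ in range(5):
            onsets = np.sort(rng.uniform(0, 3, size=12))
            spec = fft_best_beat(binarize_onsets(onsets, 0.005))
            assert np.all(spec.amplitudes <= spec.p0 + 1e-12)

    def test_all_ones_raster_flags_no_beat(self):
        b = BinarySequence(values=np.ones(50), dt=0.005)
        spec = fft_best_beat(b)
        assert spec.no_beat
        assert spec.gof == 0.0

    def test_translation_invariance(self):
        onsets = np.array([0.0, 0.11, 0.24, 0.35, 0.52])
        a = fft_best_beat(binarize_onsets(onsets, 0.005))
        c = fft_best_beat(binarize_onsets(onsets + 7.3, 0.005))
        np.testing.assert_allclose(a.amplitudes, c.amplitudes, atol=1e-12)
        assert a.best_frequency == c.best_frequency
        assert a.ngof == pytest.approx(c.ngof, rel=1e-12)

    def test_f_max_above_nyquist_is_configuration_error(self):
        b = binarize_onsets(np.arange(5) * 0.1, dt=0.005)
        with pytest.raises(ConfigurationError, match="Nyquist"):
            fft_best_beat(b, f_max=150.0)


class TestGoodnessOfFit:
    def test_gof_is_share_of_internal_reference(self):
        spec = fft_best_beat(binarize_onsets(np.arange(21) * 0.1, 0.005))
        gof, ngof = goodness_of_fit(spec)
        assert gof == pytest.approx(spec.p_best / spec.p0)
        assert ngof == pytest.approx(gof / spec.n_samples)
        assert 0 <= gof <= 1

    def test_seconds_normalization_option(self):
        spec = fft_best_beat(binarize_onsets(np.arange(21) * 0.1, 0.005))
        _, ngof_s = goodness_of_fit(spec, length_units="seconds")
        assert ngof_s == pytest.approx(spec.gof / spec.duration)

    def test_jitter_degrades_gof(self):
        perfect = fft_best_beat(binarize_onsets(np.arange(21) * 0.1, 0.005))
        jittered = gen_jittered_comb(0.1, 0.2, 21, seed=5)
        noisy = fft_best_beat(binarize_onsets(jittered.onsets, 0.005))
        assert perfect.gof > noisy.gof

    def test_ngof_orders_species_standins_by_regularity_and_length(self):
        """Short noisy bout >> medium call >> very long regular train.

        The length normalization makes the long sperm-whale-like trains score
        orders of magnitude lower than the short bat-like bouts (synthetic
        stand-ins for the published datasets).
        """
        import warnings

        medians = {}
        for sp in ["C_perspicillata", "S_bilineata", "P_macrocephalus"]:
            ds = species_standin(sp, seed=99)
            vals = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for seq in ds.ioi_sequences():
                    onsets = np.concatenate([[0.0], np.cumsum(seq.iois)])
                    spec = fft_best_beat(binarize_onsets(onsets, 0.005))
                    vals.append(spec.ngof)
            medians[sp] = np.median(vals)
        assert medians["C_perspicillata"] > 5 * medians["S_bilineata"]
        assert medians["S_bilineata"] > 5 * medians["P_macrocephalus"]
        assert medians["C_perspicillata"] > 100 * medians["P_macrocephalus"]


class TestFrequencyResolution:
    def test_one_second_signal(self):
        b = BinarySequence(values=_raster(200), dt=0.005)
        assert frequency_resolution(b) == pytest.approx(1.0)

    def test_odd_length(self):
        b = BinarySequence(values=_raster(401), dt=0.005)
        assert frequency_resolution(b) == pytest.approx(200 / 401)

    def test_short_signal_warns(self):
        b = BinarySequence(values=_raster(100), dt=0.005)
        with pytest.warns(UserWarning, match="under 1 s"):
            assert frequency_resolution(b) == pytest.approx(2.0)


def _raster(n):
    x = np.zeros(n)
    x[0] = x[-1] = 1
    return x
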