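"""Preprocessing and windowing of multi-channel sEMG records."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdemg.exceptions import (
    DegenerateChannelError,
    InvalidBandError,
    TooShortError,
)
from kdemg.signal_io import (
    SignalRecord,
    WindowSpec,
    bandpass_filter,
    load_record,
    load_ninapro_mat,
    middle_third,
    remove_outliers_3sigma,
    save_record,
    segment_windows,
    standardize_channels,
    standardize_dataset,
)


def _record(samples, fs=2000.0, **kw):
    return SignalRecord(samples=np.atleast_2d(samples), fs=fs, **kw)


def _steady_amplitude(x, fs):
    """Peak amplitude ignoring the first/last 10% (filter transients)."""
    n = len(x)
    return np.max(np.abs(x[n // 10 : -n // 10]))


class TestBandpass:
    def test_dc_is_rejected(self):
        rec = _record(np.full(4000, 5.0))
        out = bandpass_filter(rec, 20.0, 500.0, 4)
        assert _steady_amplitude(out.channel(0), 2000) < 1e-6

    def test_passband_tone_preserved(self):
        t = np.arange(4000) / 2000.0
        rec = _record(np.sin(2 * np.pi * 100.0 * t))
        out = bandpass_filter(rec, 20.0, 500.0, 4)
        assert 0.95 <= _steady_amplitude(out.channel(0), 2000) <= 1.05

    def test_stopband_tone_suppressed(self):
        t = np.arange(4000) / 2000.0
        rec = _record(np.sin(2 * np.pi * 5.0 * t))
        out = bandpass_filter(rec, 20.0, 500.0, 4)
        # 4th-order high-pass edge at 20 Hz: |H(5 Hz)| = 1/sqrt(1+(20/5)^8) ~ 0.004
        assert _steady_amplitude(out.channel(0), 2000) < 0.05

    def test_linearity(self, rng):
        x = rng.standard_normal(4000)
        a = 3.7
        out1 = bandpass_filter(_record(x), 20.0, 500.0, 4).channel(0)
        out2 = bandpass_filter(_record(a * x), 20.0, 500.0, 4).channel(0)
        assert np.allclose(a * out1, out2, atol=1e-10)

    @pytest.mark.parametrize("band", [(0.0, 500.0), (20.0, 1000.0), (500.0, 20.0)])
    def test_invalid_band_rejected(self, band):
        rec = _record(np.zeros(4000))
        with pytest.raises((InvalidBandError, ValueError)):
            bandpass_filter(rec, band[0], band[1], 4)

    def test_too_short_signal_rejected(self):
        rec = _record(np.zeros(10))
        with pytest.raises(TooShortError):
            bandpass_filter(rec, 20.0, 500.0, 4)


class TestStandardize:
    def test_three_point_channel(self):
        out = standardize_channels(_record([1.0, 2.0, 3.0]))
        assert np.allclose(out.channel(0), [-1.0, 0.0, 1.0])

    def test_zero_mean_unit_sd(self, rng):
        rec = _record(rng.standard_normal((3, 500)) * 7 + 2)
        out = standardize_channels(rec)
        assert np.all(np.abs(out.samples.mean(axis=1)) < 1e-12)
        assert np.allclose(out.samples.std(axis=1, ddof=1), 1.0)

    def test_idempotent(self, rng):
        rec = _record(rng.standard_normal((2, 300)))
        once = standardize_channels(rec)
        twice = standardize_channels(once)
        assert np.allclose(once.samples, twice.samples, atol=1e-10)

    def test_constant_channel_raises(self):
        with pytest.raises(DegenerateChannelError):
            standardize_channels(_record(np.ones(100)))

    def test_pooled_standardization_preserves_relative_amplitude(self, rng):
        quiet = _record(rng.standard_normal((1, 400)) * 0.5)
        loud = _record(rng.standard_normal((1, 400)) * 5.0)
        out = standardize_dataset([quiet, loud])
        assert out[1].samples.std() > 3 * out[0].samples.std()


class TestOutlierRemoval:
    def test_inliers_untouched(self):
        x = np.clip(np.random.default_rng(17).standard_normal(1000), -2.5, 2.5)
        rec = standardize_channels(_record(x))
        out = remove_outliers_3sigma(rec)
        assert len(out.channel(0)) == len(rec.channel(0))

    def test_gross_outlier_removed(self, rng):
        inliers = np.clip(rng.standard_normal(500), -2.5, 2.5)
        rec = _record(np.concatenate([inliers, [10.0]]))
        out = remove_outliers_3sigma(rec)
        assert len(out.channel(0)) == 500
        assert np.max(np.abs(out.channel(0))) < 10.0

    def test_gaussian_removal_fraction(self):
        x = np.random.default_rng(29).standard_normal(10_000)
        out = remove_outliers_3sigma(_record(x))
        frac = 1.0 - len(out.channel(0)) / 10_000
        assert abs(frac - 0.0027) < 0.002  # 2*Phi(-3)

    def test_result_is_ragged(self, rng):
        rec = _record(rng.standard_normal((2, 1000)))
        out = remove_outliers_3sigma(rec)
        assert out.ragged


class TestWindows:
    def test_window_count_formula(self):
        rec = _record(np.zeros(10_000), fs=2000.0)
        wins = segment_windows(rec, WindowSpec(width_ms=400, step_ms=300))
        assert len(wins) == 16  # floor((10000-800)/600)+1

    def test_single_window_when_width_equals_duration(self):
        rec = _record(np.zeros(800), fs=2000.0)
        wins = segment_windows(rec, WindowSpec(width_ms=400, step_ms=400))
        assert len(wins) == 1

    def test_too_short_record(self):
        rec = _record(np.zeros(100), fs=2000.0)
        with pytest.raises(TooShortError):
            segment_windows(rec, WindowSpec(width_ms=400, step_ms=300))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        n=st.integers(min_value=100, max_value=5000),
        width=st.integers(min_value=50, max_value=100),
        step=st.integers(min_value=10, max_value=50),
    )
    def test_count_formula_property(self, n, width, step):
        fs = 1000.0
        rec = _record(np.zeros(max(n, width)), fs=fs)
        wins = segment_windows(rec, WindowSpec(width_ms=width, step_ms=step))
        expected = (max(n, width) - width) // step + 1
        assert len(wins) == expected
        assert all(w.n_samples == width for w in wins)


class TestMiddleThird:
    @pytest.mark.parametrize(
        "n, expected_idx",
        [(9, [3, 4, 5]), (10, [3, 4, 5]), (3, [1])],
    )
    def test_boundary_convention(self, n, expected_idx):
        rec = _record(np.arange(n, dtype=float))
        out = middle_third(rec)
        assert out.channel(0).tolist() == [float(i) for i in expected_idx]

    @pytest.mark.parametrize("n", [3, 4, 5, 10, 100, 101, 1001])
    def test_length_invariant(self, n):
        out = middle_third(_record(np.zeros(n)))
        assert out.n_samples in (n // 3, n // 3 + 1)

    def test_too_short(self):
        with pytest.raises(TooShortError):
            middle_third(_record(np.zeros(2)))


class TestDiskIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        rec = SignalRecord(rng.standard_normal((3, 50)), fs=2000.0,
                           label=4, repetition=2, subject="s9")
        save_record(rec, tmp_path / "rec")
        back = load_record(tmp_path / "rec")
        assert np.allclose(back.samples, rec.samples)
        assert (back.fs, back.label, back.repetition, back.subject) == (2000.0, 4, 2, "s9")

    def test_mat_adapter_splits_contractions(self, tmp_path, rng):
        from scipy.io import savemat

        emg = rng.standard_normal((300, 4))
        stim = np.r_[np.zeros(50), np.full(100, 3), np.zeros(50), np.full(100, 7)]
        rep = np.r_[np.zeros(50), np.full(100, 1), np.zeros(50), np.full(100, 2)]
        savemat(tmp_path / "x.mat", {"emg": emg, "stimulus": stim,
                                     "repetition": rep, "frequency": 2000.0})
        recs = load_ninapro_mat(tmp_path / "x.mat")
        assert [r.label for r in recs] == [3, 7]
        assert [r.repetition for r in recs] == [1, 2]
        assert recs[0].n_samples == 100 and recs[0].n_channels == 4
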