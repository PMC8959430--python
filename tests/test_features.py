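"""Window features: trimmed mean, ApEn, density features, classic and DWT."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from kdemg.exceptions import EmptyInputError, TooShortError
from kdemg.features import (
    ApEnParams,
    TrimSpec,
    approximate_entropy,
    classic_time_features,
    dwt_energies,
    extract_feature_table,
    kde_features,
    trimmed_mean,
)
from kdemg.density import kde_diffusion
from kdemg.signal_io import SignalRecord, WindowSpec


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def trimmed_mean_oracle(values, lower_pct, upper_pct):
    """Sort, drop floor(pct*n) per side, average the rest."""
    xs = sorted(values)
    n = len(xs)
    lo = int(np.floor(lower_pct / 100.0 * n))
    hi = int(np.floor(upper_pct / 100.0 * n))
    kept = xs[lo : n - hi]
    return sum(kept) / len(kept)


def apen_oracle(x, m, r):
    """Definitional ApEn with the explicit double loop (self-matches included)."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(mm):
        emb = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in emb:
            c = sum(1 for b in emb if np.max(np.abs(a - b)) <= r)
            total += np.log(c / len(emb))
        return total / len(emb)

    return phi(m) - phi(m + 1)


def dwt_energy_oracle(x, wavelet="sym4", levels=3):
    """Filter-bank oracle: circular convolution + dyadic downsampling with the
    half-filter-length phase convention of periodized transforms."""
    w = pywt.Wavelet(wavelet)
    lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)
    off = len(lo) // 2
    a = np.asarray(x, dtype=float)
    energies = []
    for _ in range(levels):
        n = len(a)
        conv_hi = np.array(
            [sum(hi[k] * a[(2 * i + off - k) % n] for k in range(len(hi)))
             for i in range(n // 2)]
        )
        conv_lo = np.array(
            [sum(lo[k] * a[(2 * i + off - k) % n] for k in range(len(lo)))
             for i in range(n // 2)]
        )
        energies.append(np.sum(conv_hi**2))
        a = conv_lo
    energies.append(np.sum(a**2))
    return np.array(energies)  # [D1, D2, D3, A3]


# ---------------------------------------------------------------------------
# trimmed mean
# ---------------------------------------------------------------------------

class TestTrimmedMean:
    def test_constant_vector(self):
        assert trimmed_mean(np.full(37, 4.2)) == pytest.approx(4.2)

    def test_drops_extremes_of_1_to_20(self):
        assert trimmed_mean(np.arange(1, 21), TrimSpec(5, 5)) == 10.5

    def test_robust_to_gross_outlier(self):
        vals = np.r_[np.arange(1, 20), 1000.0]
        assert trimmed_mean(vals, TrimSpec(5, 5)) == 10.5

    def test_zero_trim_equals_mean(self, rng):
        x = rng.standard_normal(101)
        assert trimmed_mean(x, TrimSpec(0, 0)) == pytest.approx(x.mean(), abs=1e-14)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            trimmed_mean(np.array([]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        data=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        lo=st.floats(0, 49.9),
        hi=st.floats(0, 49.9),
    )
    def test_matches_sort_and_drop_oracle(self, data, lo, hi):
        expected = trimmed_mean_oracle(data, lo, hi)
        got = trimmed_mean(np.array(data), TrimSpec(lo, hi))
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# approximate entropy
# ---------------------------------------------------------------------------

class TestApproximateEntropy:
    def test_constant_sequence_is_zero(self):
        assert approximate_entropy(np.full(50, 3.0), ApEnParams(2, 0.2)) == 0.0

    def test_equals_definitional_oracle(self, rng):
        for _ in range(5):
            x = rng.random(100)
            r = 0.2 * x.std()
            got = approximate_entropy(x, ApEnParams(2, 0.2))
            assert got == pytest.approx(apen_oracle(x, 2, r), abs=1e-12)

    def test_regular_series_less_complex_than_shuffled(self, rng):
        regular = np.tile([0.0, 1.0], 50)
        shuffled = rng.permutation(regular)
        p = ApEnParams(2, 0.2)
        assert approximate_entropy(regular, p) < approximate_entropy(shuffled, p)

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            approximate_entropy(np.array([1.0, 2.0]), ApEnParams(2, 0.2))


# ---------------------------------------------------------------------------
# density features
# ---------------------------------------------------------------------------

class TestKdeFeatures:
    def test_permutation_invariance(self, rng):
        x = rng.standard_normal(400)
        assert kde_features(x, n_grid=512) == kde_features(rng.permutation(x), n_grid=512)

    def test_tmd_is_trimmed_mean_of_density_values(self, rng):
        x = rng.standard_normal(400)
        tmd, _, tmavdd = kde_features(x, n_grid=512)
        est = kde_diffusion(x, n_grid=512)
        assert tmd == trimmed_mean(est.values, TrimSpec(5, 5))
        assert tmavdd >= 0.0

    def test_deterministic_across_runs(self, rng):
        x = rng.standard_normal(300)
        assert kde_features(x.copy(), n_grid=512) == kde_features(x.copy(), n_grid=512)


class TestClassicFeatures:
    def test_rms_of_constant(self):
        rms, _, _ = classic_time_features(np.full(10, -3.0))
        assert rms == pytest.approx(3.0)

    def test_waveform_length(self):
        _, wl, _ = classic_time_features(np.array([0.0, 1.0, 0.0, 1.0]))
        assert wl == 3.0

    def test_mean_absolute_value(self):
        _, _, mav = classic_time_features(np.array([-1.0, 1.0, -1.0]))
        assert mav == 1.0


class TestDwtEnergies:
    def test_zero_signal(self):
        assert np.all(dwt_energies(np.zeros(64)) == 0.0)

    def test_energy_conservation(self, rng):
        x = rng.standard_normal(256)
        energies = dwt_energies(x)
        assert np.sum(energies) == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_impulse_matches_filter_bank_oracle(self):
        x = np.zeros(64)
        x[10] = 1.0
        assert np.allclose(dwt_energies(x), dwt_energy_oracle(x), atol=1e-10)

    def test_random_signal_matches_filter_bank_oracle(self, rng):
        x = rng.standard_normal(64)
        assert np.allclose(dwt_energies(x), dwt_energy_oracle(x), atol=1e-10)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

class TestFeatureTable:
    def _records(self, rng, n_channels, n_records=2, n=400):
        return [
            SignalRecord(rng.standard_normal((n_channels, n)), fs=1000.0,
                         label=i % 2 + 1, repetition=i + 1)
            for i in range(n_records)
        ]

    def test_twelve_channels_give_36_kde_columns(self, rng):
        table = extract_feature_table(
            self._records(rng, 12), feature_set="kde",
            window=WindowSpec(mode="whole"), n_grid=256,
        )
        assert len(table.feature_names) == 36
        assert table.feature_names[:3] == ["ch01_TMD", "ch01_ED", "ch01_TMAVDD"]

    def test_row_count_equals_window_count(self, rng):
        records = self._records(rng, 2, n_records=3, n=1000)
        table = extract_feature_table(
            records, feature_set="classic",
            window=WindowSpec(width_ms=200, step_ms=100, mode="sliding"),
        )
        # each 1000-sample record at 1 kHz: floor((1000-200)/100)+1 = 9 windows
        assert len(table.data) == 3 * 9

    def test_degenerate_channel_drops_row(self, rng):
        good = SignalRecord(rng.standard_normal((2, 400)), fs=1000.0, label=1)
        bad = SignalRecord(np.vstack([np.ones(400), rng.standard_normal(400)]),
                           fs=1000.0, label=2)
        table = extract_feature_table([good, bad], feature_set="kde",
                                      window=WindowSpec(mode="whole"), n_grid=256)
        assert len(table.data) == 1
        assert table.y.tolist() == [1]

    def test_separability_of_well_separated_classes(self, rng):
        # amplitude ratio >= 3 between classes -> per-channel TMD separates them
        recs = []
        for rep in range(1, 5):
            recs.append(SignalRecord(rng.standard_normal((1, 600)) * 1.0,
                                     fs=1000.0, label=1, repetition=rep))
            recs.append(SignalRecord(rng.standard_normal((1, 600)) * 3.0,
                                     fs=1000.0, label=2, repetition=rep))
        table = extract_feature_table(recs, feature_set="tmd",
                                      window=WindowSpec(mode="whole"), n_grid=256)
        tmd = table.X[:, 0]
        a, b = tmd[table.y == 1], tmd[table.y == 2]
        spread = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) / spread > 1.0
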