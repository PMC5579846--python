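"""Feature extraction, per-subject normalization, and PCA."""

import numpy as np
import pandas as pd
import pytest

from oitkit import (
    FeatureSpec,
    autocorr_lag_set,
    autocorrelation,
    build_feature_table,
    channel_feature_count,
    dft_peaks,
    extract_features,
    feature_columns,
    normalize_per_subject,
    pca_reduce,
    scree,
)


class TestAutocorrelation:
    def test_lag_zero_is_population_variance(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert autocorrelation(x, [0])[0] == pytest.approx(1.0)

    def test_constant_sequence_gives_zeros(self):
        out = autocorrelation(np.full(50, 3.3), [0, 5, 10])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        lags = list(range(5, 55, 5))
        a = autocorrelation(x, [0] + lags)
        assert np.all(np.abs(a[1:]) / a[0] < 0.05)

    def test_lag_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            autocorrelation(np.ones(10), [10])

    def test_lag_set_truncates_with_short_windows(self):
        assert autocorr_lag_set(125) == [0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50]
        assert autocorr_lag_set(40) == [0, 5, 10, 15, 20, 25, 30, 35]
        assert autocorr_lag_set(6) == [0, 5]
        assert autocorr_lag_set(5) == [0]


class TestDftPeaks:
    def test_pure_cosine_peak_bin_and_frequency(self):
        n = np.arange(128)
        x = np.cos(2 * np.pi * 10 * n / 128)
        mags, freqs = dft_peaks(x, n_peaks=5, min_separation=11, rate=50.0)
        assert freqs[0] == pytest.approx(10 * 50.0 / 128)  # ~3.906 Hz
        assert mags[0] == pytest.approx(64.0, rel=1e-6)

    def test_constant_sequence_peaks_at_dc_only(self):
        mags, freqs = dft_peaks(np.full(64, 2.0), rate=1.0)
        assert freqs[0] == 0.0
        assert mags[0] == pytest.approx(128.0)
        np.testing.assert_allclose(mags[1:], 0.0, atol=1e-9)
        np.testing.assert_array_equal(freqs[1:], 0.0)

    def test_short_window_zero_fills_missing_peaks(self, rng):
        # 21 one-sided bins with pairwise distance >= 11 admit at most 2 peaks
        x = rng.normal(size=40)
        mags, freqs = dft_peaks(x, n_peaks=5, min_separation=11, rate=8.0)
        assert mags.shape == (5,) and freqs.shape == (5,)
        assert np.count_nonzero(mags) <= 2
        assert np.all(mags[2:] == 0.0)

    def test_selected_peaks_respect_separation(self, rng):
        x = rng.normal(size=500)
        _, freqs = dft_peaks(x, n_peaks=5, min_separation=11, rate=500.0)
        chosen = np.round(freqs).astype(int)  # rate/L = 1, so bin = freq
        diffs = np.abs(chosen[:, None] - chosen[None, :])
        np.fill_diagonal(diffs, 99)
        assert np.all(diffs >= 11)


class TestExtractFeatures:
    def test_per_channel_counts(self):
        assert channel_feature_count(125) == 26
        assert channel_feature_count(40) == 23
        assert channel_feature_count(128) == 26
        assert channel_feature_count(500) == 26
        assert channel_feature_count(260) == 26

    @pytest.mark.parametrize(
        "n_channels,L,total",
        [(45, 125, 1170), (12, 40, 276), (9, 128, 234), (6, 500, 156), (3, 260, 78)],
    )
    def test_dataset_totals_from_configuration(self, rng, n_channels, L, total):
        channels = {f"c{i}": rng.normal(size=L) for i in range(n_channels)}
        vec = extract_features(channels, FeatureSpec(), rate=25.0)
        assert len(vec) == total

    def test_constant_channel_degenerate_conventions(self):
        vec = extract_features({"c": np.full(125, 4.0)}, rate=25.0)
        assert vec["c:min"] == vec["c:max"] == vec["c:mean"] == 4.0
        assert vec["c:skewness"] == 0.0 and vec["c:kurtosis"] == 0.0
        assert vec["c:ac0"] == 0.0
        assert vec["c:dftmag1"] > 0 and vec["c:dftfreq1"] == 0.0
        # remaining slots carry at most round-off energy
        assert np.all(vec[[f"c:dftmag{i}" for i in range(2, 6)]] < 1e-9)

    def test_variance_feature_is_autocorrelation_at_lag_zero(self, rng):
        x = rng.normal(size=100)
        vec = extract_features({"c": x}, rate=1.0)
        assert vec["c:ac0"] == autocorrelation(x, [0])[0]

    def test_unequal_channel_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="unequal"):
            extract_features(
                {"a": rng.normal(size=10), "b": rng.normal(size=12)}, rate=1.0
            )

    def test_nonfinite_channel_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            extract_features({"a": np.array([1.0, np.nan, 2.0])}, rate=1.0)


class TestNormalizePerSubject:
    def _table(self, subjects, values):
        return pd.DataFrame(
            {
                "subject": subjects,
                "activity": ["a1"] * len(subjects),
                "segment_index": range(len(subjects)),
                "f": values,
            }
        )

    def test_min_max_scaling(self):
        out = normalize_per_subject(self._table(["s1"] * 3, [2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out["f"], [0.0, 0.5, 1.0])

    def test_subjects_scaled_independently(self):
        out = normalize_per_subject(
            self._table(["s1", "s1", "s2", "s2"], [0.0, 10.0, 100.0, 200.0])
        )
        np.testing.assert_allclose(out["f"], [0.0, 1.0, 0.0, 1.0])

    def test_constant_within_subject_maps_to_zero(self):
        out = normalize_per_subject(self._table(["s1"] * 3, [5.0, 5.0, 5.0]))
        np.testing.assert_allclose(out["f"], 0.0)

    def test_output_in_unit_interval_and_idempotent(self, rng):
        tbl = pd.DataFrame(
            {
                "subject": rng.choice(["s1", "s2", "s3"], size=60),
                "activity": ["a"] * 60,
                "segment_index": range(60),
                "f1": rng.normal(size=60),
                "f2": rng.uniform(-5, 5, size=60),
            }
        )
        once = normalize_per_subject(tbl)
        cols = ["f1", "f2"]
        assert once[cols].to_numpy().min() >= 0.0
        assert once[cols].to_numpy().max() <= 1.0
        twice = normalize_per_subject(once)
        np.testing.assert_allclose(
            twice[cols].to_numpy(), once[cols].to_numpy(), atol=1e-12
        )


class TestPca:
    def _table(self, x, subjects=None):
        n = x.shape[0]
        d = {
            "subject": subjects if subjects is not None else ["s1"] * n,
            "activity": ["a"] * n,
            "segment_index": range(n),
        }
        for j in range(x.shape[1]):
            d[f"f{j}"] = x[:, j]
        return pd.DataFrame(d)

    def test_full_rank_projection_preserves_distances(self, rng):
        x = rng.normal(size=(50, 5))
        tbl = self._table(x)
        tr, te, _ = pca_reduce(tbl.iloc[:40], tbl.iloc[40:], M=5)
        cols = feature_columns(tr)
        d_orig = np.linalg.norm(x[:40, None] - x[None, :40], axis=2)
        proj = tr[cols].to_numpy()
        d_proj = np.linalg.norm(proj[:, None] - proj[None, :], axis=2)
        np.testing.assert_allclose(d_proj, d_orig, atol=1e-8)

    def test_eigenvalues_non_increasing(self, rng):
        x = rng.normal(size=(80, 10)) * np.linspace(5, 0.1, 10)
        tbl = self._table(x)
        _, _, ev = pca_reduce(tbl, tbl, M=10)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_dominant_direction_retains_variance(self, rng):
        n = 200
        t = rng.normal(size=n)
        x = np.column_stack([t, t]) + rng.normal(scale=0.01, size=(n, 2))
        tbl = self._table(x)
        tr, _, ev = pca_reduce(tbl, tbl, M=1)
        assert ev[0] >= 0.99 * x.var(axis=0, ddof=1).sum()

    def test_m_exceeding_feature_count_rejected(self, rng):
        tbl = self._table(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            pca_reduce(tbl, tbl, M=4)

    def test_train_only_fit_ignores_test_rows(self, rng):
        x = rng.normal(size=(60, 4))
        tbl = self._table(x)
        tr1, _, ev1 = pca_reduce(tbl.iloc[:30], tbl.iloc[30:], M=2, fit_mode="train_only")
        tr2, _, ev2 = pca_reduce(tbl.iloc[:30], tbl.iloc[:10], M=2, fit_mode="train_only")
        np.testing.assert_allclose(ev1, ev2)
        np.testing.assert_allclose(
            tr1[feature_columns(tr1)].to_numpy(),
            tr2[feature_columns(tr2)].to_numpy(),
        )


class TestScree:
    def test_sum_of_eigenvalues_equals_total_variance(self, rng):
        x = rng.normal(size=(100, 8))
        d = {"subject": ["s"] * 100, "activity": ["a"] * 100, "segment_index": range(100)}
        for j in range(8):
            d[f"f{j}"] = x[:, j]
        tbl = pd.DataFrame(d)
        ev = scree(tbl)
        assert ev.sum() == pytest.approx(x.var(axis=0, ddof=1).sum(), rel=1e-8)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_white_data_has_flat_spectrum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20_000, 5))
        d = {"subject": ["s"] * x.shape[0], "activity": ["a"] * x.shape[0],
             "segment_index": range(x.shape[0])}
        for j in range(5):
            d[f"f{j}"] = x[:, j]
        ev = scree(pd.DataFrame(d), 5)
        assert ev[0] / ev[-1] < 1.1
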