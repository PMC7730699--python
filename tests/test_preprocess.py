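"""Signal pretreatment: Savitzky-Golay, MSC, truncation, autoscaling,
drift correction and Fisher-ratio sensor selection."""

import numpy as np
import pandas as pd
import pytest

from pollensense.preprocess import (
    autoscale_fit_apply,
    discrimination_power,
    drift_correct_etongue,
    msc_correct,
    savgol_smooth,
    select_sensors_by_discrimination,
    truncate_range,
)

from conftest import make_sensor_block, make_spectral_block


class TestSavgol:
    def test_quadratic_is_invariant(self):
        """An order-2 polynomial passes through an order-2 SG filter
        unchanged, including at the truncated-window edges."""
        wl = 900.0 + 3.0 * np.arange(120)
        x = (wl - 1200.0) / 100.0
        spectrum = 3.0 + 2.0 * x + 0.5 * x**2
        block = make_spectral_block(spectrum[None, :], wl)
        out = savgol_smooth(block, window=21, polyorder=2)
        assert np.allclose(out.X[0], spectrum, atol=1e-9)

    def test_constant_spectrum_unchanged(self):
        block = make_spectral_block(np.full((3, 60), 1.7))
        out = savgol_smooth(block)
        assert np.allclose(out.X, 1.7, atol=1e-12)

    def test_interior_matches_per_window_quadratic_fit(self, rng):
        """Oracle: each interior point equals the centre value of the
        least-squares quadratic fitted to its 21-point window."""
        X = rng.normal(size=(4, 80))
        block = make_spectral_block(X)
        out = savgol_smooth(block, window=21, polyorder=2)
        t = np.arange(-10, 11)
        V = np.vander(t, 3, increasing=True)
        H = np.linalg.pinv(V)  # row 0 evaluates the fit at t = 0
        for i in [10, 30, 69]:
            expected = X[:, i - 10 : i + 11] @ H[0]
            assert np.allclose(out.X[:, i], expected, atol=1e-10)

    def test_linearity(self, rng):
        a, b = 2.5, -1.25
        X = rng.normal(size=(2, 60))
        Y = rng.normal(size=(2, 60))
        s = lambda M: savgol_smooth(make_spectral_block(M)).X
        assert np.allclose(s(a * X + b * Y), a * s(X) + b * s(Y), atol=1e-9)

    @pytest.mark.parametrize("window,polyorder", [(20, 2), (3, 5), (999, 2)])
    def test_invalid_window_rejected(self, window, polyorder):
        block = make_spectral_block(np.zeros((1, 50)))
        with pytest.raises(ValueError):
            savgol_smooth(block, window=window, polyorder=polyorder)


class TestMSC:
    def test_reference_spectrum_is_fixed_point(self, rng):
        ref = rng.normal(size=40).cumsum()
        block = make_spectral_block(ref[None, :])
        out, used = msc_correct(block, ref)
        assert np.allclose(out.X[0], ref, atol=1e-9)
        assert np.allclose(used, ref)

    def test_inverts_affine_scatter_exactly(self, rng):
        ref = np.abs(rng.normal(size=50)).cumsum()
        distorted = 2.0 * ref + 3.0
        block = make_spectral_block(np.vstack([ref, distorted]))
        out, _ = msc_correct(block, ref)
        assert np.allclose(out.X[1], ref, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        ref = rng.normal(size=30).cumsum()
        X = rng.normal(size=(5, 30)) + ref
        block = make_spectral_block(X)
        out, _ = msc_correct(block, ref)
        for i in range(5):
            a, b = np.polyfit(ref, X[i], 1)
            assert np.allclose(out.X[i], (X[i] - b) / a, atol=1e-9)

    def test_idempotent_with_fixed_reference(self, rng):
        ref = rng.normal(size=30).cumsum()
        X = rng.uniform(0.8, 1.2, size=(4, 1)) * ref + rng.normal(size=(4, 1))
        once, _ = msc_correct(make_spectral_block(X), ref)
        twice, _ = msc_correct(once, ref)
        assert np.allclose(once.X, twice.X, atol=1e-9)

    def test_constant_reference_rejected(self):
        block = make_spectral_block(np.random.default_rng(0).normal(size=(2, 20)))
        with pytest.raises(ValueError, match="constant reference"):
            msc_correct(block, np.ones(20))


class TestTruncate:
    def test_closed_interval_retained(self):
        block = make_spectral_block(
            np.zeros((2, 267)), 900.0 + 3.0 * np.arange(267)
        )
        out = truncate_range(block, 950, 1650)
        assert out.wavelengths.min() >= 950
        assert out.wavelengths.max() <= 1650
        # closed interval: a grid point exactly at the bound is kept
        assert 1650.0 in out.wavelengths

    def test_single_point_range(self):
        block = make_spectral_block(np.zeros((1, 50)))
        wl = block.wavelengths[10]
        out = truncate_range(block, wl, wl)
        assert out.X.shape[1] == 1

    def test_disjoint_range_rejected(self):
        block = make_spectral_block(np.zeros((1, 50)))
        with pytest.raises(ValueError, match="no wavelengths"):
            truncate_range(block, 100, 200)


class TestAutoscale:
    def test_train_columns_standardised_and_heldout_uses_train_state(self, rng):
        train = rng.normal(3.0, 2.0, size=(30, 6))
        held = rng.normal(3.0, 2.0, size=(8, 6))
        strain, sheld, state = autoscale_fit_apply(train, held)
        assert np.allclose(strain.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(strain.std(axis=0, ddof=1), 1.0, atol=1e-12)
        mu = train.mean(axis=0)
        sd = train.std(axis=0, ddof=1)
        assert np.allclose(sheld, (held - mu) / sd, atol=1e-12)

    def test_apply_to_train_is_identity_of_scaled_train(self, rng):
        train = rng.normal(size=(10, 3))
        strain, sapply, _ = autoscale_fit_apply(train, train)
        assert np.allclose(strain, sapply)

    def test_constant_column_named_in_error(self, rng):
        train = rng.normal(size=(10, 3))
        train[:, 1] = 5.0
        with pytest.raises(ValueError, match="b"):
            autoscale_fit_apply(train, column_names=["a", "b", "c"])


class TestDriftCorrection:
    def _block(self, clean, offsets):
        n_per = clean.shape[0]
        X = np.vstack([clean + off for off in offsets])
        sessions = np.repeat(np.arange(1, len(offsets) + 1), n_per)
        return make_sensor_block(X, sessions=sessions)

    def test_exactly_removes_additive_session_offsets(self, rng):
        clean = rng.normal(size=(10, 5))
        offsets = rng.normal(size=(4, 5))
        offsets -= offsets.mean(axis=0)  # identifiable part of the drift
        block = self._block(clean, offsets)
        out = drift_correct_etongue(block)
        assert np.allclose(out.X, np.vstack([clean] * 4), atol=1e-9)

    def test_zero_drift_is_identity(self, rng):
        clean = rng.normal(size=(6, 4))
        block = self._block(clean, np.zeros((3, 4)))
        out = drift_correct_etongue(block)
        assert np.allclose(out.X, block.X, atol=1e-9)

    def test_session_means_equal_grand_mean_after_correction(self, rng):
        X = rng.normal(size=(40, 6))
        sessions = rng.integers(1, 5, size=40)
        block = make_sensor_block(X, sessions=sessions)
        out = drift_correct_etongue(block)
        grand = out.X.mean(axis=0)
        for s in np.unique(sessions):
            assert np.allclose(out.X[sessions == s].mean(axis=0), grand, atol=1e-9)

    def test_within_session_contrasts_preserved(self, rng):
        X = rng.normal(size=(12, 3))
        sessions = np.repeat([1, 2, 3], 4)
        out = drift_correct_etongue(make_sensor_block(X, sessions=sessions))
        for s in [1, 2, 3]:
            idx = np.flatnonzero(sessions == s)
            orig = X[idx] - X[idx[0]]
            corr = out.X[idx] - out.X[idx[0]]
            assert np.allclose(orig, corr, atol=1e-12)

    def test_single_session_warns_and_returns_unchanged(self, rng):
        block = make_sensor_block(rng.normal(size=(5, 3)))
        with pytest.warns(UserWarning, match="single-session"):
            out = drift_correct_etongue(block)
        assert np.allclose(out.X, block.X)


class TestSensorSelection:
    def test_constant_sensor_scores_zero(self, rng):
        X = rng.normal(size=(12, 3))
        X[:, 1] = 7.0
        classes = np.repeat(["a", "b", "c"], 4)
        block = make_sensor_block(X, classes=classes)
        scores = discrimination_power(block)
        assert scores.iloc[1] == 0.0
        selected = select_sensors_by_discrimination(block, k=2)
        assert "S01" not in selected.sensor_ids

    def test_perfect_separator_ranks_first(self):
        X = np.column_stack(
            [np.array([0, 0, 0, 1, 1, 1]), [0.1, 0.9, 0.5, 0.4, 0.2, 0.8]]
        )
        block = make_sensor_block(X, classes=["a"] * 3 + ["b"] * 3)
        scores = discrimination_power(block)
        assert np.isinf(scores.iloc[0])
        selected = select_sensors_by_discrimination(block, k=1)
        assert selected.sensor_ids == ["S00"]

    def test_ranking_matches_anova_ss_oracle(self, rng):
        X = rng.normal(size=(30, 8))
        classes = np.repeat([f"c{i}" for i in range(5)], 6)
        X[:, 0] += np.repeat(np.arange(5.0), 6)  # make one sensor informative
        block = make_sensor_block(X, classes=classes)
        scores = discrimination_power(block)
        # oracle: SSB/SSW from one-way ANOVA identities per sensor
        for j in range(8):
            groups = [X[classes == c, j] for c in np.unique(classes)]
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            grand = X[:, j].mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            assert scores.iloc[j] == pytest.approx(ssb / ssw, rel=1e-10)
        order = scores.sort_values(ascending=False)
        assert order.index[0] == "S00"

    def test_ranking_invariant_to_affine_rescaling(self, rng):
        X = rng.normal(size=(20, 5))
        classes = np.repeat(["a", "b", "c", "d"], 5)
        block = make_sensor_block(X, classes=classes)
        before = discrimination_power(block).rank(ascending=False)
        X2 = X.copy()
        X2[:, 2] = 100.0 * X2[:, 2] - 7.0
        after = discrimination_power(
            make_sensor_block(X2, classes=classes)
        ).rank(ascending=False)
        pd.testing.assert_series_equal(before, after)

    def test_k_larger_than_sensor_count_rejected(self, rng):
        block = make_sensor_block(
            rng.normal(size=(10, 3)), classes=["a"] * 5 + ["b"] * 5
        )
        with pytest.raises(ValueError, match="exceeds"):
            select_sensors_by_discrimination(block, k=4)
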