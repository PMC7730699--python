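"""Block alignment, prediction-based outlier screening and the two-round
PLSR workflow."""

import numpy as np
import pandas as pd
import pytest

from pollensense.blocks import SensorBlock, SpectralBlock
from pollensense.fusion import (
    align_blocks,
    detect_prediction_outliers,
    two_round_plsr,
)


def _mini_blocks(rng, n_scans=5, n_sessions=4, n_classes=3, n_reps=2):
    """Small consistent NIR / e-tongue / e-nose trio."""
    classes = [f"c{i}" for i in range(n_classes)]
    units = [(c, r) for c in classes for r in range(1, n_reps + 1)]
    wl = 900.0 + 3.0 * np.arange(12)
    nir_rows, nir_meta = [], []
    for c, r in units:
        for s in range(1, n_scans + 1):
            nir_rows.append(rng.normal(size=12))
            nir_meta.append((c, c, r, s))
    nir = SpectralBlock(
        wl,
        np.vstack(nir_rows),
        pd.DataFrame(nir_meta, columns=["sample_id", "class_label", "replicate_id", "scan_index"]),
    )
    et_rows, et_meta = [], []
    for s in range(1, n_sessions + 1):
        for c, r in units:
            et_rows.append(rng.normal(size=4))
            et_meta.append((c, c, r, s))
    et = SensorBlock(
        ["ZZ", "JE", "JB", "HA"],
        np.vstack(et_rows),
        pd.DataFrame(et_meta, columns=["sample_id", "class_label", "replicate_id", "session_id"]),
    )
    en_rows, en_meta = [], []
    for c, r in units:
        en_rows.append(rng.normal(size=6))
        en_meta.append((c, c, r, 1))
    en = SensorBlock(
        [f"{500 + 10 * j:.2f}-1A" for j in range(6)],
        np.vstack(en_rows),
        pd.DataFrame(en_meta, columns=["sample_id", "class_label", "replicate_id", "session_id"]),
    )
    return nir, et, en


class TestAlignBlocks:
    def test_row_and_column_bookkeeping(self, rng):
        nir, et, en = _mini_blocks(rng)
        fused = align_blocks(nir, et, en)
        assert fused.n_obs == nir.n_obs == 30
        assert fused.X.shape[1] == 12 + 4 + 6
        # each e-nose row repeated once per NIR scan of its unit
        raw_en = fused.block_view("enose", original_scale=True)
        for u in range(6):
            rows = raw_en[u * 5 : (u + 1) * 5]
            assert np.allclose(rows, rows[0], atol=1e-12)
            assert np.allclose(rows[0], en.X[u], atol=1e-12)

    def test_etongue_averaged_when_fewer_rows_than_scans(self, rng):
        """4 e-tongue sessions vs 5 NIR scans: each NIR row of a unit gets
        the unit's e-tongue average."""
        nir, et, en = _mini_blocks(rng)
        fused = align_blocks(nir, et, en)
        raw_et = fused.block_view("etongue", original_scale=True)
        key = list(zip(et.meta["sample_id"], et.meta["replicate_id"]))
        unit0 = (nir.meta.loc[0, "sample_id"], nir.meta.loc[0, "replicate_id"])
        expected = et.X[[i for i, k in enumerate(key) if k == unit0]].mean(axis=0)
        assert np.allclose(raw_et[0], expected, atol=1e-12)

    def test_equal_row_counts_is_plain_concatenation(self, rng):
        nir, et, en = _mini_blocks(rng, n_scans=1, n_sessions=1)
        fused = align_blocks(nir, et, en)
        assert fused.n_obs == 6
        assert np.allclose(
            fused.block_view("etongue", original_scale=True), et.X, atol=1e-12
        )

    def test_fused_matrix_is_autoscaled(self, rng):
        nir, et, en = _mini_blocks(rng)
        fused = align_blocks(nir, et, en)
        assert np.allclose(fused.X.mean(axis=0), 0.0, atol=1e-9)

    def test_block_content_recoverable(self, rng):
        """Undoing the fused autoscaling recovers each aligned block's rows
        exactly."""
        nir, et, en = _mini_blocks(rng)
        fused = align_blocks(nir, et, en)
        assert np.allclose(
            fused.block_view("nir", original_scale=True), nir.X, atol=1e-9
        )

    def test_missing_sample_rejected_with_name(self, rng):
        nir, et, en = _mini_blocks(rng)
        keep = en.meta["sample_id"] != "c1"
        en_missing = SensorBlock(
            en.sensor_ids, en.X[keep.to_numpy()], en.meta[keep]
        )
        with pytest.raises(ValueError, match="c1"):
            align_blocks(nir, et, en_missing)


class TestOutlierDetection:
    def test_constant_group_flags_nothing(self):
        pred = np.array([1.0, 1.0, 1.0, 5.0, 5.0, 5.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        rep = detect_prediction_outliers(pred, groups)
        assert rep.n_flagged == 0

    def test_single_gross_outlier_flagged_exactly(self):
        """A displacement of many IQRs in an otherwise tight group flags
        exactly that observation (direct quantile arithmetic)."""
        rng = np.random.default_rng(0)
        pred = np.concatenate([rng.uniform(9.9, 10.1, 9), [25.0]])
        groups = np.array(["g"] * 10)
        rep = detect_prediction_outliers(pred, groups)
        assert rep.flagged.tolist() == [9]
        lo, hi = rep.bounds["g"]
        q1, med, q3 = np.percentile(pred, [25, 50, 75])
        assert lo == pytest.approx(med - 1.5 * (q3 - q1))
        assert hi == pytest.approx(med + 1.5 * (q3 - q1))

    def test_boundary_values_retained(self):
        # symmetric group: whiskers at med ± 1.5·IQR; a point exactly on the
        # whisker is kept
        pred = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        med = 2.0
        iqr = 2.0
        pred = np.append(pred, med + 1.5 * iqr)
        rep = detect_prediction_outliers(pred, np.array(["g"] * 6))
        # appended point changed quantiles; recompute on final group
        q1, m, q3 = np.percentile(pred, [25, 50, 75])
        on_whisker = np.isclose(pred, m + 1.5 * (q3 - q1))
        assert not set(np.flatnonzero(on_whisker)) & set(rep.flagged)

    def test_scale_equivariance(self, rng):
        pred = rng.normal(size=30)
        pred[5] += 10.0
        groups = np.repeat(["a", "b", "c"], 10)
        before = detect_prediction_outliers(pred, groups).flagged
        after = detect_prediction_outliers(3.0 * pred - 7.0, groups).flagged
        assert np.array_equal(before, after)

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            rep = detect_prediction_outliers(
                np.array([1.0, 2.0, 1.0, 1.0, 100.0]),
                np.array(["tiny", "tiny", "g", "g", "g"]),
            )
        assert "tiny" not in rep.bounds

    def test_tukey_variant(self, rng):
        pred = np.concatenate([rng.uniform(0, 1, 9), [3.2]])
        groups = np.array(["g"] * 10)
        rep = detect_prediction_outliers(pred, groups, whisker="tukey")
        q1, _, q3 = np.percentile(pred, [25, 50, 75])
        assert rep.bounds["g"] == (
            pytest.approx(q1 - 1.5 * (q3 - q1)),
            pytest.approx(q3 + 1.5 * (q3 - q1)),
        )


class TestTwoRoundPLSR:
    @staticmethod
    def _study_like_problem(rng, n_samples=5, units_per=3, rows_per_unit=3, p=10):
        """Sample-level signal in X, sample-level response: within a sample
        group the cross-validated predictions cluster tightly, as they do
        when regressing a panel attribute on instrument fingerprints."""
        n = n_samples * units_per * rows_per_unit
        patterns = 3.0 * rng.normal(size=(n_samples, p))
        sample_idx = np.repeat(np.arange(n_samples), units_per * rows_per_unit)
        X = patterns[sample_idx] + 0.3 * rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = patterns[sample_idx] @ beta + 0.1 * rng.normal(size=n)
        groups = np.repeat(np.arange(n_samples * units_per), rows_per_unit)
        return y, X, groups, sample_idx

    def test_outlier_free_data_keeps_round1(self, rng):
        """With exactly reproducible rows inside every sample group nothing
        is flagged and round 2 is round 1 unchanged."""
        patterns = 3.0 * rng.normal(size=(5, 10))
        samples = np.repeat(np.arange(5), 9)
        X = patterns[samples]
        y = patterns[samples] @ rng.normal(size=10)
        groups = np.repeat(np.arange(15), 3)
        r2, report, r1 = two_round_plsr(y, X, groups, 4, sample_groups=samples)
        assert report.n_flagged == 0
        assert r2 is r1
        assert r2.n_obs == y.size

    def test_contaminated_rows_flagged_and_error_improves(self):
        """Gross predictor-side contamination produces deviant round-1
        predictions, is flagged, and its removal lowers RMSECV
        (at least 9 of 10 seeds)."""
        successes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y, X, groups, samples = self._study_like_problem(rng)
            units = rng.choice(15, size=3, replace=False)
            bad = units * 3 + rng.integers(0, 3, size=3)
            X = X.copy()
            X[bad] += (
                20.0
                * np.sign(rng.normal(size=(3, X.shape[1])))
                * rng.uniform(0.5, 1.5, size=(3, X.shape[1]))
            )
            r2, report, r1 = two_round_plsr(y, X, groups, 8, sample_groups=samples)
            flagged_bad = set(bad) <= set(report.flagged.tolist())
            improved = r2.rmsecv < r1.rmsecv
            successes += flagged_bad and improved
        assert successes >= 9

    def test_n_obs_reflects_removed_rows(self, rng):
        y, X, groups, samples = self._study_like_problem(rng)
        X = X.copy()
        X[0] += 40.0
        r2, report, r1 = two_round_plsr(y, X, groups, 8, sample_groups=samples)
        assert r2.n_obs == y.size - report.n_flagged
        assert report.n_flagged >= 1

    def test_sane_flag_rate_on_clean_gaussian_data(self):
        """On clean data the screen never flags more than a quarter of the
        rows (20 seeds)."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y, X, groups, samples = self._study_like_problem(rng)
            _, report, _ = two_round_plsr(y, X, groups, 6, sample_groups=samples)
            assert report.n_flagged <= 0.25 * y.size
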