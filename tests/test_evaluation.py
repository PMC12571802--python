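"""Waveform metrics, clinical feature extraction, paired statistics, and the
two-model comparison report."""

import numpy as np
import pytest
from scipy import stats

from capwave import (
    DegenerateInputError,
    ModelConfig,
    NormalizationScheme,
    PressureWaveform,
    TCNAttention,
    ValidationError,
    evaluate_model,
    evaluate_models,
    extract_features,
    paired_ttest,
    spearman,
    waveform_metrics,
)
from capwave.cohort import PairedRecord
from capwave.evaluation import BP_ROWS, ERROR_COLS


class TestWaveformMetrics:
    def test_perfect_monotone_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert waveform_metrics(y, y) == (0.0, 0.0, 0.0, 1.0)

    def test_hand_computed_errors(self):
        mae, rmse, mx, scc = waveform_metrics([0, 0, 0, 0], [2, 0, 0, 0])
        assert (mae, rmse, mx) == (0.5, 1.0, 2.0)
        assert np.isnan(scc)  # constant reference has no rank ordering

    def test_reversed_ranks_give_scc_minus_one(self):
        *_, scc = waveform_metrics([1, 2, 3], [3, 2, 1])
        assert scc == -1.0  # d = [-2, 0, 2]: 1 - 48/24

    def test_scc_matches_rank_correlation_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 6, size=n).astype(float)  # many ties
            y_hat = rng.integers(0, 6, size=n).astype(float)
            if len(set(y)) < 2 or len(set(y_hat)) < 2:
                continue
            expected = stats.spearmanr(y, y_hat).statistic
            assert spearman(y, y_hat) == pytest.approx(expected, abs=1e-9)

    def test_scc_matches_closed_form_without_ties(self, rng):
        y = rng.normal(size=40)
        y_hat = rng.normal(size=40)
        d = stats.rankdata(y) - stats.rankdata(y_hat)
        closed = 1 - 6 * (d ** 2).sum() / (40 * (40 ** 2 - 1))
        assert spearman(y, y_hat) == pytest.approx(closed, abs=1e-12)

    def test_error_ordering_inequalities(self, rng):
        for _ in range(40):
            y = rng.normal(size=30)
            y_hat = rng.normal(size=30)
            mae, rmse, mx, _ = waveform_metrics(y, y_hat)
            assert mx >= rmse >= mae

    def test_scc_invariant_under_monotone_transform(self, rng):
        y = rng.normal(size=50)
        y_hat = rng.normal(size=50)
        base = spearman(y, y_hat)
        assert spearman(np.exp(y), y_hat) == pytest.approx(base, abs=1e-12)
        assert spearman(y, 3.0 * y_hat + 7.0) == pytest.approx(base, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValidationError):
            waveform_metrics([1.0], [1.0])
        with pytest.raises(ValidationError):
            waveform_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFeatures:
    def test_constant_waveform(self):
        assert extract_features(PressureWaveform(np.full(10, 80.0))) == (80.0, 80.0, 80.0)

    def test_linear_ramp_map_is_midpoint(self):
        w = PressureWaveform(np.linspace(60.0, 120.0, 61))
        sbp, dbp, mean_ap = extract_features(w)
        assert (sbp, dbp) == (120.0, 60.0)
        assert mean_ap == pytest.approx(90.0, abs=1e-12)

    def test_formula_map_estimator(self):
        w = PressureWaveform(np.linspace(60.0, 120.0, 61))
        *_, mean_ap = extract_features(w, map_method="formula")
        assert mean_ap == pytest.approx(80.0, abs=1e-12)  # DBP + PP/3

    def test_noise_free_records_match_generator_targets(self, small_cohort):
        for rec in small_cohort:
            sbp, dbp, _ = extract_features(rec.aortic)
            assert sbp == pytest.approx(rec.subject.aortic_sbp, abs=1e-9)
            assert dbp == pytest.approx(rec.subject.aortic_dbp, abs=1e-9)


class TestPairedTTest:
    def test_closed_form_example(self):
        # differences [1, 2, 3]: mean 2, sd 1 -> t = 2 sqrt(3)
        t, df, p = paired_ttest([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert df == 2
        assert p == pytest.approx(0.074179, abs=1e-5)

    def test_matches_scipy_oracle(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        t, df, p = paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_samples_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_antisymmetry(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        t1, _, p1 = paired_ttest(a, b)
        t2, _, p2 = paired_ttest(b, a)
        assert t2 == pytest.approx(-t1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)


class TestModelEvaluation:
    def test_perfect_predictor_scores_zero_error(self, small_cohort):
        rec = small_cohort[0]
        mirrored = PairedRecord(radial=rec.aortic.copy(), aortic=rec.aortic.copy(),
                                subject=rec.subject, record_id="mirror")
        metrics = evaluate_model(lambda x: x, [mirrored], name="perfect")
        row = metrics.per_record.iloc[0]
        assert row["TW_MAE"] == pytest.approx(0.0, abs=1e-12)
        assert row["TW_MAX"] == pytest.approx(0.0, abs=1e-12)
        assert row["SBP_MAE"] == pytest.approx(0.0, abs=1e-12)
        assert metrics.scc_mean == pytest.approx(1.0, abs=1e-12)

    def test_identical_models_are_not_significant(self, small_cohort):
        model = TCNAttention(ModelConfig(num_levels=2, channels=4, dropout=0.0),
                             seed=0)
        report = evaluate_models(model, model, small_cohort.records[:4])
        assert all(v == "n.s." for v in report.significance.values())

    def test_report_has_four_bp_rows_and_three_error_columns(self, small_cohort):
        m_a = TCNAttention(ModelConfig(num_levels=2, channels=4, dropout=0.0), seed=0)
        m_b = TCNAttention(ModelConfig(num_levels=2, channels=4, dropout=0.0,
                                       attention="none"), seed=1)
        report = evaluate_models(m_a, m_b, small_cohort.records[:4])
        payload = report.to_dict()
        for model_block in payload["models"].values():
            agg = model_block["aggregate"]
            assert tuple(agg.keys()) == BP_ROWS
            for row in agg.values():
                assert tuple(row.keys()) == ERROR_COLS
        assert set(payload["significance"].values()) <= {"n.s.", "*", "**"}
        # scalar features: MAE and RMSE columns coincide per record
        for metrics in (report.metrics_a, report.metrics_b):
            for bp in ("SBP", "DBP", "MAP"):
                np.testing.assert_array_equal(metrics.per_record[f"{bp}_MAE"],
                                              metrics.per_record[f"{bp}_RMSE"])
        assert "BP" in report.to_table()

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_model(lambda x: x, [])
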