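"""Feature assembly, robust bisquare fitting, training and calibration."""

import dataclasses

import numpy as np
import pytest

import nailhgb as nh
from nailhgb.errors import (
    DegenerateCalibrationError,
    SchemaError,
    SingularityError,
    ValidationError,
)
from nailhgb.qc import ColorFeatures


def _cf(rgb, lab=(50.0, 30.0, 18.0)):
    return ColorFeatures(mean_rgb=tuple(map(float, rgb)), mean_lab=lab,
                         retained_fraction=1.0)


META = nh.CaptureMetadata(flash_fired=True, exposure_time=1 / 60, iso=64.0,
                          f_number=2.2, brightness_value=5.0)


def _records(X, y, schema):
    return [nh.SubjectRecord(subject_id=f"S{i}",
                             feature_vector=nh.FeatureVector(tuple(row), schema),
                             cbc_hgb=float(v))
            for i, (row, v) in enumerate(zip(X, y))]


class TestBuildFeatures:
    def test_identical_fingers_average_to_same_color(self):
        fv = nh.build_features({f: _cf((150, 70, 60)) for f in (2, 3, 4, 5)},
                               skin_L=55.0, metadata=META)
        assert fv.values[fv.schema.index("nail_mean_r")] == 150.0

    def test_arithmetic_mean_across_fingers(self):
        colors = {f: _cf((r, 70, 60)) for f, r in zip((2, 3, 4, 5),
                                                      (100, 110, 120, 130))}
        fv = nh.build_features(colors, skin_L=55.0, metadata=META)
        assert fv.values[fv.schema.index("nail_mean_r")] == 115.0

    def test_thumb_excluded(self):
        colors = {f: _cf((r, 70, 60)) for f, r in zip((2, 3, 4, 5),
                                                      (100, 110, 120, 130))}
        colors[1] = _cf((255, 255, 255))  # thumb must not contribute
        fv = nh.build_features(colors, skin_L=55.0, metadata=META)
        assert fv.values[fv.schema.index("nail_mean_r")] == 115.0

    def test_no_usable_finger_is_subject_error(self):
        from nailhgb.errors import SubjectUnusableError

        with pytest.raises(SubjectUnusableError):
            nh.build_features({1: _cf((100, 70, 60))}, skin_L=50.0, metadata=META)

    def test_missing_required_metadata_named(self):
        meta = nh.CaptureMetadata(flash_fired=True)  # numeric fields absent
        from nailhgb.errors import MetadataError

        with pytest.raises(MetadataError, match="exposure_time_s"):
            nh.build_features({2: _cf((100, 70, 60))}, skin_L=50.0, metadata=meta)


class TestFitRobust:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        beta = np.array([2.0, -1.0, 0.5])
        y = 3.0 + X @ beta
        m = nh.fit_robust(X, y)
        assert m.constant == pytest.approx(3.0, abs=1e-6)
        np.testing.assert_allclose(m.weights, beta, atol=1e-6)
        assert m.fit_info["robust_weights_min"] == 1.0

    def test_matches_ols_on_clean_gaussian_data(self):
        """Without outliers the bisquare fit agrees with closed-form OLS
        normal equations to within 1%."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.2, 200)
        m = nh.fit_robust(x[:, None], y)
        X1 = np.column_stack([np.ones(200), x])
        ols = np.linalg.solve(X1.T @ X1, X1.T @ y)
        assert m.weights[0] == pytest.approx(ols[1], rel=0.01)
        assert m.constant == pytest.approx(ols[0], rel=0.01)

    def test_resists_gross_outliers(self):
        """Three +20 g/dL outliers barely move the robust slope while they
        shift plain OLS by > 15%."""
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 50)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 50)
        yc = y.copy()
        yc[np.argsort(x)[-3:]] += 20.0
        clean = nh.fit_robust(x[:, None], y)
        robust = nh.fit_robust(x[:, None], yc)
        X1 = np.column_stack([np.ones(50), x])
        ols = np.linalg.lstsq(X1, yc, rcond=None)[0]
        assert abs(robust.weights[0] - clean.weights[0]) / abs(clean.weights[0]) < 0.05
        assert abs(ols[1] - clean.weights[0]) / abs(clean.weights[0]) > 0.15

    def test_cross_check_against_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = 1.5 + X @ [2.0, -1.0, 0.5] + rng.normal(0, 1, 200)
        y[:10] += 15.0
        mine = nh.fit_robust(X, y)
        ref = sm.RLM(y, sm.add_constant(X),
                     M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
        np.testing.assert_allclose(np.r_[mine.constant, mine.weights],
                                   ref.params, rtol=2e-2, atol=2e-3)

    def test_zero_variance_column_named(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        X[:, 1] = 7.0
        with pytest.raises(SingularityError, match="flat"):
            nh.fit_robust(X, rng.normal(size=30), schema=("ok", "flat"))

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        X = np.column_stack([a, 2 * a + 1e-12, rng.normal(size=30)])
        with pytest.raises(SingularityError):
            nh.fit_robust(X, rng.normal(size=30), schema=("a", "twice_a", "b"))

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            nh.fit_robust(np.ones((3, 2)) + np.eye(3, 2), np.ones(3))


class TestBiasAdjustAndPredict:
    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        y = 1.0 + X @ [1.0, 2.0]
        m = nh.fit_robust(X, y)
        m_low = nh.HgbModel(constant=m.constant - 0.5, weights=m.weights,
                            schema=m.schema)
        adj = nh.bias_adjust(m_low, X, y)
        assert adj.bias_adjustment == pytest.approx(0.5, abs=1e-8)

    def test_zero_mean_discovery_residual(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 3))
        y = 2.0 + X @ [1.0, -0.5, 0.2] + rng.normal(0, 1, 60)
        m = nh.bias_adjust(nh.fit_robust(X, y), X, y)
        resid = nh.predict_matrix(m, X) - y
        assert abs(resid.mean()) < 1e-10

    def test_empty_discovery_rejected(self):
        m = nh.HgbModel(constant=0.0, weights=np.array([1.0]), schema=("a",))
        with pytest.raises(ValidationError):
            nh.bias_adjust(m, np.empty((0, 1)), np.empty(0))

    def test_predict_intercept_and_unit_weight(self):
        m = nh.HgbModel(constant=2.0, weights=np.array([1.0, 0.0]),
                        schema=("a", "b"), bias_adjustment=0.25)
        assert nh.predict(m, nh.FeatureVector((0.0, 0.0), ("a", "b"))) == 2.25
        m2 = nh.HgbModel(constant=0.0, weights=np.array([1.0]), schema=("a",))
        assert nh.predict(m2, nh.FeatureVector((9.5,), ("a",))) == 9.5

    def test_schema_mismatch_raises(self):
        m = nh.HgbModel(constant=0.0, weights=np.array([1.0]), schema=("a",))
        with pytest.raises(SchemaError):
            nh.predict(m, nh.FeatureVector((1.0,), ("z",)))

    def test_display_rounding(self):
        assert nh.display_hgb(10.9499) == 10.9


class TestTrainPopulation:
    SCHEMA = ("a", "b")

    def _cohort(self, n=40, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = 10.0 + X @ [1.5, -0.7] + rng.normal(0, noise, n)
        return _records(X, y, self.SCHEMA)

    def test_noiseless_cohort_zero_test_error(self):
        res = nh.train_population(self._cohort(), n_repeats=5, discovery_n=25,
                                  rng_seed=0, schema=self.SCHEMA)
        assert (res.summary.test_mae < 1e-8).all()

    def test_deterministic_given_seed(self):
        a = nh.train_population(self._cohort(noise=0.5), n_repeats=2,
                                discovery_n=25, rng_seed=5, schema=self.SCHEMA)
        b = nh.train_population(self._cohort(noise=0.5), n_repeats=2,
                                discovery_n=25, rng_seed=5, schema=self.SCHEMA)
        assert a.best.repeat_index == b.best.repeat_index
        assert a.summary.equals(b.summary)
        np.testing.assert_array_equal(a.best.model.weights, b.best.model.weights)

    def test_split_hygiene(self):
        res = nh.train_population(self._cohort(noise=0.5), n_repeats=3,
                                  discovery_n=25, rng_seed=1, schema=self.SCHEMA)
        assert not set(res.best.discovery_ids) & set(res.best.test_ids)
        assert len(res.best.discovery_ids) + len(res.best.test_ids) == 40

    def test_cohort_too_small(self):
        with pytest.raises(ValidationError):
            nh.train_population(self._cohort(n=20), n_repeats=1,
                                discovery_n=237, schema=self.SCHEMA)

    def test_constant_columns_pruned(self):
        recs = self._cohort(noise=0.1)
        schema = ("a", "b", "const")
        recs = [nh.SubjectRecord(subject_id=r.subject_id,
                                 feature_vector=nh.FeatureVector(
                                     (*r.feature_vector.values, 3.3), schema),
                                 cbc_hgb=r.cbc_hgb)
                for r in recs]
        res = nh.train_population(recs, n_repeats=2, discovery_n=25,
                                  rng_seed=0, schema=schema)
        assert res.pruned_features == ("const",)
        assert res.schema == ("a", "b")


class TestCalibratePersonal:
    def test_noiseless_grid_aligned_recovery(self, noiseless_params):
        """Four noiseless calibration weeks recover the color-Hgb line
        exactly; test-week predictions match truth to machine precision."""
        weekly = [12.0 + k / 5.5 for k in (-6, -3, 0, 3, -4, -2, 2, 4)]
        sessions = nh.generate_serial_subject(weekly, params=noiseless_params,
                                              rng_seed=1)
        recs = [nh.record_from_subject(s) for s in sessions]
        pm = nh.calibrate_personal(recs[:4])
        for rec in recs[4:]:
            assert nh.predict(pm, rec.feature_vector) == pytest.approx(
                rec.cbc_hgb, abs=1e-6)

    def test_constant_hgb_degenerate(self, params):
        sessions = nh.generate_serial_subject([10.0] * 4, params=params,
                                              rng_seed=2)
        recs = [nh.record_from_subject(s) for s in sessions]
        with pytest.raises(DegenerateCalibrationError):
            nh.calibrate_personal(recs)

    def test_fewer_than_two_sessions_rejected(self, params):
        s = nh.generate_subject(10.0, params=params, rng_seed=0)
        with pytest.raises(ValidationError):
            nh.calibrate_personal([nh.record_from_subject(s)])

    def test_personal_beats_population_on_serial_study(self, params,
                                                       true_rgb_model):
        """With subject-level measurement offsets in play, per-subject
        calibration shrinks the test-week LoA below the population model's
        on the same sessions (the serial-monitoring premise)."""
        rng = np.random.default_rng(0)
        pop_pred, per_pred, ref, ids = [], [], [], []
        for i in range(8):
            base = rng.uniform(8, 13)
            weekly = [base + d for d in (2, 1, 0, -1, 2, 1, 0, -1)]
            sessions = nh.generate_serial_subject(weekly, params=params,
                                                  rng_seed=100 + i,
                                                  subject_id=f"P{i}")
            recs = [nh.record_from_subject(s) for s in sessions]
            pm = nh.calibrate_personal(recs[:4])
            for r in recs[4:]:
                per_pred.append(nh.predict(pm, r.feature_vector))
                pop_pred.append(nh.predict(true_rgb_model, r.feature_vector))
                ref.append(r.cbc_hgb)
                ids.append(r.subject_id)
        pop = nh.loa_random_effects(np.array(pop_pred), np.array(ref), np.array(ids))
        per = nh.loa_random_effects(np.array(per_pred), np.array(ref), np.array(ids))
        assert per.sd < pop.sd


class TestModelIO:
    def test_json_round_trip(self, tmp_path):
        m = nh.HgbModel(constant=-20.7, weights=np.array([0.18, 0.0]),
                        schema=("nail_mean_r", "skin_L"), bias_adjustment=0.1,
                        fit_info={"converged": True})
        p = nh.save_model(m, tmp_path / "m.json", seed=7)
        back = nh.load_model(p)
        assert back.constant == m.constant
        np.testing.assert_array_equal(back.weights, m.weights)
        assert back.schema == m.schema
        assert back.bias_adjustment == m.bias_adjustment
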