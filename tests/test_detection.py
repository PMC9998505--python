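import numpy as np
import pytest

from hdotools.detection import (DetectorModel, detect, evaluate_detector,
                                extract_features, train_detector)
from hdotools.spectral import HDOBand
from hdotools.synth import OscillationSpec, SignalRecipe, simulate_time_course
from hdotools.timecourse import TimeCourse


def _make_model(band, logit):
    """Hand-built detector with a constant output logit (for trivial cases)."""
    return DetectorModel(band=band, scaler_mean=np.zeros(22),
                         scaler_scale=np.ones(22),
                         weights=[np.zeros((22, 8)), np.zeros(8),
                                  np.zeros(8), logit])


class TestExtractFeatures:
    def test_periodic_signal_group_members_equal(self, band):
        """5-s-periodic signal: the three lags of each group share a phase."""
        t = np.arange(600.0)
        tc = TimeCourse(1.0 + 0.05 * np.cos(2 * np.pi * t / 5.0), dt=1.0)
        x = tc.values - tc.values.mean()
        denom = np.dot(x, x)
        ac = np.array([np.dot(x[:-k], x[k:]) / denom for k in range(1, 16)])
        # independent closed form: biased autocorrelation of a sinusoid
        oracle = (1 - np.arange(1, 16) / 600.0) * np.cos(2 * np.pi *
                                                         np.arange(1, 16) / 5)
        np.testing.assert_allclose(ac, oracle, atol=0.02)
        fv = extract_features(tc, band)
        # groups {1,6,11}..{5,10,15}: members equal up to the O(k/N) bias
        for g in range(5):
            members = ac[[g, g + 5, g + 10]]
            assert np.ptp(members) < 0.04
        # the group containing lag 5 (in-phase) is the largest
        assert np.argmax(fv.autocorr) == 4

    def test_white_noise_groups_near_zero(self, band):
        rng = np.random.default_rng(0)
        tc = TimeCourse(100 + rng.normal(0, 1, 600), dt=1.0)
        fv = extract_features(tc, band)
        assert np.all(np.abs(fv.autocorr) < 2.0 / np.sqrt(600))

    def test_trend_invariance(self, band):
        rng = np.random.default_rng(1)
        base = 100 + rng.normal(0, 1, 600)
        t = np.arange(600.0)
        fv0 = extract_features(TimeCourse(base, dt=1.0), band)
        fv1 = extract_features(TimeCourse(base + 5.0 + 0.01 * t, dt=1.0), band)
        np.testing.assert_allclose(fv1.spectral, fv0.spectral, atol=0.02)
        np.testing.assert_allclose(fv1.autocorr, fv0.autocorr, atol=0.05)

    def test_scaling_after_normalization_invariance(self, band):
        from hdotools.preprocess import normalize_mean

        rng = np.random.default_rng(2)
        tc = TimeCourse(100 + rng.normal(0, 1, 600), dt=1.0)
        scaled = tc.with_values(3.7 * tc.values)
        fv0 = extract_features(normalize_mean(tc), band)
        fv1 = extract_features(normalize_mean(scaled), band)
        np.testing.assert_allclose(fv1.as_array(), fv0.as_array(), atol=1e-12)

    def test_feature_dimensions(self, band):
        rng = np.random.default_rng(3)
        fv = extract_features(TimeCourse(100 + rng.normal(0, 1, 600), dt=1.0),
                              band)
        assert fv.spectral.shape == (17,)
        assert fv.autocorr.shape == (5,)

    def test_preconditions(self, band):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="dt"):
            extract_features(TimeCourse(rng.normal(size=100), dt=2.0), band)
        with pytest.raises(ValueError, match="60 s"):
            extract_features(TimeCourse(rng.normal(size=30), dt=1.0), band)
        with pytest.raises(ValueError, match="zero-variance"):
            extract_features(TimeCourse(np.full(600, 5.0), dt=1.0), band)


class TestTrainDetector:
    def _separable_features(self, band, n=40):
        rng = np.random.default_rng(5)
        feats, labels = [], []
        for i in range(n):
            pos = i % 2 == 0
            spectral = rng.normal(0, 0.1, 17) + (3.0 if pos else 0.0)
            feats.append(type("FV", (), {})())
            from hdotools.detection import FeatureVector

            feats[-1] = FeatureVector(spectral, rng.normal(0, 0.1, 5), band)
            labels.append(pos)
        return feats, labels

    def test_separable_training_accuracy(self, band):
        feats, labels = self._separable_features(band)
        model = train_detector(feats, labels, seed=0)
        pred = [model.score(fv) >= 0.5 for fv in feats]
        assert pred == labels

    def test_deterministic_given_seed(self, band):
        feats, labels = self._separable_features(band)
        m1 = train_detector(feats, labels, seed=3)
        m2 = train_detector(feats, labels, seed=3)
        assert m1.to_json() == m2.to_json()

    def test_shuffled_labels_chance_cv(self, band):
        from hdotools.detection import FeatureVector

        rng = np.random.default_rng(6)
        feats = [FeatureVector(rng.normal(size=17), rng.normal(size=5), band)
                 for _ in range(120)]
        labels = rng.permutation([True, False] * 60)
        model = train_detector(feats, labels, seed=0)
        assert abs(model.cv_accuracy - 0.5) < 0.15

    def test_single_class_rejected(self, band):
        from hdotools.detection import FeatureVector

        rng = np.random.default_rng(7)
        feats = [FeatureVector(rng.normal(size=17), rng.normal(size=5), band)
                 for _ in range(10)]
        with pytest.raises(ValueError, match="classes"):
            train_detector(feats, [True] * 10, seed=0)


class TestDetect:
    def test_strong_oscillation_detected(self, band, trained_detector):
        r = SignalRecipe(duration=600, dt=1.0, drift_order=1,
                         hdo=OscillationSpec(0.2, 0.025, 5.0), seed=101)
        res = detect(simulate_time_course(r), trained_detector)
        assert res["oscillatory"] is True
        assert 0.5 <= res["score"] <= 1.0

    def test_zero_variance_rejected(self, trained_detector):
        with pytest.raises(ValueError, match="zero-variance"):
            detect(TimeCourse(np.full(600, 2.0), dt=1.0), trained_detector)

    def test_band_mismatch_rejected(self, trained_detector):
        rng = np.random.default_rng(8)
        tc = TimeCourse(100 + rng.normal(0, 1, 600), dt=1.0)
        other = HDOBand(0.25, 0.02)
        fv = extract_features(tc, other)
        with pytest.raises(ValueError, match="band"):
            trained_detector.score(fv)

    def test_json_round_trip_scores(self, band, trained_detector, tmp_path):
        path = tmp_path / "model.json"
        trained_detector.to_json(path)
        back = DetectorModel.from_json(path)
        rng = np.random.default_rng(9)
        tc = TimeCourse(100 + rng.normal(0, 1, 600), dt=1.0)
        assert detect(tc, back)["score"] == detect(tc, trained_detector)["score"]


class TestEvaluateDetector:
    def _courses(self, n_pos, n_neg, seed0):
        courses, labels = [], []
        for i in range(n_pos + n_neg):
            pos = i < n_pos
            hdo = OscillationSpec(0.2, 0.02, 5.0) if pos else None
            r = SignalRecipe(duration=600, dt=1.0, drift_order=1, hdo=hdo,
                             seed=seed0 + i)
            courses.append(simulate_time_course(r))
            labels.append(pos)
        return courses, labels

    def test_strong_separation_is_perfect(self, trained_detector):
        courses, labels = self._courses(15, 15, seed0=300)
        res = evaluate_detector(trained_detector, courses, labels)
        assert res["specificity"] == 1.0
        assert res["sensitivity"] == 1.0

    def test_all_positive_classifier(self, band):
        courses, labels = self._courses(5, 5, seed0=400)
        model = _make_model(band, logit=50.0)
        res = evaluate_detector(model, courses, labels)
        assert res["specificity"] == 0.0
        assert res["sensitivity"] == 1.0

    def test_single_class_metric_undefined(self, band):
        courses, labels = self._courses(5, 0, seed0=500)
        res = evaluate_detector(_make_model(band, 50.0), courses, labels)
        assert np.isnan(res["specificity"])
        assert res["sensitivity"] == 1.0
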