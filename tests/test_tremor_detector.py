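"""Classifier training, threshold calibration and the decision cascade."""
import itertools

import numpy as np
import pandas as pd
import pytest

import tremorkit as tk
from tremorkit.spectral_features import WindowFeatures
from tremorkit.tremor_detector import (MFCC_COLS, TremorDetectionModel,
                                       calibrate_threshold, classify_features,
                                       classify_window, fit_detector,
                                       fit_movement_threshold,
                                       train_classifier)


def toy_model(tau=0.5, theta=10.0):
    """Model whose probability is driven by mfcc_1 alone (sigmoid(10*z1))."""
    return TremorDetectionModel(
        feature_means=np.zeros(12), feature_sds=np.ones(12),
        coefficients=np.array([10.0] + [0.0] * 11), intercept=0.0,
        prob_threshold=tau, movement_power_threshold=theta,
        config_hash=tk.PipelineConfig().hash(),
        config=tk.PipelineConfig().to_dict())


def feature_row(mfcc1=0.0, peak=5.0, low_power=1.0, tremor_power=2.0):
    return WindowFeatures(peak_freq_hz=peak,
                          mfcc=np.array([mfcc1] + [0.0] * 11),
                          low_band_power=low_power, tremor_power=tremor_power)


class TestTrainClassifier:
    def test_separable_features_perfect_at_half(self, rng):
        X = rng.normal(size=(200, 12))
        y = X[:, 0] > 0
        X[y, 0] += 3.0
        coef, intercept, means, sds = train_classifier(X, y)
        z = (X - means) / sds
        p = 1 / (1 + np.exp(-(z @ coef + intercept)))
        assert ((p >= 0.5) == y).mean() == 1.0

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(50, 12))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, np.ones(50, dtype=bool))

    def test_constant_feature_stays_finite(self, rng):
        X = rng.normal(size=(100, 12))
        X[:, 5] = 2.5
        y = X[:, 0] > 0
        coef, intercept, _, sds = train_classifier(X, y)
        assert np.all(np.isfinite(coef)) and np.isfinite(intercept)
        assert sds[5] == 1.0

    def test_oversampling_suppresses_cycling_false_positives(self):
        """Weight-100 cycling training lowers LR-level cycling false positives
        (paired over 10 seeds, matched specificity calibration)."""
        fp = {1.0: 0, 100.0: 0}
        cfg = tk.SimulationConfig(cycling_harmonic_decay=0.85, noise_sd=1.0)
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            tremor = tk.simulate_activity_windows("tremor", 120, cfg, rng)
            rest = tk.simulate_activity_windows("rest", 240, cfg, rng)
            cyc = tk.simulate_activity_windows("cycling", 120, cfg, rng)
            feats = tk.featurize_array(np.concatenate([tremor, rest, cyc]),
                                       cfg.fs)
            y = np.r_[np.ones(120), np.zeros(360)].astype(bool)
            acts = np.r_[["rest"] * 360, ["cycling"] * 120]
            X = feats[MFCC_COLS].to_numpy()
            for factor in (1.0, 100.0):
                coef, b, mu, sd = train_classifier(
                    X, y, acts, cycling_oversample=factor, seed=seed)
                p = 1 / (1 + np.exp(-(((X - mu) / sd) @ coef + b)))
                tau = calibrate_threshold(p[~y], 0.95)
                fp[factor] += int((p[-120:] >= tau).sum())
        assert fp[100.0] <= fp[1.0]


class TestCalibrateThreshold:
    def test_uniform_negatives_order_statistic(self):
        probs = np.arange(1, 100 + 1) / 100.0 - 0.005  # 0.005 .. 0.995
        tau = calibrate_threshold(probs, 0.95)
        assert tau == pytest.approx(sorted(probs)[95])  # 96th smallest
        assert (probs >= tau).sum() == 5

    def test_target_one_gives_perfect_training_specificity(self, rng):
        probs = rng.uniform(size=500)
        tau = calibrate_threshold(probs, 1.0)
        assert (probs < tau).all()
        assert tau > probs.max()

    def test_specificity_bracket(self, rng):
        for n in (100, 137, 1000):
            probs = rng.uniform(size=n)
            tau = calibrate_threshold(probs, 0.95)
            spec = (probs < tau).mean()
            assert 0.95 <= spec <= 0.96

    def test_empty_negatives_raise(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([]))


class TestMovementThreshold:
    def test_bimodal_mixture_midpoint(self, rng):
        logp = np.concatenate([rng.normal(-2.0, 0.3, 5000),
                               rng.normal(1.0, 0.3, 5000)])
        theta = fit_movement_threshold(10.0 ** logp, seed=0)
        assert -2.0 < np.log10(theta) < 1.0
        assert abs(np.log10(theta) - (-0.5)) < 0.3

    def test_identical_values_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_movement_threshold(np.full(500, 3.0))

    def test_seed_invariant_midpoint(self, rng):
        logp = np.concatenate([rng.normal(-2.0, 0.3, 2000),
                               rng.normal(1.0, 0.3, 2000)])
        thetas = {fit_movement_threshold(10.0 ** logp, seed=s)
                  for s in (0, 1, 42)}
        assert max(thetas) / min(thetas) < 1.001


class TestDecisionCascade:
    def test_truth_table_all_eight_combinations(self):
        """Exhaustive mapping (lr, peak, movement) -> final_state."""
        model = toy_model(tau=0.5, theta=10.0)
        for lr, peak_ok, move in itertools.product([False, True], repeat=3):
            f = feature_row(mfcc1=1.0 if lr else -1.0,
                            peak=5.0 if peak_ok else 9.0,
                            low_power=20.0 if move else 1.0)
            c = classify_window(model, f)
            assert c.lr_positive == lr
            assert c.peak_in_rest_band == peak_ok
            assert c.arm_movement == move
            if move:
                expected = "rejected_movement"
            elif lr and peak_ok:
                expected = "tremor"
            else:
                expected = "no_tremor"
            assert c.final_state == expected
            assert (c.tremor_power is not None) == (expected == "tremor")

    def test_band_boundaries_inclusive(self):
        model = toy_model()
        for peak in (3.0, 7.0):
            assert classify_window(model, feature_row(mfcc1=1.0, peak=peak)
                                   ).final_state == "tremor"
        for peak in (2.5, 7.5):
            assert classify_window(model, feature_row(mfcc1=1.0, peak=peak)
                                   ).final_state == "no_tremor"

    def test_null_peak_fails_clinical_criterion(self):
        model = toy_model()
        c = classify_window(model, feature_row(mfcc1=1.0, peak=None))
        assert not c.peak_in_rest_band
        assert c.final_state == "no_tremor"

    def test_movement_filter_ablation_superset(self, small_cohort_features):
        cfg, feats = small_cohort_features
        model = fit_detector(feats, tk.PipelineConfig())
        with_f = classify_features(model, feats, movement_filter=True)
        without = classify_features(model, feats, movement_filter=False)
        w_set = with_f.final_state == "tremor"
        wo_set = without.final_state == "tremor"
        assert (w_set <= wo_set).all()          # per-window subset property
        assert wo_set.sum() >= w_set.sum()
        assert (without.final_state != "rejected_movement").all()

    def test_cascade_scale_robustness(self, rng):
        # gain changes flip neither the LR decision nor the clinical filter
        from .conftest import noise_window, tone_window
        w = tone_window(5.0, 15.0) + noise_window(rng)
        model = toy_model(theta=1e9)
        cfg = tk.PipelineConfig()
        decisions = set()
        for k in (0.1, 1.0, 50.0):
            f = tk.featurize_window(k * w, 100, cfg)
            c = classify_window(model, f)
            decisions.add((c.lr_positive, c.peak_in_rest_band))
        assert len(decisions) == 1

    def test_config_hash_mismatch_refused(self, small_cohort_features):
        import dataclasses
        from tremorkit.tremor_detector import ConfigMismatchError
        cfg, feats = small_cohort_features
        model = fit_detector(feats, tk.PipelineConfig())
        other = dataclasses.replace(
            tk.PipelineConfig(),
            welch=dataclasses.replace(tk.PipelineConfig().welch, segment_s=1.0))
        with pytest.raises(ConfigMismatchError):
            classify_features(model, feats, config=other)


class TestModelPersistence:
    def test_json_round_trip(self, tmp_path, small_cohort_features):
        cfg, feats = small_cohort_features
        model = fit_detector(feats, tk.PipelineConfig())
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = TremorDetectionModel.from_json(path)
        np.testing.assert_array_equal(loaded.coefficients, model.coefficients)
        assert loaded.prob_threshold == model.prob_threshold
        assert loaded.config_hash == model.config_hash
        p1 = model.predict_proba(feats[MFCC_COLS].to_numpy()[:50])
        p2 = loaded.predict_proba(feats[MFCC_COLS].to_numpy()[:50])
        np.testing.assert_allclose(p1, p2)

    def test_training_is_deterministic(self, small_cohort_features):
        cfg, feats = small_cohort_features
        m1 = fit_detector(feats, tk.PipelineConfig())
        m2 = fit_detector(feats, tk.PipelineConfig())
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        assert m1.prob_threshold == m2.prob_threshold
        assert m1.movement_power_threshold == m2.movement_power_threshold
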