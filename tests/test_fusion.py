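"""Feature fusion, the FCN classifier, and the two-stage cascade."""

import hashlib
import pickle

import numpy as np
import pytest

import boldfusion as bf
from boldfusion.fusion import STAGE1_FFM, STAGE2_FFM, fuse_features


@pytest.fixture(scope="module")
def fitted_cascade(tiny_pool):
    """One small fitted cascade shared by the routing tests."""
    return bf.CascadeClassifier(
        stage1_params={"lstm_epochs": 2, "fcn_max_iter": 120},
        stage2_params={"lstm_epochs": 2, "fcn_max_iter": 120},
        random_state=0,
    ).fit(tiny_pool)


class TestFuseFeatures:
    def test_paper_preset_dimensions(self, rng):
        fL = rng.normal(size=100)
        fR = rng.normal(size=2048)
        fF = rng.normal(size=607)
        fused = fuse_features(fL, fR, fF, expected=STAGE1_FFM)
        assert fused.shape == (2755,)
        np.testing.assert_array_equal(fused[:100], fL)
        np.testing.assert_array_equal(fused[100:2148], fR)
        np.testing.assert_array_equal(fused[2148:], fF)

    def test_ablation_sums_enabled_parts(self, rng):
        fused = fuse_features(fL=None, fR=rng.normal(size=2048), fF=rng.normal(size=607))
        assert fused.shape == (2655,)
        with pytest.raises(ValueError):
            fuse_features()

    def test_preset_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="preset"):
            fuse_features(rng.normal(size=99), rng.normal(size=2048),
                          rng.normal(size=607), expected=STAGE1_FFM)


class TestFcnClassifier:
    def test_separable_problem_is_learned(self, rng):
        n = 120
        y = np.arange(n) % 2
        X = rng.normal(size=(n, 8))
        X[:, 0] += 6.0 * y
        clf = bf.FcnClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.99

    def test_probabilities_normalise(self, rng):
        y = np.arange(60) % 3
        X = rng.normal(size=(60, 5)) + y[:, None]
        clf = bf.FcnClassifier(random_state=0).fit(X, y)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_training_is_reproducible(self, rng):
        y = np.arange(40) % 2
        X = rng.normal(size=(40, 6)) + y[:, None]
        a = bf.FcnClassifier(random_state=4).fit(X, y)
        b = bf.FcnClassifier(random_state=4).fit(X, y)
        for wa, wb in zip(a.net_.coefs_, b.net_.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            bf.FcnClassifier().fit(rng.normal(size=(10, 3)), np.zeros(10))


class TestCascadeRouting:
    def test_every_signal_gets_stage1_and_scores_normalise(self, fitted_cascade, tiny_pool):
        preds = bf.run_cascade(tiny_pool, fitted_cascade)
        assert len(preds) == len(tiny_pool)
        for p in preds:
            assert p.stage1_label in ("emotion", "memory", "motor", "resting")
            assert sum(p.stage1_scores.values()) == pytest.approx(1.0, abs=1e-6)

    def test_stage2_only_for_emotion_and_memory(self, fitted_cascade, tiny_pool):
        preds = bf.run_cascade(tiny_pool, fitted_cascade)
        routed = sum(p.stage1_label in ("emotion", "memory") for p in preds)
        with_stage2 = sum(bool(p.stage2) for p in preds)
        assert with_stage2 == routed
        for p in preds:
            if p.stage1_label == "emotion":
                assert len(p.stage2) == 3
                assert all(lab in ("high", "medium", "low") for _, lab, _ in p.stage2)
            elif p.stage1_label == "memory":
                assert len(p.stage2) == 2
                assert all(lab in ("encode", "recall") for _, lab, _ in p.stage2)
            else:
                assert p.stage2 == []

    def test_resting_only_pool_has_no_stage2(self, fitted_cascade):
        resting = bf.SignalPool(
            [s for s in bf.generate_pool(6, 2, seed=21) if s.task_label == "resting"],
            target_length=600,
        )
        preds = fitted_cascade.predict(resting)
        routed = [p for p in preds if p.stage1_label in ("emotion", "memory")]
        unrouted = [p for p in preds if p not in routed]
        assert all(p.stage2 == [] for p in unrouted)

    def test_misrouted_motor_signal_still_gets_three_emotion_phases(
        self, fitted_cascade, tiny_conditioned
    ):
        motor = next(s for s in tiny_conditioned if s.task_label == "motor")
        out = bf.stage2_classify(motor, "emotion", fitted_cascade)
        assert len(out) == 3  # cascade error propagation is observable

    def test_stage2_rejects_non_routable_labels(self, fitted_cascade, tiny_conditioned):
        sig = tiny_conditioned.signals[0]
        with pytest.raises(ValueError, match="emotion/memory"):
            bf.stage2_classify(sig, "resting", fitted_cascade)

    def test_stage1_rejects_unpadded_signals(self, fitted_cascade, tiny_pool):
        raw = next(s for s in tiny_pool if len(s) != 600)
        with pytest.raises(ValueError, match="length"):
            bf.stage1_classify(raw, fitted_cascade)

    def test_prediction_never_mutates_the_fitted_system(self, fitted_cascade, tiny_pool):
        before = hashlib.sha256(pickle.dumps(fitted_cascade)).hexdigest()
        fitted_cascade.predict(tiny_pool)
        after = hashlib.sha256(pickle.dumps(fitted_cascade)).hexdigest()
        assert before == after

    def test_cascade_predictions_are_deterministic(self, fitted_cascade, tiny_pool):
        a = fitted_cascade.predict(tiny_pool)
        b = fitted_cascade.predict(tiny_pool)
        assert [p.stage1_label for p in a] == [p.stage1_label for p in b]
        assert [p.stage2 for p in a] == [p.stage2 for p in b]


class TestFfmClassifier:
    def test_selected_feature_count_follows_preset(self, fitted_cascade):
        stage1 = fitted_cascade.stage1_
        assert len(stage1.selector_.selection_) == STAGE1_FFM["n_selected"]
        stage2 = fitted_cascade.stage2_emotion_
        assert len(stage2.selector_.selection_) == STAGE2_FFM["n_selected"]

    def test_wrong_input_length_rejected(self, rng):
        clf = bf.FfmClassifier(use_lstm=False, use_cnn=False)
        with pytest.raises(ValueError, match="length 600"):
            clf.fit(rng.normal(size=(8, 200)), np.arange(8) % 2)

    def test_spectral_only_ablation_fits_and_predicts(self, tiny_conditioned):
        X = tiny_conditioned.to_matrix()
        y = tiny_conditioned.task_labels()
        clf = bf.FfmClassifier(
            use_lstm=False, use_cnn=False, n_selected=64, fcn_max_iter=150,
            random_state=0,
        ).fit(X, y)
        assert clf.featurize(X).shape == (len(y), 607)
        proba = clf.predict_proba(X)
        assert proba.shape == (len(y), 4)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_bundles_expose_branch_slices(self, fitted_cascade, tiny_conditioned):
        X = tiny_conditioned.to_matrix()[:2]
        bundles = fitted_cascade.stage1_.bundles(X)
        for b in bundles:
            assert b.fused.shape == (2755,)
            np.testing.assert_array_equal(b.fused[100:2148], b.fR)
            assert b.selected.shape == (512,)
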