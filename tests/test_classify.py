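"""Sample-weighted forests, confidence correction, end-time detection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.ensemble import RandomForestClassifier

from pgesdetect import (
    ArtifactArchetype,
    RFParams,
    SimulationParams,
    build_feature_matrix,
    correct_predictions,
    detect_pges_end,
    fit_kmeans,
    make_sample_weights,
    predict_recording,
    simulate_dataset,
    train_ensemble,
)
from pgesdetect.classify import DetectionResult, EpochPredictions
from pgesdetect.clustering import ClusterModel
from pgesdetect.emd import ArtifactFeatureMap, artifact_feature_map
from pgesdetect.features import EpochFeatureMatrix, NON_SUPPRESSION, SUPPRESSION
from pgesdetect.preprocess import bandpass
from pgesdetect.synthetic import boxcar_envelope


class TestSampleWeights:
    def _matrix(self, small_features):
        return small_features[0]

    def test_boost_one_reduces_to_uniform(self, small_features):
        matrix = self._matrix(small_features)
        assignments = {rid: 0 for rid in matrix.frame["recording_id"].unique()}
        w = make_sample_weights(matrix, assignments, focal_cluster=0, boost=1.0)
        np.testing.assert_array_equal(w, 1.0)

    def test_weight_sum_arithmetic(self, small_features):
        matrix = self._matrix(small_features)
        rids = list(matrix.frame["recording_id"].unique())
        assignments = {rid: (0 if i < 4 else 1) for i, rid in enumerate(rids)}
        w = make_sample_weights(matrix, assignments, focal_cluster=0, boost=3.0)
        n_focal = int((matrix.frame["recording_id"].isin(rids[:4])).sum())
        n_rest = len(w) - n_focal
        assert w.sum() == pytest.approx(n_focal * 3.0 + n_rest)

    def test_empty_focal_cluster(self, small_features):
        matrix = self._matrix(small_features)
        assignments = {rid: 0 for rid in matrix.frame["recording_id"].unique()}
        w = make_sample_weights(matrix, assignments, focal_cluster=5, boost=2.0)
        np.testing.assert_array_equal(w, 1.0)

    def test_unknown_recording_rejected(self, small_features):
        matrix = self._matrix(small_features)
        with pytest.raises(ValueError, match="without a cluster"):
            make_sample_weights(matrix, {"nope": 0}, 0, 2.0)

    def test_boost_below_one_rejected(self, small_features):
        matrix = self._matrix(small_features)
        assignments = {rid: 0 for rid in matrix.frame["recording_id"].unique()}
        with pytest.raises(ValueError):
            make_sample_weights(matrix, assignments, 0, 0.5)


class TestTrainEnsemble:
    def test_one_model_per_nonempty_cluster(self, small_features, fast_rf):
        matrix, maps = small_features
        model = fit_kmeans(maps, K=3, seed=0)
        ensemble = train_ensemble(matrix, model, rf_params=fast_rf, boost=2.0)
        assert set(ensemble.models) == set(model.assignments.values())

    def test_single_class_labels_rejected(self, small_features, fast_rf):
        matrix, maps = small_features
        model = fit_kmeans(maps, K=1, seed=0)
        only_supp = EpochFeatureMatrix(
            matrix.frame[matrix.frame["label"] == SUPPRESSION].reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="non-suppression"):
            train_ensemble(only_supp, model, rf_params=fast_rf)

    def test_plain_rf_reduction(self, small_features, fast_rf):
        """K = 1 with boost = 1 must predict identically to a plain
        random forest with the same seed on the same features."""
        matrix, maps = small_features
        model = fit_kmeans(maps, K=1, seed=0)
        ensemble = train_ensemble(matrix, model, rf_params=fast_rf, boost=1.0)
        assert ensemble.n_models == 1
        plain = RandomForestClassifier(
            n_estimators=fast_rf.n_trees, max_features="sqrt",
            random_state=fast_rf.seed, n_jobs=1,
        ).fit(matrix.X, matrix.y)
        forest = ensemble.models[0]
        np.testing.assert_array_equal(forest.predict(matrix.X), plain.predict(matrix.X))

    def test_save_load_round_trip(self, small_features, fast_rf, tmp_path):
        from pgesdetect.classify import SWRFEnsemble

        matrix, maps = small_features
        model = fit_kmeans(maps, K=2, seed=0)
        ensemble = train_ensemble(matrix, model, rf_params=fast_rf, boost=2.0)
        ensemble.save(tmp_path / "ens")
        back = SWRFEnsemble.load(tmp_path / "ens")
        assert set(back.models) == set(ensemble.models)
        np.testing.assert_array_equal(
            back.models[0].predict(matrix.X[:10]),
            ensemble.models[0].predict(matrix.X[:10]),
        )


class TestSWRFSpecialization:
    def test_focal_forest_not_worse_on_its_cluster(self, fast_rf):
        """On recordings carrying the focal cluster's breathing artifacts,
        the boosted forest's epoch error rate must not exceed a plain
        forest's (paired comparison on simulator ground truth)."""
        clean = simulate_dataset(
            10, seed=31, base_params=SimulationParams(duration=60.0),
            pges_sampler=lambda rng: float(rng.uniform(10, 45)),
        )
        breathing = ArtifactArchetype(
            "breath", tuple(range(9)), boxcar_envelope(0, 60, 150.0, 60), "breathing"
        )
        noisy = simulate_dataset(
            14, [breathing], seed=32,
            base_params=SimulationParams(duration=60.0),
            pges_sampler=lambda rng: float(rng.uniform(10, 45)),
        )
        for i, item in enumerate(noisy):
            item.recording.id = item.annotation.recording_id = f"noisy{i:02d}"
        train_items = clean + noisy[:8]
        test_items = noisy[8:]

        train_matrix = EpochFeatureMatrix.concat(
            [build_feature_matrix(d.recording, d.annotation) for d in train_items]
        )
        assignments = {d.recording.id: (1 if d.archetype else 0) for d in train_items}
        cluster_model = ClusterModel(
            K=2, centroids=np.zeros((2, 18 * 300)), inertia=0.0,
            assignments=assignments,
        )
        boosted = train_ensemble(
            train_matrix, cluster_model, rf_params=fast_rf, boost=3.0, clusters=[1]
        ).models[1]
        plain = RandomForestClassifier(
            n_estimators=fast_rf.n_trees, max_features="sqrt",
            random_state=fast_rf.seed, n_jobs=1,
        ).fit(train_matrix.X, train_matrix.y)

        err_boosted = err_plain = 0
        for d in test_items:
            fm = build_feature_matrix(d.recording, d.annotation)
            err_boosted += int(np.sum(boosted.predict(fm.X) != fm.y))
            err_plain += int(np.sum(plain.predict(fm.X) != fm.y))
        assert err_boosted <= err_plain


class TestPredictRecording:
    def test_confidence_bounds_and_determinism(self, small_dataset, small_features, fast_rf):
        matrix, maps = small_features
        model = fit_kmeans(maps, K=2, seed=0)
        ensemble = train_ensemble(matrix, model, rf_params=fast_rf, boost=2.0)
        rid = small_dataset[0].recording.id
        fm = matrix.for_recording(rid)
        amap = [m for m in maps if m.recording_id == rid][0]
        p1 = predict_recording(fm, amap, model, ensemble)
        p2 = predict_recording(fm, amap, model, ensemble)
        assert np.all((p1.confidence >= 0.5) & (p1.confidence <= 1.0))
        np.testing.assert_array_equal(p1.labels, p2.labels)
        np.testing.assert_array_equal(p1.confidence, p2.confidence)

    def test_epochs_away_from_transition_mostly_correct(
        self, small_dataset, small_features, fast_rf
    ):
        matrix, maps = small_features
        model = fit_kmeans(maps, K=1, seed=0)
        ensemble = train_ensemble(matrix, model, rf_params=fast_rf, boost=1.0)
        correct = total = 0
        for item in small_dataset:
            rid = item.recording.id
            fm = matrix.for_recording(rid)
            amap = [m for m in maps if m.recording_id == rid][0]
            preds = predict_recording(fm, amap, model, ensemble)
            truth = fm.y
            t_end = item.annotation.pges_end
            starts = np.arange(len(truth), dtype=float)
            away = np.abs(starts - t_end) > 2.0
            away[:3] = False  # seizure-tail epochs are not suppression-like
            correct += int(np.sum(preds.labels[away] == truth[away]))
            total += int(np.sum(away))
        assert correct / total >= 0.90

    def test_fallback_to_nearest_modelled_cluster(self, small_features, fast_rf):
        matrix, maps = small_features
        model = fit_kmeans(maps, K=3, seed=0)
        focal = model.assignments[maps[0].recording_id]
        ensemble = train_ensemble(
            matrix, model, rf_params=fast_rf, boost=2.0, clusters=[focal]
        )
        # a recording whose own cluster has no model must still be scored
        other = [m for m in maps if model.assignments[m.recording_id] != focal][0]
        preds = predict_recording(matrix.for_recording(other.recording_id), other,
                                  model, ensemble)
        assert preds.cluster == focal


class TestCorrection:
    def _preds(self, labels, conf):
        return EpochPredictions(
            labels=np.array(labels), confidence=np.array(conf, dtype=float)
        )

    def test_short_low_confidence_run_absorbed(self):
        S, I = SUPPRESSION, NON_SUPPRESSION
        preds = self._preds([S, S, S, I, S, S], [0.9, 0.9, 0.9, 0.55, 0.9, 0.9])
        out = correct_predictions(preds, min_run=2, conf_thresh=0.8)
        np.testing.assert_array_equal(out, [S] * 6)

    def test_confident_short_run_kept(self):
        S, I = SUPPRESSION, NON_SUPPRESSION
        preds = self._preds([S, S, S, I, S, S], [0.9, 0.9, 0.9, 0.95, 0.9, 0.9])
        out = correct_predictions(preds, min_run=2, conf_thresh=0.8)
        np.testing.assert_array_equal(out, [S, S, S, I, S, S])

    def test_homogeneous_input_unchanged(self):
        S = SUPPRESSION
        preds = self._preds([S] * 6, [0.6] * 6)
        out = correct_predictions(preds, min_run=3, conf_thresh=0.8)
        np.testing.assert_array_equal(out, [S] * 6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        labels=st.lists(st.integers(0, 1), min_size=1, max_size=40),
        seed=st.integers(0, 10_000),
    )
    def test_long_runs_never_changed(self, labels, seed):
        rng = np.random.default_rng(seed)
        labels = np.array(labels)
        conf = rng.uniform(0.5, 1.0, size=len(labels))
        preds = EpochPredictions(labels=labels.copy(), confidence=conf)
        min_run = 3
        out = correct_predictions(preds, min_run=min_run, conf_thresh=0.8)
        # every maximal run of length ≥ min_run keeps its original labels
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                if i - start >= min_run:
                    np.testing.assert_array_equal(out[start:i], labels[start:i])
                start = i


class TestDetectEnd:
    S, I = SUPPRESSION, NON_SUPPRESSION

    def test_transition_detected(self):
        labels = [self.S] * 43 + [self.I] * 5
        result = detect_pges_end(np.array(labels))
        assert result.p_end == 43.0
        assert result.censored is False

    def test_no_suppression(self):
        result = detect_pges_end(np.array([self.I] * 20))
        assert result.p_end is None
        assert result.detected is False

    def test_suppression_never_ends_is_censored(self):
        result = detect_pges_end(np.array([self.S] * 300))
        assert result.p_end == 300.0
        assert result.censored is True

    def test_leading_non_suppression_ignored(self):
        # seizure-tail epochs classified non-suppression must not trigger
        labels = [self.I] * 2 + [self.S] * 30 + [self.I] * 8
        assert detect_pges_end(np.array(labels)).p_end == 32.0
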