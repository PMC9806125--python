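"""Cluster-oriented sample-weighted random forests (SWRF) and the
first-intermittent-slow-wave decision rule.

One forest is trained per artifact cluster; forest *i* sees every epoch
of every training recording, but epochs from recordings in cluster *i*
carry an elevated sample weight, so the forest specializes in the
artifact regime of its cluster while retaining the full training set.
An unseen recording is routed to its nearest cluster and scored by that
cluster's forest; short low-confidence label runs are absorbed by their
context, and the predicted PGES end is the start of the first
non-suppression epoch that follows suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .clustering import ClusterModel, assign
from .emd import ArtifactFeatureMap
from .features import NON_SUPPRESSION, SUPPRESSION, EpochFeatureMatrix

__all__ = [
    "RFParams",
    "SWRFEnsemble",
    "EpochPredictions",
    "DetectionResult",
    "make_sample_weights",
    "train_ensemble",
    "predict_recording",
    "correct_predictions",
    "detect_pges_end",
]

DEFAULT_BOOST = 2.0
DEFAULT_MIN_RUN = 3
DEFAULT_CONF_THRESH = 0.8


@dataclass
class RFParams:
    """Random-forest hyperparameters (defaults: 100 trees, unlimited
    depth, sqrt-features per split)."""

    n_trees: int = 100
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    seed: int = 0

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class EpochPredictions:
    """Per-epoch labels with vote-fraction confidences."""

    labels: np.ndarray  # int, SUPPRESSION/NON_SUPPRESSION per epoch
    confidence: np.ndarray  # probability of the predicted class, ∈ [0, 1]
    corrected_labels: np.ndarray | None = None
    cluster: int | None = None

    @property
    def final_labels(self) -> np.ndarray:
        return self.corrected_labels if self.corrected_labels is not None else self.labels


@dataclass
class DetectionResult:
    """Predicted end of suppression for one recording.

    ``p_end`` is None when no suppression epoch was found; ``censored``
    is True when suppression never ended inside the window (``p_end`` is
    then the window end).
    """

    p_end: float | None
    censored: bool = False

    @property
    def detected(self) -> bool:
        return self.p_end is not None


def make_sample_weights(
    matrix: EpochFeatureMatrix,
    assignments: dict[str, int],
    focal_cluster: int,
    boost: float,
) -> np.ndarray:
    """Per-row weights: ``boost`` for rows of focal-cluster recordings, 1 else."""
    if boost < 1:
        raise ValueError("boost must be ≥ 1")
    rids = matrix.frame["recording_id"]
    unknown = set(rids.unique()) - set(assignments)
    if unknown:
        raise ValueError(f"recordings without a cluster assignment: {sorted(unknown)}")
    in_focal = rids.map(assignments).to_numpy() == focal_cluster
    return np.where(in_focal, float(boost), 1.0)


@dataclass
class SWRFEnsemble:
    """One specialist forest per (non-empty) cluster."""

    models: dict[int, RandomForestClassifier]
    boost: float
    rf_params: RFParams

    @property
    def n_models(self) -> int:
        return len(self.models)

    def save(self, directory: str | Path) -> Path:
        import json

        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for cluster, model in self.models.items():
            joblib.dump(model, directory / f"forest_cluster{cluster}.joblib")
        manifest = {
            "clusters": sorted(self.models),
            "boost": self.boost,
            "rf_params": {
                "n_trees": self.rf_params.n_trees,
                "max_depth": self.rf_params.max_depth,
                "max_features": self.rf_params.max_features,
                "seed": self.rf_params.seed,
            },
        }
        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "SWRFEnsemble":
        import json

        import joblib

        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        models = {
            c: joblib.load(directory / f"forest_cluster{c}.joblib")
            for c in manifest["clusters"]
        }
        return cls(
            models=models,
            boost=manifest["boost"],
            rf_params=RFParams(**manifest["rf_params"]),
        )


def train_ensemble(
    matrix: EpochFeatureMatrix,
    cluster_model: ClusterModel,
    rf_params: RFParams | None = None,
    boost: float = DEFAULT_BOOST,
    clusters: list[int] | None = None,
) -> SWRFEnsemble:
    """Train one sample-weighted forest per non-empty cluster.

    ``clusters`` restricts training to the given cluster indices (the
    leave-one-out driver trains only the fold's focal cluster).  With a
    single cluster and ``boost = 1`` the ensemble reduces to one plain
    random forest.
    """
    rf_params = rf_params or RFParams()
    y = matrix.y
    present = np.unique(y)
    if len(present) < 2:
        missing = (
            "suppression" if SUPPRESSION not in present else "non-suppression"
        )
        raise ValueError(f"training labels contain no {missing} epochs")
    X = matrix.X
    non_empty = sorted(set(cluster_model.assignments.values()))
    if clusters is not None:
        non_empty = [c for c in non_empty if c in clusters]
    models: dict[int, RandomForestClassifier] = {}
    for cluster in non_empty:
        weights = make_sample_weights(matrix, cluster_model.assignments, cluster, boost)
        forest = rf_params.build()
        forest.fit(X, y, sample_weight=weights)
        models[cluster] = forest
    return SWRFEnsemble(models=models, boost=boost, rf_params=rf_params)


def predict_recording(
    matrix: EpochFeatureMatrix,
    amap: ArtifactFeatureMap,
    cluster_model: ClusterModel,
    ensemble: SWRFEnsemble,
) -> EpochPredictions:
    """Route a recording to its cluster's forest and score every epoch.

    The label is the forest's majority class; confidence is the vote
    fraction of that class.  A recording routed to a cluster without a
    trained model falls back to the nearest cluster that has one.
    """
    cluster = assign(amap, cluster_model)
    if cluster not in ensemble.models:
        x = amap.flatten()
        d2 = ((cluster_model.centroids - x[None, :]) ** 2).sum(axis=1)
        for c in np.argsort(d2, kind="stable"):
            if int(c) in ensemble.models:
                cluster = int(c)
                break
        else:
            raise ValueError("ensemble contains no trained models")
    forest = ensemble.models[cluster]
    proba = forest.predict_proba(matrix.X)
    idx = np.argmax(proba, axis=1)
    labels = forest.classes_[idx].astype(int)
    confidence = proba[np.arange(len(idx)), idx]
    return EpochPredictions(labels=labels, confidence=confidence, cluster=cluster)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, stop_exclusive, label)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, int(labels[start])))
            start = i
    return runs


def correct_predictions(
    preds: EpochPredictions,
    min_run: int = DEFAULT_MIN_RUN,
    conf_thresh: float = DEFAULT_CONF_THRESH,
) -> np.ndarray:
    """Absorb implausibly short, low-confidence label runs.

    Sudden one-or-two-epoch state flips are unlikely to be real
    suppression boundaries.  Scanning left to right, any run shorter
    than ``min_run`` whose mean confidence is below ``conf_thresh`` and
    whose neighbours agree with each other is flipped to the surrounding
    label; the scan repeats until a fixpoint.  Runs of length ≥
    ``min_run`` — and confident short runs — are never changed.
    """
    labels = preds.labels.copy()
    conf = preds.confidence
    while True:
        changed = False
        runs = _runs(labels)
        for k, (start, stop, lab) in enumerate(runs):
            if stop - start >= min_run:
                continue
            if float(np.mean(conf[start:stop])) >= conf_thresh:
                continue
            left = runs[k - 1][2] if k > 0 else None
            right = runs[k + 1][2] if k + 1 < len(runs) else None
            surround = left if left is not None else right
            if surround is None:
                continue
            if left is not None and right is not None and left != right:
                continue  # ambiguous context
            labels[start:stop] = surround
            changed = True
            break  # re-derive runs after each flip (left-to-right fixpoint)
        if not changed:
            break
    preds.corrected_labels = labels
    return labels


def detect_pges_end(labels: np.ndarray, epoch_length: float = 1.0) -> DetectionResult:
    """End of suppression from the (corrected) per-epoch labels.

    The predicted end time is the start of the first non-suppression
    epoch that follows at least one suppression epoch, on the epoch grid.
    """
    labels = np.asarray(labels)
    supp = np.flatnonzero(labels == SUPPRESSION)
    if len(supp) == 0:
        return DetectionResult(p_end=None)
    first_supp = supp[0]
    after = np.flatnonzero(labels[first_supp:] == NON_SUPPRESSION)
    if len(after) == 0:
        return DetectionResult(p_end=len(labels) * epoch_length, censored=True)
    return DetectionResult(p_end=float((first_supp + after[0]) * epoch_length))
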