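"""End-to-end orchestration over directories of EDF files + annotation
tables: feature extraction, clustering, training, detection, evaluation,
with stage outputs cached on disk and a manifest recording config hash,
seed and library versions."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import (
    SWRFEnsemble,
    correct_predictions,
    detect_pges_end,
    predict_recording,
    train_ensemble,
)
from .clustering import ClusterModel, fit_kmeans
from .config import PipelineConfig
from .emd import ArtifactFeatureMap, artifact_feature_map
from .evaluate import EvaluationReport, LOOConfig, loo_cv, summarize, time_distance, _true_end
from .features import EpochFeatureMatrix, build_feature_matrix
from .io import Annotation, Recording, read_annotations, read_recording
from .preprocess import bandpass, extract_postictal

log = logging.getLogger("pgesdetect")

__all__ = ["run_pipeline", "load_dataset", "compute_features_and_maps"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and recording id."""

    def __init__(self, stage: str, recording_id: str | None, cause: Exception):
        self.stage = stage
        self.recording_id = recording_id
        super().__init__(
            f"stage {stage!r} failed"
            + (f" on recording {recording_id!r}" if recording_id else "")
            + f": {cause}"
        )


def load_dataset(
    edf_dir: str | Path, annotations_csv: str | Path, config: PipelineConfig
) -> list[tuple[Recording, Annotation]]:
    """Read every annotated EDF and cut its postictal window."""
    edf_dir = Path(edf_dir)
    annotations = {a.recording_id: a for a in read_annotations(annotations_csv)}
    pairs = []
    for rid, annotation in sorted(annotations.items()):
        path = edf_dir / f"{rid}.edf"
        try:
            recording = read_recording(path, recording_id=rid)
            window = extract_postictal(
                recording, annotation, duration=config.postictal_duration
            )
        except Exception as exc:  # noqa: BLE001 - surfaced with context
            raise StageError("load", rid, exc) from exc
        # postictal window times are relative to seizure end now
        pairs.append((window, Annotation(rid, 0.0, annotation.has_pges, annotation.pges_end)))
    return pairs


def compute_features_and_maps(
    pairs: Sequence[tuple[Recording, Annotation]],
    config: PipelineConfig,
    cache_dir: str | Path | None = None,
) -> tuple[EpochFeatureMatrix, list[ArtifactFeatureMap]]:
    """Per-recording feature matrices and artifact maps, cached as
    CSV/NPY keyed by recording id and config hash."""
    cache = Path(cache_dir) if cache_dir else None
    digest = config.digest()
    feats, maps = [], []
    for recording, annotation in pairs:
        t0 = time.perf_counter()
        fcsv = cache / f"{recording.id}.{digest}.features.csv" if cache else None
        mnpy = cache / f"{recording.id}.{digest}.map.npy" if cache else None
        try:
            if fcsv is not None and fcsv.exists():
                import pandas as pd

                feats.append(EpochFeatureMatrix(pd.read_csv(fcsv)))
            else:
                fm = build_feature_matrix(
                    recording,
                    annotation,
                    emd_band=config.emd_band,
                    baseline_band=config.baseline_band,
                )
                feats.append(fm)
                if fcsv is not None:
                    cache.mkdir(parents=True, exist_ok=True)
                    fm.to_csv(fcsv)
            if mnpy is not None and mnpy.exists():
                maps.append(
                    ArtifactFeatureMap(np.load(mnpy), recording_id=recording.id)
                )
            else:
                amap = artifact_feature_map(
                    bandpass(recording, *config.emd_band), T=config.map_T
                )
                maps.append(amap)
                if mnpy is not None:
                    cache.mkdir(parents=True, exist_ok=True)
                    np.save(mnpy, amap.values)
        except Exception as exc:  # noqa: BLE001
            raise StageError("features", recording.id, exc) from exc
        log.info(
            "features %s: %d epochs in %.1f s",
            recording.id,
            feats[-1].frame.shape[0],
            time.perf_counter() - t0,
        )
    return EpochFeatureMatrix.concat(feats), maps


def run_pipeline(
    config: PipelineConfig,
    edf_dir: str | Path,
    annotations_csv: str | Path,
    out_dir: str | Path,
    loo: bool = False,
) -> EvaluationReport:
    """Run every stage and leave artifacts in ``out_dir``.

    Without ``loo``, a single clustering model and ensemble are fitted on
    the full dataset and each recording is scored in-sample (a smoke/fit
    mode); with ``loo`` the recording-based leave-one-out protocol is
    used.  Outputs: features/ cache, cluster_model.json, ensemble/,
    report.json, report.csv, manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = load_dataset(edf_dir, annotations_csv, config)
    log.info("loaded %d recordings", len(pairs))
    features, maps = compute_features_and_maps(
        pairs, config, cache_dir=out_dir / "features"
    )

    if loo:
        loo_config = LOOConfig(
            K=config.K,
            boost=config.boost,
            rf_params=config.rf_params,
            min_run=config.min_run,
            conf_thresh=config.conf_thresh,
            map_T=config.map_T,
            seed=config.seed,
        )
        report = loo_cv(pairs, loo_config, features=features, maps=maps)
    else:
        try:
            cluster_model = fit_kmeans(maps, K=config.K, seed=config.seed)
        except Exception as exc:  # noqa: BLE001
            raise StageError("cluster", None, exc) from exc
        cluster_model.to_json(out_dir / "cluster_model.json")
        try:
            ensemble = train_ensemble(
                features, cluster_model, rf_params=config.rf_params, boost=config.boost
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("train", None, exc) from exc
        ensemble.save(out_dir / "ensemble")
        map_by_id = {m.recording_id: m for m in maps}
        distances, flagged = {}, []
        for recording, annotation in pairs:
            try:
                preds = predict_recording(
                    features.for_recording(recording.id),
                    map_by_id[recording.id],
                    cluster_model,
                    ensemble,
                )
                corrected = correct_predictions(
                    preds, min_run=config.min_run, conf_thresh=config.conf_thresh
                )
                detection = detect_pges_end(corrected)
            except Exception as exc:  # noqa: BLE001
                raise StageError("detect", recording.id, exc) from exc
            p_end = detection.p_end if detection.p_end is not None else 0.0
            if detection.p_end is None or detection.censored:
                flagged.append(recording.id)
            distances[recording.id] = time_distance(p_end, _true_end(annotation))
        report = summarize(distances, flagged=flagged)

    report.to_json(out_dir / "report.json")
    report.to_csv(out_dir / "report.csv")
    _write_manifest(config, out_dir, n=report.n, loo=loo)
    log.info(
        "report: n=%d TD_avg=%.2f Acc_5s=%.3f Acc_10s=%.3f",
        report.n,
        report.TD_avg,
        report.Acc_5s,
        report.Acc_10s,
    )
    return report


def _write_manifest(config: PipelineConfig, out_dir: Path, n: int, loo: bool) -> None:
    import sklearn

    import pgesdetect

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_recordings": n,
        "loo": loo,
        "versions": {
            "pgesdetect": pgesdetect.__version__,
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
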