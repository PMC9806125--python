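"""Synthetic validation experiments.

The clinical recordings the detector was designed for are private, so
the package validates itself on simulated postictal EEG whose ground
truth is known exactly.  Each function here defines one fixed study
condition — signal family, dataset size, artifact archetypes, detector
configuration — and measures the corresponding quantity from scratch.
The conditions are deliberately frozen: they are the package's reference
experiments, reported by ``scripts/acceptance.py`` and asserted by the
test suite.

Problem sizes (60 recordings × 150 s for end-to-end recovery, 36 × 120 s
for the hybrid-vs-baseline comparison, 50-tree forests, focal-cluster
training per leave-one-out fold) keep a full run on one CPU in the
minutes range.
"""

from __future__ import annotations

import numpy as np

from .classify import RFParams
from .emd import _count_rule_ok, artifact_feature_map, emd, hilbert_analytic
from .evaluate import EvaluationReport, LOOConfig, loo_cv
from .features import EpochFeatureMatrix, build_feature_matrix
from .preprocess import EMD_BAND, bandpass
from .synthetic import ArtifactArchetype, SimulationParams, boxcar_envelope, simulate_dataset


def _archetype(name, channels, start, stop, amplitude, total, kind):
    return ArtifactArchetype(
        name=name,
        channel_mask=tuple(channels),
        time_envelope=boxcar_envelope(start, stop, amplitude, total=total),
        kind=kind,
    )


__all__ = [
    "emd_reconstruction_benchmark",
    "hilbert_tone_benchmark",
    "clustering_recovery_benchmark",
    "loo_recovery_benchmark",
    "hybrid_vs_baseline_benchmark",
]


def emd_reconstruction_benchmark(
    seed: int = 0, n_signals: int = 200, fs: float = 200.0, duration: float = 3.0
) -> dict:
    """Decompose random tone-plus-noise mixtures and audit the EMD axioms.

    Signals are mixtures of 2–4 sinusoids with frequencies drawn from
    1–30 Hz, unit-scale amplitudes, and additive Gaussian noise.  Reports
    the worst-case relative reconstruction error of Σ IMF + residual and
    the fraction of returned modes satisfying the extrema/zero-crossing
    count rule.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    max_rel = 0.0
    modes_total = 0
    modes_ok = 0
    for _ in range(n_signals):
        x = np.zeros(n)
        for _ in range(rng.integers(2, 5)):
            x += rng.uniform(0.5, 2.0) * np.sin(
                2 * np.pi * rng.uniform(1.0, 30.0) * t + rng.uniform(0, 2 * np.pi)
            )
        x += 0.3 * rng.standard_normal(n)
        d = emd(x)
        rel = float(np.max(np.abs(d.reconstruct() - x)) / np.max(np.abs(x)))
        max_rel = max(max_rel, rel)
        for m in d.imfs:
            modes_total += 1
            modes_ok += int(_count_rule_ok(m))
    return {
        "max_rel_error": max_rel,
        "count_rule_pass_rate": modes_ok / modes_total,
        "n_signals": n_signals,
        "n_modes": modes_total,
    }


def hilbert_tone_benchmark(
    freqs: tuple[float, ...] = (1.0, 2.0, 4.0, 10.0),
    amplitude: float = 2.0,
    fs: float = 200.0,
    duration: float = 10.0,
) -> dict:
    """Instantaneous amplitude/frequency error on pure tones.

    Worst-case interior errors (outer 10 % of samples excluded, where the
    finite analytic signal is edge-distorted), as percentages.
    """
    n = int(duration * fs)
    t = np.arange(n) / fs
    interior = slice(n // 10, -n // 10)
    amp_err = freq_err = 0.0
    for f in freqs:
        x = amplitude * np.sin(2 * np.pi * f * t)
        amp, inst_f = hilbert_analytic(x, fs)
        amp_err = max(amp_err, float(np.max(np.abs(amp[interior] - amplitude)) / amplitude))
        freq_err = max(freq_err, float(np.max(np.abs(inst_f[interior] - f)) / f))
    return {
        "max_amplitude_error_pct": 100.0 * amp_err,
        "max_frequency_error_pct": 100.0 * freq_err,
        "n_tones": len(freqs),
    }


def clustering_recovery_benchmark(
    seed: int = 0, n: int = 40, duration: float = 90.0
) -> dict:
    """Recover two disjoint-channel artifact populations with K-means.

    Two movement archetypes hit the front (channels 0–7) and back
    (channels 8–15) channel groups at high amplitude.  Reports the
    fraction of recordings whose cluster matches their generating
    archetype, maximized over the label permutation.
    """
    archetypes = [
        _archetype("front", range(0, 8), 5, 60, 300.0, int(duration), "movement"),
        _archetype("back", range(8, 16), 5, 60, 300.0, int(duration), "movement"),
    ]
    ds = simulate_dataset(
        n,
        archetypes,
        seed=seed,
        base_params=SimulationParams(duration=duration),
        pges_sampler=lambda rng: float(rng.uniform(10.0, duration * 0.75)),
    )
    from .clustering import fit_kmeans

    maps = [
        artifact_feature_map(bandpass(d.recording, *EMD_BAND), T=300) for d in ds
    ]
    model = fit_kmeans(maps, K=2, seed=seed)
    truth = np.array([d.archetype == "back" for d in ds], dtype=int)
    labels = np.array([model.assignments[d.recording.id] for d in ds])
    match = max(
        float(np.mean(labels == truth)), float(np.mean(labels == 1 - truth))
    )
    return {"recovery_accuracy": match, "n_recordings": n}


def _dataset_features(ds):
    feats = [build_feature_matrix(d.recording, d.annotation) for d in ds]
    maps = [artifact_feature_map(bandpass(d.recording, *EMD_BAND), T=300) for d in ds]
    return EpochFeatureMatrix.concat(feats), maps


def loo_recovery_benchmark(
    seed: int = 0, n: int = 60, duration: float = 150.0
) -> EvaluationReport:
    """End-to-end parameter recovery on an artifact-light dataset.

    ``n`` recordings with suppression durations uniform on 20–120 s;
    leave-one-out with the hybrid detector (K = 2, boost = 2, 50 trees).
    """
    ds = simulate_dataset(
        n,
        seed=seed,
        base_params=SimulationParams(duration=duration),
        pges_sampler=lambda rng: float(rng.uniform(20.0, 120.0)),
    )
    features, maps = _dataset_features(ds)
    config = LOOConfig(K=2, boost=2.0, rf_params=RFParams(n_trees=50, seed=seed), seed=seed)
    return loo_cv(ds, config, features=features, maps=maps)


def hybrid_vs_baseline_benchmark(
    seed: int = 0, n: int = 36, duration: float = 120.0
) -> dict:
    """Hybrid (clustered, sample-weighted) vs plain-forest baseline.

    Three artifact archetypes occupy disjoint channel groups; the hybrid
    detector clusters recordings (K = 3) and boosts the focal cluster's
    epochs, the baseline is the identical pipeline reduced to one cluster
    with uniform weights (K = 1, boost = 1).  Both run leave-one-out on
    the same folds, features and seed.
    """
    T = int(duration)
    archetypes = [
        _archetype("breath", range(0, 6), 0, 50, 120.0, T, "breathing"),
        _archetype("muscle", range(6, 12), 10, 70, 60.0, T, "muscle"),
        _archetype("move", range(12, 18), 20, 60, 150.0, T, "movement"),
    ]
    ds = simulate_dataset(
        n,
        archetypes,
        seed=seed,
        base_params=SimulationParams(duration=duration),
        pges_sampler=lambda rng: float(rng.uniform(15.0, 90.0)),
    )
    features, maps = _dataset_features(ds)
    rf = RFParams(n_trees=50, seed=seed)
    hybrid = loo_cv(
        ds, LOOConfig(K=3, boost=2.0, rf_params=rf, seed=seed),
        features=features, maps=maps,
    )
    baseline = loo_cv(
        ds, LOOConfig(K=1, boost=1.0, rf_params=rf, seed=seed),
        features=features, maps=maps,
    )
    return {"hybrid": hybrid, "baseline": baseline, "n_recordings": n}
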