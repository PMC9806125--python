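"""Synthetic postictal EEG generator: ground-truth and spectral checks."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import periodogram

from pgesdetect import (
    ArtifactArchetype,
    SimulationParams,
    boxcar_envelope,
    simulate_dataset,
    simulate_recording,
)


def band_power(x, fs, lo, hi):
    """Independent periodogram oracle used to audit generated content."""
    freqs, pxx = periodogram(x, fs=fs)
    return pxx[(freqs >= lo) & (freqs <= hi)].sum()


class TestSimulateRecording:
    def test_suppression_quieter_than_resumption(self):
        params = SimulationParams(
            duration=80.0, pges_duration=40.0, seizure_tail_duration=0.0, seed=3
        )
        rec, ann = simulate_recording(params)
        assert ann.pges_end == 40.0
        fs = int(rec.fs)
        quiet = np.abs(rec.samples[:, : 40 * fs]).mean(axis=1)
        loud = np.abs(rec.samples[:, 40 * fs :]).mean(axis=1)
        assert np.all(quiet < loud)

    def test_seed_determinism(self):
        params = SimulationParams(duration=30.0, pges_duration=10.0, seed=9)
        r1, _ = simulate_recording(params)
        r2, _ = simulate_recording(params)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_pges_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_recording(SimulationParams(duration=60.0, pges_duration=90.0))

    def test_no_pges_recording(self):
        params = SimulationParams(duration=30.0, pges_duration=None, seed=5)
        rec, ann = simulate_recording(params)
        assert ann.has_pges is False
        assert ann.pges_end is None
        # activity present from the start: no suppressed leading interval
        first = np.abs(rec.samples[:, : int(5 * rec.fs)]).mean()
        assert first > 5.0

    def test_breathing_artifact_band_power(self):
        """0.2–0.5 Hz power on masked channels during the active window
        must dominate the same band outside it (periodogram oracle)."""
        archetype = ArtifactArchetype(
            name="breath",
            kind="breathing",
            channel_mask=tuple(range(8)),
            time_envelope=boxcar_envelope(10, 20, 120.0, total=60),
        )
        params = SimulationParams(
            duration=60.0, pges_duration=50.0, artifacts=(archetype,), seed=21
        )
        rec, _ = simulate_recording(params)
        fs = rec.fs
        for c in range(8):
            active = band_power(rec.samples[c, int(10 * fs) : int(20 * fs)], fs, 0.2, 0.5)
            quiet = band_power(rec.samples[c, int(30 * fs) : int(40 * fs)], fs, 0.2, 0.5)
            assert active > 5 * quiet

    def test_artifact_respects_channel_mask(self):
        archetype = ArtifactArchetype(
            name="move", kind="movement", channel_mask=(0, 1),
            time_envelope=boxcar_envelope(5, 15, 200.0, total=30),
        )
        params = SimulationParams(
            duration=30.0, pges_duration=25.0, artifacts=(archetype,), seed=2
        )
        rec, _ = simulate_recording(params)
        sl = slice(int(5 * rec.fs), int(15 * rec.fs))
        masked = np.abs(rec.samples[:2, sl]).mean()
        unmasked = np.abs(rec.samples[2:, sl]).mean()
        assert masked > 10 * unmasked

    def test_suppression_threshold_recovers_boundary(self):
        """A plain 10 μV peak-to-peak rule per epoch finds the true
        boundary within one epoch on artifact-free data."""
        for seed in (0, 1, 2):
            params = SimulationParams(
                duration=60.0, pges_duration=33.6, seizure_tail_duration=0.0,
                seed=seed,
            )
            rec, ann = simulate_recording(params)
            fs = int(rec.fs)
            n_epochs = int(rec.duration)
            epochs = rec.samples[:, : n_epochs * fs].reshape(18, n_epochs, fs)
            p2p = epochs.max(axis=2) - epochs.min(axis=2)
            suppressed = (p2p < 10.0).all(axis=0)
            boundary = np.flatnonzero(~suppressed)[0]
            assert abs(boundary - ann.pges_end) <= 1.0


class TestSimulateDataset:
    def test_stratified_counts(self):
        archetypes = [
            ArtifactArchetype("a", (0,), boxcar_envelope(0, 10, 50.0)),
            ArtifactArchetype("b", (1,), boxcar_envelope(0, 10, 50.0)),
        ]
        base = SimulationParams(duration=20.0)
        ds = simulate_dataset(10, archetypes, mix=(0.5, 0.5), seed=1, base_params=base,
                              pges_sampler=lambda rng: 8.0)
        assert len(ds) == 10
        tags = [d.archetype for d in ds]
        assert tags.count("a") == 5 and tags.count("b") == 5

    def test_single_archetype_mix(self):
        archetypes = [ArtifactArchetype("only", (0,), boxcar_envelope(0, 5, 50.0))]
        base = SimulationParams(duration=20.0)
        ds = simulate_dataset(4, archetypes, mix=(1.0,), seed=1, base_params=base,
                              pges_sampler=lambda rng: 8.0)
        assert all(d.archetype == "only" for d in ds)

    def test_disjoint_channel_archetypes_separate_in_band_power(self):
        """Mean artifact-band power over each channel group separates the
        two archetype tags with zero overlap (band-power oracle)."""
        g1, g2 = tuple(range(0, 8)), tuple(range(8, 16))
        archetypes = [
            ArtifactArchetype("left", g1, boxcar_envelope(5, 30, 150.0, 40), "movement"),
            ArtifactArchetype("right", g2, boxcar_envelope(5, 30, 150.0, 40), "movement"),
        ]
        base = SimulationParams(duration=40.0)
        ds = simulate_dataset(12, archetypes, seed=4, base_params=base,
                              pges_sampler=lambda rng: float(rng.uniform(8, 30)))
        scores = {"left": [], "right": []}
        for item in ds:
            p1 = np.mean([band_power(item.recording.samples[c], 200.0, 0.2, 5.0) for c in g1])
            p2 = np.mean([band_power(item.recording.samples[c], 200.0, 0.2, 5.0) for c in g2])
            scores[item.archetype].append(p1 - p2)
        assert min(scores["left"]) > 0 > max(scores["right"])

    def test_dataset_determinism(self):
        base = SimulationParams(duration=20.0)
        d1 = simulate_dataset(3, seed=6, base_params=base)
        d2 = simulate_dataset(3, seed=6, base_params=base)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.recording.samples, b.recording.samples)
            assert a.annotation.pges_end == b.annotation.pges_end

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_dataset(0)
        archetypes = [ArtifactArchetype("a", (0,), boxcar_envelope(0, 5, 10.0))]
        with pytest.raises(ValueError):
            simulate_dataset(5, archetypes, mix=(0.7, 0.7), seed=0)

    def test_no_pges_fraction(self):
        base = SimulationParams(duration=20.0)
        ds = simulate_dataset(12, seed=3, base_params=base, p_no_pges=0.5,
                              pges_sampler=lambda rng: 10.0)
        flags = [d.annotation.has_pges for d in ds]
        assert any(flags) and not all(flags)
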