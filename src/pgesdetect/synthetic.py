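"""Synthetic postictal EEG with known ground truth.

The clinical recordings the detector targets are not publicly available,
so every downstream stage is exercised on simulated postictal windows
that reproduce the structure the method relies on:

* a brief decaying seizure tail at the window start;
* a suppression interval with background attenuation well below the
  10 μV peak-to-peak criterion that defines PGES;
* resumption of activity at a known time, announced by intermittent slow
  waves (0.5–5 Hz bursts) over a restored background;
* optional artifact bursts — breathing-like slow rhythms, muscle-like
  broadband activity, movement-like transients — with configurable
  per-channel and per-time profiles, mimicking the spatiotemporal
  artifact patterns that make real PGES annotation hard.

Background EEG is modelled as 0.5–30 Hz band-limited Gaussian noise;
no claim of physiological realism is made beyond frequency content and
amplitude scale (μV).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import MONTAGE, Annotation, Recording

__all__ = [
    "SimulationParams",
    "ArtifactArchetype",
    "SimulatedRecording",
    "simulate_recording",
    "simulate_dataset",
    "boxcar_envelope",
]

ARTIFACT_KINDS = ("breathing", "muscle", "movement")


def boxcar_envelope(start: float, stop: float, amplitude: float, total: int = 300) -> np.ndarray:
    """Per-second intensity profile that is ``amplitude`` on [start, stop)."""
    env = np.zeros(total)
    env[int(start) : int(stop)] = amplitude
    return env


@dataclass
class ArtifactArchetype:
    """One spatiotemporal artifact pattern.

    ``time_envelope`` gives the artifact amplitude in μV for each second
    after seizure end (zero beyond its length); ``channel_mask`` lists the
    channel indices (0-based, canonical montage order) the artifact
    contaminates.  ``kind`` selects the waveform family:

    * ``breathing`` — 0.2–0.5 Hz high-amplitude rhythm;
    * ``muscle`` — 20–30 Hz noise bursts (inside the 0.5–30 Hz band);
    * ``movement`` — large smooth transient offsets.
    """

    name: str
    channel_mask: tuple[int, ...]
    time_envelope: np.ndarray
    kind: str = "movement"

    def __post_init__(self) -> None:
        self.channel_mask = tuple(int(c) for c in self.channel_mask)
        self.time_envelope = np.asarray(self.time_envelope, dtype=float)
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if np.any(self.time_envelope < 0):
            raise ValueError("artifact intensities must be ≥ 0")
        if any(c < 0 or c >= len(MONTAGE) for c in self.channel_mask):
            raise ValueError("channel_mask indices must be in [0, 18)")


@dataclass
class SimulationParams:
    """Knobs of one simulated postictal recording.

    Amplitudes are μV.  ``suppression_sigma`` defaults to 1 μV so the
    suppressed background stays comfortably below the 10 μV peak-to-peak
    attenuation criterion per 1-s epoch; ``background_sigma`` defaults to
    15 μV, restoring clearly non-suppressed activity.  ``pges_duration``
    of ``None`` simulates a recording without PGES (activity from t = 0).
    """

    n_channels: int = 18
    fs: float = 200.0
    duration: float = 300.0
    pges_duration: float | None = 40.0
    background_sigma: float = 15.0
    suppression_sigma: float = 1.0
    isw_rate: float = 0.5
    isw_band: tuple[float, float] = (0.5, 5.0)
    isw_amplitude: float = 60.0
    seizure_tail_duration: float = 2.0
    seizure_tail_amplitude: float = 80.0
    artifacts: tuple[ArtifactArchetype, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels != len(MONTAGE):
            raise ValueError("simulator produces the fixed 18-channel montage")
        lo, hi = self.isw_band
        if not (0.5 <= lo < hi <= 5.0):
            raise ValueError("isw_band must lie within 0.5–5 Hz")


@dataclass
class SimulatedRecording:
    """A simulated recording, its annotation, and its generating archetype.

    The archetype tag is hidden from the pipeline; it serves as ground
    truth when testing artifact clustering.
    """

    recording: Recording
    annotation: Annotation
    archetype: str | None = None


def _bandlimited_noise(rng, shape, fs, band=(0.5, 30.0)):
    noise = rng.standard_normal(shape)
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, noise, axis=-1)
    std = filtered.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return filtered / std


def _hann_burst(n_samples: int) -> np.ndarray:
    return np.hanning(n_samples)


def _isw_times(rng, start: float, stop: float, rate: float) -> list[float]:
    """Poisson arrivals on (start, stop); the first burst is at `start`."""
    times = [start]
    t = start
    while True:
        t += rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if t >= stop:
            break
        times.append(t)
    return times


def simulate_recording(
    params: SimulationParams, recording_id: str = "sim"
) -> tuple[Recording, Annotation]:
    """Generate one postictal recording and its ground-truth annotation."""
    if params.pges_duration is not None and params.pges_duration > params.duration:
        raise ValueError("pges_duration exceeds the recording duration")
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    n_ch = params.n_channels

    if params.pges_duration is None:
        pges_end = 0.0
        has_pges = False
    else:
        pges_end = float(params.pges_duration)
        has_pges = True

    # background: suppressed sigma before pges_end, restored after
    sigma = np.where(t < pges_end, params.suppression_sigma, params.background_sigma)
    samples = _bandlimited_noise(rng, (n_ch, n), fs) * sigma[None, :]

    # decaying seizure tail riding on the first seconds
    if params.seizure_tail_duration > 0 and params.seizure_tail_amplitude > 0:
        tail_n = min(n, int(round(params.seizure_tail_duration * fs)))
        decay = np.exp(-3.0 * np.arange(tail_n) / tail_n)
        tail = _bandlimited_noise(rng, (n_ch, tail_n), fs, band=(2.0, 30.0))
        samples[:, :tail_n] += params.seizure_tail_amplitude * decay * tail

    # intermittent slow waves from pges_end onward; first burst exactly there
    start = pges_end if has_pges else 0.0
    if params.isw_rate > 0:
        for burst_t in _isw_times(rng, start, params.duration, params.isw_rate):
            dur = rng.uniform(0.8, 1.6)
            freq = rng.uniform(*params.isw_band)
            phase = rng.uniform(0, 2 * np.pi)
            amp = params.isw_amplitude * rng.uniform(0.7, 1.3)
            i0 = int(round(burst_t * fs))
            i1 = min(n, i0 + int(round(dur * fs)))
            if i1 <= i0:
                continue
            tt = t[i0:i1] - burst_t
            wave = np.sin(2 * np.pi * freq * tt + phase) * _hann_burst(i1 - i0)
            gains = rng.uniform(0.8, 1.2, size=n_ch)
            samples[:, i0:i1] += amp * gains[:, None] * wave[None, :]

    for archetype in params.artifacts:
        samples += _render_artifact(rng, archetype, n_ch, n, fs)

    recording = Recording(
        id=recording_id, samples=samples, fs=fs, channel_labels=MONTAGE, t0=0.0
    )
    annotation = Annotation(
        recording_id=recording_id,
        seizure_end=0.0,
        has_pges=has_pges,
        pges_end=pges_end if has_pges else None,
    )
    return recording, annotation


def _render_artifact(rng, archetype: ArtifactArchetype, n_ch, n, fs) -> np.ndarray:
    """Waveform of one artifact archetype, full (channels × samples) array."""
    t = np.arange(n) / fs
    env_seconds = archetype.time_envelope
    sec_grid = np.arange(len(env_seconds), dtype=float)
    envelope = np.interp(t, sec_grid, env_seconds, left=0.0, right=0.0)
    out = np.zeros((n_ch, n))
    if not np.any(envelope > 0):
        return out

    if archetype.kind == "breathing":
        freq = rng.uniform(0.2, 0.5)
        phase = rng.uniform(0, 2 * np.pi)
        wave = envelope * np.sin(2 * np.pi * freq * t + phase)
    elif archetype.kind == "muscle":
        wave = envelope * _bandlimited_noise(rng, n, fs, band=(20.0, 30.0))
    else:  # movement: smooth large transients at random times inside the envelope
        wave = np.zeros(n)
        active = np.flatnonzero(envelope > 0)
        n_bumps = max(1, int(len(active) / fs * 0.5))
        for _ in range(n_bumps):
            center = rng.choice(active)
            dur = rng.uniform(1.0, 3.0)
            half = int(dur * fs / 2)
            i0, i1 = max(0, center - half), min(n, center + half)
            if i1 <= i0:
                continue
            bump = _hann_burst(i1 - i0) * rng.choice([-1.0, 1.0])
            wave[i0:i1] += envelope[center] * bump

    gains = rng.uniform(0.8, 1.2, size=n_ch)
    for c in archetype.channel_mask:
        out[c] = gains[c] * wave
    return out


def _stratified_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n recordings to archetypes."""
    mix = np.asarray(mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-6:
        raise ValueError("mix proportions must sum to 1")
    raw = n * mix
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def default_pges_sampler(rng: np.random.Generator) -> float:
    """Lognormal PGES duration, median ≈ 40 s, clipped to [5, 240] s."""
    return float(np.clip(rng.lognormal(mean=np.log(40.0), sigma=0.5), 5.0, 240.0))


def simulate_dataset(
    n: int,
    archetypes: Sequence[ArtifactArchetype] = (),
    mix: Sequence[float] | None = None,
    seed: int = 0,
    base_params: SimulationParams | None = None,
    pges_sampler: Callable[[np.random.Generator], float] | None = None,
    p_no_pges: float = 0.0,
) -> list[SimulatedRecording]:
    """Generate a dataset of postictal recordings with known ground truth.

    Each recording is assigned one artifact archetype (deterministic
    stratified assignment by ``mix``, largest-remainder rounding) and a
    PGES duration drawn from ``pges_sampler`` (default: lognormal with
    median ≈ 40 s).  A fraction ``p_no_pges`` of recordings is generated
    without suppression.  With no archetypes the dataset is artifact-free.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    base = base_params or SimulationParams()
    sampler = pges_sampler or default_pges_sampler

    if archetypes:
        if mix is None:
            mix = [1.0 / len(archetypes)] * len(archetypes)
        if len(mix) != len(archetypes):
            raise ValueError("mix length must match archetypes")
        counts = _stratified_counts(n, mix)
        tags: list[int | None] = []
        for i, c in enumerate(counts):
            tags.extend([i] * c)
    else:
        tags = [None] * n

    master = np.random.SeedSequence(seed)
    children = master.spawn(n)
    out = []
    draw_rng = np.random.default_rng(master.spawn(1)[0])
    for i in range(n):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        no_pges = draw_rng.uniform() < p_no_pges
        pges = None if no_pges else min(sampler(draw_rng), base.duration * 0.9)
        tag = tags[i]
        arts = (archetypes[tag],) if tag is not None else ()
        params = replace(
            base, pges_duration=pges, artifacts=arts, seed=child_seed
        )
        rid = f"sim{i:03d}"
        recording, annotation = simulate_recording(params, recording_id=rid)
        out.append(
            SimulatedRecording(
                recording=recording,
                annotation=annotation,
                archetype=archetypes[tag].name if tag is not None else None,
            )
        )
    return out
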