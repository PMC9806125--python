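"""Postictal window extraction, band-pass filtering, 1-second epoching.

Two pass bands are used downstream: 0.5–30 Hz for the EMD/Hilbert
features and 0.5–5 Hz for everything else (the intermittent slow waves
that mark the end of suppression live below 5 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import Annotation, Recording

__all__ = ["EpochedSignal", "extract_postictal", "bandpass", "epoch"]

#: Default postictal analysis window, seconds.
POSTICTAL_DURATION = 300.0
EMD_BAND = (0.5, 30.0)
BASELINE_BAND = (0.5, 5.0)


@dataclass
class EpochedSignal:
    """Non-overlapping 1-second epochs of a filtered recording.

    ``epochs`` has shape (n_channels, n_epochs, samples_per_epoch); epoch
    ``i`` covers the half-open interval [i, i+1) seconds after seizure
    end.  A trailing partial second is discarded.
    """

    epochs: np.ndarray
    fs: float
    band: tuple[float, float] | None = None
    epoch_length: float = 1.0

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[1]


def extract_postictal(
    recording: Recording,
    annotation: Annotation,
    duration: float = POSTICTAL_DURATION,
) -> Recording:
    """Cut the postictal analysis window from a source-file recording.

    ``annotation.seizure_end`` is in source-file seconds (relative to the
    recording's ``t0``).  The returned window starts at seizure end
    (``t0 = 0``) and spans up to ``duration`` seconds; when the file ends
    earlier the window is truncated with a warning.
    """
    offset = annotation.seizure_end - recording.t0
    start = int(round(offset * recording.fs))
    if start < 0 or start >= recording.n_samples:
        raise ValueError(
            f"seizure end at {annotation.seizure_end} s lies outside the "
            f"recording ({recording.duration:.1f} s from t0={recording.t0})"
        )
    stop = start + int(round(duration * recording.fs))
    if stop > recording.n_samples:
        got = (recording.n_samples - start) / recording.fs
        warnings.warn(
            f"recording {recording.id!r}: only {got:.1f} s follow seizure "
            f"end (requested {duration:.0f} s); truncating",
            stacklevel=2,
        )
        stop = recording.n_samples
    return recording.copy_with(samples=recording.samples[:, start:stop], t0=0.0)


def bandpass(recording: Recording, low: float, high: float) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass.

    Applied forward-backward (so epoch timing is not shifted) with
    reflective padding against edge transients.
    """
    nyq = recording.fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={recording.fs}")
    sos = butter(4, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    padlen = min(recording.n_samples - 1, int(3 * recording.fs))
    filtered = sosfiltfilt(
        sos, recording.samples, axis=1, padtype="even", padlen=padlen
    )
    return recording.copy_with(samples=filtered)


def epoch(recording: Recording, band: tuple[float, float] | None = None) -> EpochedSignal:
    """Split into non-overlapping 1-second epochs (trailing partial dropped)."""
    spe = int(round(recording.fs))
    n_epochs = recording.n_samples // spe
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    trimmed = recording.samples[:, : n_epochs * spe]
    epochs = trimmed.reshape(recording.n_channels, n_epochs, spe)
    return EpochedSignal(epochs=epochs, fs=recording.fs, band=band)
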