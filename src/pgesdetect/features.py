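"""Per-epoch feature bank: time-domain, spectral, wavelet, inter-channel
correlation, and the EMD/Hilbert epoch feature.

Baseline features are computed on the 0.5–5 Hz filtered signal — the
band where intermittent slow waves (and the artifacts that mimic them)
live — while the Hilbert-spectrum feature uses the 0.5–30 Hz signal.
Frequency bands above 5 Hz are deliberately absent: on a 0.5–5 Hz
filtered epoch they would only measure filter stop-band leakage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.signal import periodogram
from scipy.stats import kurtosis as _kurtosis, skew as _skew

from .emd import hht_epoch_feature
from .io import MONTAGE, Annotation, Recording
from .preprocess import BASELINE_BAND, EMD_BAND, bandpass, epoch

__all__ = [
    "EpochFeatureMatrix",
    "time_features",
    "band_powers",
    "wavelet_features",
    "channel_correlations",
    "build_feature_matrix",
]

TIME_FEATURE_NAMES = ("mean", "kurtosis", "skewness", "activity", "mobility", "complexity")
BANDS = {"slow": (0.5, 1.0), "delta": (1.0, 4.0), "upper": (4.0, 5.0)}
WAVELET = "db4"
# 3 levels keep the periodized transform orthogonal on 200-sample epochs
# (a 4th level would halve an odd-length array and break energy conservation)
WAVELET_LEVELS = 3
SUPPRESSION = 1  #: positive class: epoch inside the suppression interval
NON_SUPPRESSION = 0

#: canonical channel-pair order for the 153 correlation features
CHANNEL_PAIRS = tuple(itertools.combinations(range(len(MONTAGE)), 2))


def time_features(epoch_samples: np.ndarray) -> np.ndarray:
    """Statistical moments and Hjorth parameters, per channel.

    Returns (n_channels, 6): mean, excess kurtosis, skewness, Hjorth
    activity (variance), mobility sqrt(var(Δx)/var(x)) and complexity
    mobility(Δx)/mobility(x).  Zero-variance channels score 0 for the
    moment ratios and both derived Hjorth parameters.
    """
    x = np.atleast_2d(np.asarray(epoch_samples, dtype=float))
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant epochs trigger scipy's catastrophic-cancellation warning;
        # their moments are imputed to 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = _kurtosis(x, axis=1, fisher=True, bias=True)
        skw = _skew(x, axis=1, bias=True)
    kurt = np.nan_to_num(kurt)
    skw = np.nan_to_num(skw)

    dx = np.diff(x, axis=1)
    ddx = np.diff(dx, axis=1)
    var_dx = dx.var(axis=1)
    var_ddx = ddx.var(axis=1)
    mobility = np.zeros_like(var)
    complexity = np.zeros_like(var)
    ok = var > 0
    mobility[ok] = np.sqrt(var_dx[ok] / var[ok])
    ok2 = ok & (var_dx > 0)
    complexity[ok2] = np.sqrt(var_ddx[ok2] / var_dx[ok2]) / mobility[ok2]
    return np.column_stack([mean, kurt, skw, var, mobility, complexity])


def band_powers(epoch_samples: np.ndarray, fs: float) -> np.ndarray:
    """Periodogram power per channel in the slow (0.5–1 Hz), delta
    (1–4 Hz) and upper (4–5 Hz) bands.

    Band membership is lo < f ≤ hi, so adjacent bands never share a bin.
    Returns (n_channels, 3).
    """
    x = np.atleast_2d(np.asarray(epoch_samples, dtype=float))
    freqs, pxx = periodogram(x, fs=fs, axis=1)
    out = np.empty((x.shape[0], len(BANDS)))
    for j, (lo, hi) in enumerate(BANDS.values()):
        mask = (freqs > lo) & (freqs <= hi)
        out[:, j] = pxx[:, mask].sum(axis=1)
    return out


def wavelet_features(epoch_samples: np.ndarray) -> np.ndarray:
    """Energy per discrete-wavelet level (Daubechies-4, 3 levels).

    Periodized transform, so total coefficient energy equals signal
    energy.  Returns (n_channels, 4): approximation energy then detail
    energies from coarsest to finest.
    """
    x = np.atleast_2d(np.asarray(epoch_samples, dtype=float))
    coeffs = pywt.wavedec(x, WAVELET, level=WAVELET_LEVELS, mode="periodization", axis=1)
    return np.column_stack([(c**2).sum(axis=1) for c in coeffs])


def channel_correlations(epoch_samples: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of the 18 channels (153 values).

    Pairs follow the canonical (i, j), i < j order; pairs involving a
    zero-variance channel score 0.
    """
    x = np.asarray(epoch_samples, dtype=float)
    if x.shape[0] != len(MONTAGE):
        raise ValueError("channel_correlations expects the 18-channel epoch")
    ok = (x.max(axis=1) - x.min(axis=1)) > 0  # exact constant-channel guard
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    out = np.empty(len(CHANNEL_PAIRS))
    for k, (i, j) in enumerate(CHANNEL_PAIRS):
        out[k] = r[i, j] if ok[i] and ok[j] else 0.0
    return np.nan_to_num(out)


@dataclass
class EpochFeatureMatrix:
    """One row per (recording, epoch); named feature columns plus labels.

    ``frame`` carries metadata columns ``recording_id``, ``epoch_index``
    and ``label`` (1 = suppression, 0 = non-suppression) followed by the
    feature columns in stable order.
    """

    frame: pd.DataFrame

    META_COLUMNS = ("recording_id", "epoch_index", "label")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.META_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def for_recording(self, recording_id: str) -> "EpochFeatureMatrix":
        sub = self.frame[self.frame["recording_id"] == recording_id]
        return EpochFeatureMatrix(sub.reset_index(drop=True))

    def without_recording(self, recording_id: str) -> "EpochFeatureMatrix":
        sub = self.frame[self.frame["recording_id"] != recording_id]
        return EpochFeatureMatrix(sub.reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def concat(cls, parts: list["EpochFeatureMatrix"]) -> "EpochFeatureMatrix":
        return cls(pd.concat([p.frame for p in parts], ignore_index=True))


def _feature_column_names() -> list[str]:
    names = []
    for ch in MONTAGE:
        for f in TIME_FEATURE_NAMES:
            names.append(f"{ch}:{f}")
        for b in BANDS:
            names.append(f"{ch}:power_{b}")
        names.append(f"{ch}:wavelet_a{WAVELET_LEVELS}")
        for lvl in range(WAVELET_LEVELS, 0, -1):
            names.append(f"{ch}:wavelet_d{lvl}")
        names.append(f"{ch}:hht")
    for i, j in CHANNEL_PAIRS:
        names.append(f"corr:{MONTAGE[i]}|{MONTAGE[j]}")
    return names


def build_feature_matrix(
    recording: Recording,
    annotation: Annotation | None = None,
    emd_band: tuple[float, float] = EMD_BAND,
    baseline_band: tuple[float, float] = BASELINE_BAND,
) -> EpochFeatureMatrix:
    """Assemble the full per-epoch feature matrix for one recording.

    The recording must already be the postictal window (t0 = 0).  Epoch
    ``i`` is labelled suppression iff its start time lies before the
    annotated first-ISW time; recordings without PGES have every epoch
    labelled non-suppression.  Passing no annotation labels everything
    non-suppression (prediction-time use).
    """
    low_rec = bandpass(recording, *baseline_band)
    emd_rec = bandpass(recording, *emd_band)
    low = epoch(low_rec, band=baseline_band)
    wide = epoch(emd_rec, band=emd_band)
    n_epochs = low.n_epochs
    fs = recording.fs

    rows = np.empty((n_epochs, len(_feature_column_names())))
    for e in range(n_epochs):
        le = low.epochs[:, e, :]
        we = wide.epochs[:, e, :]
        tf = time_features(le)
        bp = band_powers(le, fs)
        wf = wavelet_features(le)
        hht = hht_epoch_feature(we, fs)
        per_channel = np.hstack([tf, bp, wf, hht[:, None]])
        rows[e] = np.concatenate([per_channel.ravel(), channel_correlations(le)])

    pges_end = None
    if annotation is not None and annotation.pges_end is not None and annotation.has_pges:
        pges_end = annotation.pges_end
    labels = np.full(n_epochs, NON_SUPPRESSION, dtype=int)
    if pges_end is not None:
        starts = np.arange(n_epochs, dtype=float)
        labels[starts < pges_end] = SUPPRESSION

    frame = pd.DataFrame(rows, columns=_feature_column_names())
    frame.insert(0, "label", labels)
    frame.insert(0, "epoch_index", np.arange(n_epochs))
    frame.insert(0, "recording_id", recording.id)
    frame[frame.columns[3:]] = frame[frame.columns[3:]].fillna(0.0)
    return EpochFeatureMatrix(frame)
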