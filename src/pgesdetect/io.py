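"""Recording / annotation containers and EDF + CSV input-output.

The pipeline operates on the fixed 18-channel longitudinal bipolar montage
(double banana) sampled at 200 Hz.  Amplitudes are microvolts everywhere:
the suppression criterion that defines PGES (background attenuation below
10 μV) is stated in μV, so no other unit ever appears.

Times follow two conventions:

* annotation ``seizure_end`` is in source-file seconds;
* every other time (``pges_end``, predicted end times, epoch indices) is in
  seconds relative to the end of the seizure, with 0 = seizure end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONTAGE",
    "Recording",
    "Annotation",
    "read_recording",
    "write_recording_edf",
    "read_annotations",
    "write_annotations",
]

#: Canonical 18-channel longitudinal bipolar montage, in fixed order.
MONTAGE: tuple[str, ...] = (
    "Fp1-F7", "F7-T7", "T7-P7", "P7-O1",
    "Fp2-F8", "F8-T8", "T8-P8", "P8-O2",
    "Fp1-F3", "F3-C3", "C3-P3", "P3-O1",
    "Fp2-F4", "F4-C4", "C4-P4", "P4-O2",
    "Fz-Cz", "Cz-Pz",
)

TARGET_FS = 200.0  #: Hz; recordings read at any other rate are resampled.


@dataclass
class Recording:
    """Multi-channel EEG window.

    Parameters
    ----------
    id : str
        Recording identifier, used to join with annotations.
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in μV, channel-major, canonical montage order.
    fs : float
        Sampling frequency in Hz.
    channel_labels : tuple of str
        Must equal :data:`MONTAGE`.
    t0 : float
        Time of the first sample in seconds; 0 means "at seizure end".
    """

    id: str
    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels × time) array")
        if self.channel_labels != MONTAGE:
            raise ValueError(
                "channel_labels must be the canonical 18-channel bipolar "
                f"montage; got {self.channel_labels!r}"
            )
        if self.samples.shape[0] != len(MONTAGE):
            raise ValueError(
                f"expected {len(MONTAGE)} channels, got {self.samples.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Window length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass
class Annotation:
    """Expert ground truth for one recording.

    ``pges_end`` is the time of the first intermittent slow wave, i.e. the
    actual end of suppression, in seconds after seizure end.  It may be
    present without ``has_pges`` (an ISW time annotated on a recording
    judged not to show generalized suppression), but ``has_pges`` implies
    its presence.
    """

    recording_id: str
    seizure_end: float
    has_pges: bool
    pges_end: float | None = None

    def __post_init__(self) -> None:
        if self.has_pges and self.pges_end is None:
            raise ValueError(
                f"recording {self.recording_id!r}: has_pges is true but "
                "pges_end is missing"
            )
        if self.pges_end is not None and self.pges_end < 0:
            raise ValueError(
                f"recording {self.recording_id!r}: pges_end must be ≥ 0"
            )


# ---------------------------------------------------------------------------
# EDF reading (via mne) with bipolar derivation
# ---------------------------------------------------------------------------

_EEG_PREFIX = re.compile(r"^EEG[ _]*", re.IGNORECASE)


def _normalize_label(label: str) -> str:
    return _EEG_PREFIX.sub("", label.strip()).lower()


def read_recording(
    path: str | Path,
    montage: Sequence[str] = MONTAGE,
    recording_id: str | None = None,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    The file may store either the 18 bipolar channels directly or
    referential electrodes; in the latter case each bipolar pair X-Y is
    derived as X − Y.  Channels are returned in canonical montage order and
    resampled to 200 Hz when the file uses a different rate.

    Raises
    ------
    ValueError
        If a required bipolar channel can neither be found nor derived; the
        message names the missing bipolar label.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns Volts for EEG; we want μV
    fs = float(raw.info["sfreq"])
    by_label = {_normalize_label(name): data[i] for i, name in enumerate(raw.ch_names)}

    rows = []
    missing = []
    for bipolar in montage:
        key = _normalize_label(bipolar)
        if key in by_label:
            rows.append(by_label[key])
            continue
        anode, cathode = bipolar.split("-")
        a, c = _normalize_label(anode), _normalize_label(cathode)
        if a in by_label and c in by_label:
            rows.append(by_label[a] - by_label[c])
        else:
            missing.append(bipolar)
    if missing:
        raise ValueError(
            "cannot construct channels (absent and referential electrodes "
            f"missing): {', '.join(missing)}"
        )
    samples = np.vstack(rows)

    if fs != TARGET_FS:
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(TARGET_FS / fs).limit_denominator(1000)
        samples = resample_poly(samples, frac.numerator, frac.denominator, axis=1)
        fs = TARGET_FS

    return Recording(
        id=recording_id or path.stem,
        samples=samples,
        fs=fs,
        channel_labels=tuple(montage),
    )


# ---------------------------------------------------------------------------
# Minimal EDF writer (16-bit, 1-second data records)
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` to a plain EDF file.

    Signals are stored as 16-bit integers with per-channel physical
    scaling (physical dimension ``uV``), one-second data records.  A
    trailing partial second is zero-padded.  Round-tripping through
    :func:`read_recording` reproduces samples to the 16-bit quantization
    of the channel's amplitude range.
    """
    return _write_edf(
        recording.samples, recording.channel_labels, recording.fs, path, recording.id
    )


def _write_edf(
    samples: np.ndarray,
    labels: Sequence[str],
    fs: float,
    path: str | Path,
    patient_id: str = "anon",
) -> Path:
    """EDF writer over raw arrays (any labels, e.g. referential electrodes)."""
    path = Path(path)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = int(np.ceil(samples.shape[1] / spr))
    n_sig = samples.shape[0]

    padded = np.zeros((n_sig, n_records * spr))
    padded[:, : samples.shape[1]] = samples

    # physical range per channel; degenerate (constant) channels get a ±1 span
    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(patient_id, 80),
            _ascii_field("Startdate 01-JAN-2000", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_sig), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(n_sig, 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_ascii_field(lbl, 16) for lbl in labels),
            b"".join(_ascii_field("", 80) for _ in range(n_sig)),
            b"".join(_ascii_field("uV", 8) for _ in range(n_sig)),
            b"".join(_ascii_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_sig)),
            b"".join(_ascii_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_sig)),
            b"".join(_ascii_field(dig_min, 8) for _ in range(n_sig)),
            b"".join(_ascii_field(dig_max, 8) for _ in range(n_sig)),
            b"".join(_ascii_field("", 80) for _ in range(n_sig)),
            b"".join(_ascii_field(spr, 8) for _ in range(n_sig)),
            b"".join(_ascii_field("", 32) for _ in range(n_sig)),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        # records are channel-blocked within each second
        for rec in range(n_records):
            block = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(block.tobytes())
    return path


# ---------------------------------------------------------------------------
# Annotation tables (CSV)
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["recording_id", "seizure_end", "has_pges", "pges_end"]


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read an annotation CSV.

    Expected header: ``recording_id,seizure_end,has_pges,pges_end`` with
    ``pges_end`` in seconds after seizure end (decimal allowed, empty when
    unannotated).  A row with ``has_pges`` true and no ``pges_end`` is a
    validation error naming the row.
    """
    df = pd.read_csv(path)
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table is missing columns: {sorted(missing)}")
    annotations = []
    for _, row in df.iterrows():
        has_pges = _parse_bool(row["has_pges"])
        pges_end = row["pges_end"]
        pges_end = None if pd.isna(pges_end) else float(pges_end)
        annotations.append(
            Annotation(
                recording_id=str(row["recording_id"]),
                seizure_end=float(row["seizure_end"]),
                has_pges=has_pges,
                pges_end=pges_end,
            )
        )
    return annotations


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "recording_id": [a.recording_id for a in annotations],
            "seizure_end": [a.seizure_end for a in annotations],
            "has_pges": [a.has_pges for a in annotations],
            "pges_end": [a.pges_end for a in annotations],
        }
    )
    df.to_csv(path, index=False)
    return path


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"cannot parse boolean annotation value {value!r}")
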