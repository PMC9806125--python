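"""Empirical mode decomposition, Hilbert spectral analysis, and the
EMD-derived features used by the detector.

The decomposition writes a signal x(t) as a sum of intrinsic mode
functions plus a residual trend,

    x(t) = Σ_i IMF_i(t) + r_N(t),

where an IMF (i) has extrema and zero-crossing counts equal or differing
by one and (ii) has a near-zero mean of its upper and lower extremal
envelopes.  Each IMF is extracted by *sifting*: subtract the mean of the
cubic-spline envelopes through the local maxima and minima, and repeat on
the result until the IMF requirements hold.  Modes come out ordered from
highest to lowest dominant frequency.

Two features are built on top:

* a per-epoch scalar per channel — the summed Hilbert-spectrum amplitude
  of all modes over the 1-second epoch (used for classification);
* a whole-recording channel × seconds *artifact feature map* — Hilbert
  amplitude accumulated only where the instantaneous frequency falls in
  the 0.5–5 Hz band, which is where breathing/movement artifacts and
  intermittent slow waves compete (used for clustering recordings).

The sifting inner loop is numba-compiled: the detector decomposes every
1-second epoch of every channel, some 10^5 small decompositions per
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import decimate, hilbert

from .io import MONTAGE, Recording

__all__ = [
    "IMFDecomposition",
    "ArtifactFeatureMap",
    "sift_one",
    "emd",
    "is_imf",
    "hilbert_analytic",
    "hht_epoch_feature",
    "artifact_feature_map",
]

#: Cauchy sifting-convergence threshold  Σ(y_prev − y)² / Σ y_prev².
SD_THRESHOLD = 0.2
#: Hard cap on sifting iterations per mode.
MAX_SIFT_ITER = 50
#: Envelope-mean tolerance for the IMF test, as a fraction of signal RMS.
ENV_TOLERANCE = 0.05
#: Default cap on the number of extracted modes.
MAX_MODES = 10


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _extrema(x):
    """Interior local maxima and minima indices (plateau edges count once)."""
    n = x.shape[0]
    maxima = np.empty(n, np.int64)
    minima = np.empty(n, np.int64)
    nmax = 0
    nmin = 0
    for i in range(1, n - 1):
        dl = x[i] - x[i - 1]
        dr = x[i + 1] - x[i]
        if dl > 0.0 and dr <= 0.0:
            maxima[nmax] = i
            nmax += 1
        elif dl < 0.0 and dr >= 0.0:
            minima[nmin] = i
            nmin += 1
    return maxima[:nmax], minima[:nmin]


@njit(cache=True)
def _zero_crossings(x):
    n = x.shape[0]
    count = 0
    prev = 0.0
    for i in range(n):
        v = x[i]
        if v != 0.0:
            if prev != 0.0 and (v > 0.0) != (prev > 0.0):
                count += 1
            prev = v
    return count


@njit(cache=True)
def _spline_eval(xk, yk, n):
    """Natural cubic spline through (xk, yk) evaluated at 0..n-1.

    Knot abscissae are strictly increasing sample coordinates that may
    extend beyond [0, n-1] (mirrored boundary extrema).  Falls back to a
    line for two knots and a constant for one.
    """
    k = xk.shape[0]
    out = np.empty(n)
    if k == 1:
        for q in range(n):
            out[q] = yk[0]
        return out
    if k == 2:
        slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
        for q in range(n):
            out[q] = yk[0] + slope * (q - xk[0])
        return out

    # second derivatives via the Thomas algorithm, natural BCs (M0 = Mk-1 = 0)
    h = np.empty(k - 1)
    for i in range(k - 1):
        h[i] = xk[i + 1] - xk[i]
    m = k - 2  # interior unknowns
    diag = np.empty(m)
    upper = np.empty(m)
    lower = np.empty(m)
    rhs = np.empty(m)
    for i in range(m):
        diag[i] = 2.0 * (h[i] + h[i + 1])
        upper[i] = h[i + 1]
        lower[i] = h[i]
        rhs[i] = 6.0 * ((yk[i + 2] - yk[i + 1]) / h[i + 1] - (yk[i + 1] - yk[i]) / h[i])
    for i in range(1, m):
        w = lower[i] / diag[i - 1]
        diag[i] -= w * upper[i - 1]
        rhs[i] -= w * rhs[i - 1]
    M = np.zeros(k)
    if m > 0:
        M[m] = rhs[m - 1] / diag[m - 1]
        for i in range(m - 2, -1, -1):
            M[i + 1] = (rhs[i] - upper[i] * M[i + 2]) / diag[i]

    seg = 0
    for q in range(n):
        t = float(q)
        while seg < k - 2 and t > xk[seg + 1]:
            seg += 1
        hs = h[seg]
        a = xk[seg + 1] - t
        b = t - xk[seg]
        out[q] = (
            M[seg] * a * a * a / (6.0 * hs)
            + M[seg + 1] * b * b * b / (6.0 * hs)
            + (yk[seg] / hs - M[seg] * hs / 6.0) * a
            + (yk[seg + 1] / hs - M[seg + 1] * hs / 6.0) * b
        )
    return out


@njit(cache=True)
def _envelope_knots(idx, x, n):
    """Knot coordinates/values for one envelope with mirrored boundaries.

    Mirrors up to two extrema about each end of the signal; when fewer
    than two extrema exist on a side the signal endpoints are added as
    knots instead, so an envelope is defined whenever ≥1 extremum exists.
    """
    k = idx.shape[0]
    last = n - 1
    xs = np.empty(k + 4)
    ys = np.empty(k + 4)
    cnt = 0
    if k >= 2:
        xs[cnt] = -float(idx[1]); ys[cnt] = x[idx[1]]; cnt += 1
        xs[cnt] = -float(idx[0]); ys[cnt] = x[idx[0]]; cnt += 1
    else:
        xs[cnt] = -float(last); ys[cnt] = x[0]; cnt += 1
        xs[cnt] = 0.0; ys[cnt] = x[0]; cnt += 1
    for i in range(k):
        xs[cnt] = float(idx[i]); ys[cnt] = x[idx[i]]; cnt += 1
    if k >= 2:
        xs[cnt] = 2.0 * last - idx[k - 1]; ys[cnt] = x[idx[k - 1]]; cnt += 1
        xs[cnt] = 2.0 * last - idx[k - 2]; ys[cnt] = x[idx[k - 2]]; cnt += 1
    else:
        xs[cnt] = float(last); ys[cnt] = x[last]; cnt += 1
        xs[cnt] = 2.0 * last; ys[cnt] = x[last]; cnt += 1
    # keep strictly increasing knots (duplicates arise when an extremum
    # coincides with an endpoint mirror image)
    keep_x = np.empty(cnt)
    keep_y = np.empty(cnt)
    kk = 0
    for i in range(cnt):
        if kk == 0 or xs[i] > keep_x[kk - 1] + 1e-9:
            keep_x[kk] = xs[i]
            keep_y[kk] = ys[i]
            kk += 1
    return keep_x[:kk], keep_y[:kk]


@njit(cache=True)
def _envelope_mean(x):
    """Mean of the upper/lower extremal envelopes; (mean, n_max, n_min)."""
    n = x.shape[0]
    maxima, minima = _extrema(x)
    if maxima.shape[0] == 0 or minima.shape[0] == 0:
        return np.zeros(n), maxima.shape[0], minima.shape[0]
    ux, uy = _envelope_knots(maxima, x, n)
    lx, ly = _envelope_knots(minima, x, n)
    upper = _spline_eval(ux, uy, n)
    lower = _spline_eval(lx, ly, n)
    return 0.5 * (upper + lower), maxima.shape[0], minima.shape[0]


@njit(cache=True)
def _count_rule_ok(x):
    maxima, minima = _extrema(x)
    n_ext = maxima.shape[0] + minima.shape[0]
    n_zc = _zero_crossings(x)
    d = n_ext - n_zc
    return -1 <= d <= 1


@njit(cache=True)
def _sift_kernel(x, sd_thresh, max_iter, env_tol):
    """One complete sifting pass; returns the candidate IMF.

    Stops as soon as the current iterate satisfies both IMF requirements
    (count rule; envelope mean within env_tol × RMS), or at the iteration
    cap.  The envelope mean of noisy modes can plateau above the
    tolerance while the count rule flips between iterates; the last
    iterate satisfying the count rule is remembered and returned at the
    cap so every extracted mode obeys the countable IMF requirement.
    """
    y = x.copy()
    best = x.copy()
    have_best = False
    for _ in range(max_iter):
        m, nmax, nmin = _envelope_mean(y)
        if nmax == 0 or nmin == 0 or nmax + nmin < 2:
            break
        denom = np.sum(y * y)
        if denom <= 0.0:
            break
        rms = np.sqrt(denom / y.shape[0])
        if _count_rule_ok(y):
            best = y.copy()
            have_best = True
            if np.mean(np.abs(m)) <= env_tol * rms:
                return best
        sd = np.sum(m * m) / denom
        y = y - m
        if sd < 1e-4 * sd_thresh:
            break  # envelope mean numerically stagnant
    if have_best:
        return best
    # rare: no iterate satisfied the count rule within the cap (boundary
    # riding waves decay slowly); extend sifting until the first one does
    for _ in range(3 * max_iter):
        if _count_rule_ok(y):
            return y
        m, nmax, nmin = _envelope_mean(y)
        if nmax == 0 or nmin == 0 or nmax + nmin < 2:
            break
        y = y - m
    return y


@njit(cache=True)
def _emd_kernel(x, max_modes, sd_thresh, max_iter, env_tol):
    """Full decomposition; returns (modes array, residual, n_modes)."""
    n = x.shape[0]
    modes = np.empty((max_modes, n))
    residual = x.copy()
    n_modes = 0
    for _ in range(max_modes):
        maxima, minima = _extrema(residual)
        if (
            maxima.shape[0] == 0
            or minima.shape[0] == 0
            or maxima.shape[0] + minima.shape[0] < 2
        ):
            break
        imf = _sift_kernel(residual, sd_thresh, max_iter, env_tol)
        if np.all(imf == 0.0):
            break
        modes[n_modes] = imf
        residual = residual - imf
        n_modes += 1
    return modes[:n_modes], residual, n_modes


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class IMFDecomposition:
    """Ordered intrinsic mode functions plus the monotone residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def sift_one(
    signal: np.ndarray,
    sd_thresh: float = SD_THRESHOLD,
    max_iter: int = MAX_SIFT_ITER,
) -> np.ndarray:
    """Extract one candidate IMF from ``signal`` by envelope-mean sifting.

    Raises
    ------
    ValueError
        "no IMF extractable" when the signal has fewer than two maxima or
        fewer than two minima (e.g. a monotone ramp).
    """
    x = np.ascontiguousarray(signal, dtype=float)
    maxima, minima = _extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        raise ValueError("no IMF extractable: fewer than 2 maxima/minima")
    return _sift_kernel(x, sd_thresh, max_iter, ENV_TOLERANCE)


def emd(
    signal: np.ndarray,
    max_modes: int = MAX_MODES,
    sd_thresh: float = SD_THRESHOLD,
    max_iter: int = MAX_SIFT_ITER,
) -> IMFDecomposition:
    """Decompose ``signal`` into IMFs and a residual trend.

    Sifting repeats on successive residuals until the residual is
    monotone (fewer than two interior extrema) or ``max_modes`` is
    reached.  Degenerate inputs (constant, monotone) yield zero modes
    with residual equal to the input.  By construction
    ``sum(imfs) + residual == signal`` to floating-point round-off.
    """
    x = np.ascontiguousarray(signal, dtype=float)
    modes, residual, n_modes = _emd_kernel(x, max_modes, sd_thresh, max_iter, ENV_TOLERANCE)
    return IMFDecomposition(imfs=[modes[i] for i in range(n_modes)], residual=residual)


def is_imf(signal: np.ndarray, env_tol: float = ENV_TOLERANCE) -> bool:
    """Check the two IMF requirements.

    (1) numbers of local extrema and zero-crossings equal or differing by
    at most one; (2) the mean of the extremal envelopes is near zero —
    here mean absolute envelope mean ≤ ``env_tol`` × RMS of the signal.
    """
    x = np.ascontiguousarray(signal, dtype=float)
    if not _count_rule_ok(x):
        return False
    m, n_max, n_min = _envelope_mean(x)
    if n_max == 0 or n_min == 0:
        # no oscillation: the signal is its own (degenerate) envelope, so
        # the envelope-mean requirement reduces to the signal being ~0
        m = x
    rms = float(np.sqrt(np.mean(x * x)))
    return float(np.mean(np.abs(m))) <= env_tol * rms


def hilbert_analytic(imf: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude and frequency of one mode.

    Amplitude is the modulus of the analytic signal; frequency is the
    time derivative of the unwrapped phase over 2π, clipped to
    [0, fs/2].  Both are per-sample arrays the length of the input.
    """
    analytic = hilbert(np.asarray(imf, dtype=float))
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase) * fs / (2.0 * np.pi)
    return amplitude, np.clip(freq, 0.0, fs / 2.0)


def hht_epoch_feature(epoch: np.ndarray, fs: float, max_modes: int = MAX_MODES) -> np.ndarray:
    """Summed Hilbert-spectrum amplitude of one 1-s epoch, per channel.

    ``epoch`` is (n_channels, n_samples) from the 0.5–30 Hz filtered
    signal.  For each channel the epoch is decomposed and the Hilbert
    amplitude of every mode is summed over modes and samples.  Epochs
    yielding no modes score 0.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    out = np.zeros(epoch.shape[0])
    for c in range(epoch.shape[0]):
        decomp = emd(epoch[c], max_modes=max_modes)
        if not decomp.imfs:
            continue
        # one analytic-signal FFT over the stacked modes
        analytic = hilbert(np.vstack(decomp.imfs), axis=1)
        out[c] = float(np.sum(np.abs(analytic)))
    return out


@dataclass
class ArtifactFeatureMap:
    """Channel × seconds map of low-frequency (0.5–5 Hz) Hilbert amplitude.

    Summarizes where in time and on which channels slow high-amplitude
    activity — the artifact classes that mimic intermittent slow waves —
    occurred over the whole postictal window.  Values are normalized per
    recording by the map's 95th percentile so clustering compares
    spatiotemporal patterns, not absolute gain.
    """

    values: np.ndarray  # (18, T), ≥ 0
    recording_id: str = ""
    padded: bool = False  # recording shorter than T; tail is zero

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(MONTAGE):
            raise ValueError("artifact feature map must be (18, T)")
        if np.any(self.values < 0):
            raise ValueError("artifact feature map values must be ≥ 0")

    def flatten(self) -> np.ndarray:
        return self.values.ravel()


def artifact_feature_map(
    recording: Recording,
    T: int = 300,
    band: tuple[float, float] = (0.5, 5.0),
    fs_map: float = 20.0,
    normalize: bool = True,
    max_modes: int = MAX_MODES,
) -> ArtifactFeatureMap:
    """Whole-recording artifact feature map from the 0.5–30 Hz signal.

    Per channel: the signal is (anti-aliased and) decimated to ``fs_map``,
    decomposed by EMD, and each mode's Hilbert amplitude is accumulated
    into 1-second bins at the samples whose instantaneous frequency lies
    inside ``band``.  The decimation is purely computational — only
    content inside the 0.5–5 Hz gate survives into the map, far below the
    decimated Nyquist.  Recordings shorter than ``T`` seconds produce a
    zero-padded, flagged map.
    """
    q = int(round(recording.fs / fs_map))
    if q < 1:
        raise ValueError("fs_map must not exceed the recording rate")
    values = np.zeros((recording.n_channels, T))
    n_seconds = int(recording.duration)
    covered = min(n_seconds, T)
    for c in range(recording.n_channels):
        x = recording.samples[c]
        if q > 1:
            x = decimate(x, q, ftype="fir", zero_phase=True)
        fs_eff = recording.fs / q
        decomp = emd(x, max_modes=max_modes)
        for imf in decomp.imfs:
            amplitude, freq = hilbert_analytic(imf, fs_eff)
            mask = (freq >= band[0]) & (freq <= band[1])
            if not np.any(mask):
                continue
            seconds = np.minimum(
                (np.arange(x.shape[0]) / fs_eff).astype(int), T - 1
            )
            np.add.at(values[c], seconds[mask], amplitude[mask])
    values[:, covered:] = 0.0
    if normalize and covered > 0:
        # robust per-recording scale from the covered seconds only; the
        # zero padding of short recordings must not bias the percentile
        scale = np.percentile(values[:, :covered], 95.0)
        if scale > 1e-12:
            values = values / scale
    return ArtifactFeatureMap(
        values=values, recording_id=recording.id, padded=covered < T
    )
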