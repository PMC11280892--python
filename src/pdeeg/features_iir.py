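"""Sub-band features from Butterworth-filtered signals.

For each of the six analysis sub-bands, 13 features are extracted per
segment: nine time-domain statistics (mean, absolute mean, power mean,
standard deviation, kurtosis, skewness, mean absolute deviation,
interquartile range, and RMAV — the ratio of absolute mean values between
adjacent sub-bands), three frequency-domain statistics of the periodogram
(frequency center, mean spectral amplitude, RMS frequency), and sample
entropy.

Conventions fixed here and used identically by the wavelet path:

* standard deviation uses the population denominator ``m`` (matching the
  1/m convention of the MAD definition);
* kurtosis is excess kurtosis (0 for a Gaussian);
* IQR is the 75th minus 25th percentile with linear interpolation;
* RMAV pairs band k with band k+1 in canonical order, and the last band
  with the 1-30 Hz broadband signal, giving exactly one RMAV per band;
* sample entropy uses m=2, r=0.2·std, Chebyshev distance, self-matches
  excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal, stats

from pdeeg.bands import BANDS, BROADBAND, SubBand

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: The 13 per-band feature names, in column order.
IIR_FEATURE_NAMES: tuple[str, ...] = (
    "mean", "abs_mean", "power_mean", "std", "kurtosis", "skewness", "mad",
    "iqr", "rmav", "freq_center", "mean_freq", "rms_freq", "sampen",
)


class TimeStats(NamedTuple):
    mean: float
    abs_mean: float
    power_mean: float
    std: float
    kurtosis: float
    skewness: float
    mad: float
    iqr: float


class SpectralStats(NamedTuple):
    freq_center: float
    mean_freq: float
    rms_freq: float


@dataclass
class IIRFeatureBlock:
    """6 bands × 13 features for one (channel, segment); ``valid`` flags degeneracy."""

    values: np.ndarray  # (n_bands, 13)
    band_names: tuple[str, ...]
    feature_names: tuple[str, ...] = IIR_FEATURE_NAMES
    valid: bool = True


def subband_filter(x: np.ndarray, band: SubBand | tuple[float, float], fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass restriction of ``x`` to one sub-band."""
    lo, hi = (band.f_lo, band.f_hi) if isinstance(band, SubBand) else band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band [{lo}, {hi}] invalid for fs={fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


def mad(x: np.ndarray) -> float:
    """Mean absolute deviation about the arithmetic mean: (1/m)·Σ|x_i − u|."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("mad of empty vector is undefined")
    return float(np.mean(np.abs(x - x.mean())))


def time_stats(x: np.ndarray) -> TimeStats:
    """The eight per-band time-domain statistics (see module docstring conventions)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError(f"need at least 4 samples for kurtosis, got {x.size}")
    std = float(x.std(ddof=0))
    if std > 0:
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
        skew = float(stats.skew(x, bias=True))
    else:
        kurt = 0.0
        skew = 0.0
    q75, q25 = np.percentile(x, [75.0, 25.0])
    return TimeStats(
        mean=float(x.mean()),
        abs_mean=float(np.abs(x).mean()),
        power_mean=float(np.mean(x**2)),
        std=std,
        kurtosis=kurt,
        skewness=skew,
        mad=mad(x),
        iqr=float(q75 - q25),
    )


def rmav(band_i: np.ndarray, band_j: np.ndarray) -> float:
    """Ratio of absolute mean values between two sub-band signals."""
    a = np.abs(np.asarray(band_i, dtype=np.float64)).mean()
    b = np.abs(np.asarray(band_j, dtype=np.float64)).mean()
    if b == 0:
        raise ZeroDivisionError("RMAV denominator band has zero absolute mean")
    return float(a / b)


def spectral_features(x: np.ndarray, fs: float) -> SpectralStats:
    """Periodogram-based frequency center, mean spectral amplitude and RMS frequency.

    freq_center = Σf·P(f)/ΣP(f), rms_freq = sqrt(Σf²·P(f)/ΣP(f)) (so
    freq_center ≤ rms_freq by Cauchy-Schwarz); mean_freq is the mean
    periodogram amplitude (1/K)·ΣP(f).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 8:
        raise ValueError(f"need at least 8 samples, got {x.size}")
    freqs, psd = signal.periodogram(x, fs=fs)
    total = psd.sum()
    if total <= 0:
        raise ValueError("all-zero signal: spectral centroid undefined")
    fc = float((freqs * psd).sum() / total)
    rmsf = float(np.sqrt((freqs**2 * psd).sum() / total))
    return SpectralStats(freq_center=fc, mean_freq=float(psd.mean()), rms_freq=rmsf)


# ---------------------------------------------------------------------------
# Sample entropy


if _HAVE_NUMBA:

    @njit(cache=False)
    def _sampen_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
        n = x.shape[0]
        n_templates = n - m  # templates of length m that can be extended
        a = 0
        b = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                match = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        match = False
                        break
                if match:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b

else:

    def _sampen_counts(x: np.ndarray, m: int, r: float):
        n = x.shape[0]
        nt = n - m
        emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
        emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
        a = 0
        b = 0
        chunk = 256
        for start in range(0, nt, chunk):
            block = emb_m[start:start + chunk]
            d = np.max(np.abs(block[:, None, :] - emb_m[None, :, :]), axis=2) <= r
            block1 = emb_m1[start:start + chunk]
            d1 = np.max(np.abs(block1[:, None, :] - emb_m1[None, :, :]), axis=2) <= r
            for ii in range(block.shape[0]):
                i = start + ii
                b += int(d[ii, i + 1:].sum())
                a += int(d1[ii, i + 1:].sum())
        return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: −ln(A/B) over Chebyshev template matches, self-matches excluded.

    A and B count matching templates of length m+1 and m.  Returns 0 for a
    constant signal (convention) and +inf when no (m+1)-template matches
    exist (flagged by callers).  Default tolerance r = 0.2·std(x).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 10:
        raise ValueError(f"need at least 10 samples, got {x.size}")
    sd = x.std(ddof=0)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    a, b = _sampen_counts(x, m, float(r))
    if a == 0 or b == 0:
        return math.inf
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# Per-segment extraction


def extract_iir_features(segment: np.ndarray, fs: float = 500.0,
                         bands: Sequence[SubBand] = BANDS) -> IIRFeatureBlock:
    """Extract the full 6×13 feature block from one segment.

    The segment is band-pass filtered into every sub-band plus the 1-30 Hz
    broadband reference; RMAV for band k divides its absolute mean by band
    k+1's (the last band uses broadband).  Degenerate inputs (zero-variance
    band, RMAV zero denominator, infinite sample entropy) yield a block
    with ``valid=False`` and NaN in the undefined slots.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("segment must be a 1-D sample vector")
    band_sigs = [subband_filter(x, b, fs) for b in bands]
    broadband = subband_filter(x, BROADBAND, fs)
    n_bands = len(bands)
    values = np.full((n_bands, len(IIR_FEATURE_NAMES)), np.nan)
    valid = True
    for k, sig in enumerate(band_sigs):
        ts = time_stats(sig)
        values[k, :8] = ts
        partner = band_sigs[k + 1] if k + 1 < n_bands else broadband
        try:
            values[k, 8] = rmav(sig, partner)
        except ZeroDivisionError:
            valid = False
        try:
            values[k, 9:12] = spectral_features(sig, fs)
        except ValueError:
            valid = False
        se = sample_entropy(sig)
        if math.isinf(se):
            valid = False
            se = np.nan
        values[k, 12] = se
    return IIRFeatureBlock(values=values, band_names=tuple(b.name for b in bands), valid=valid)
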