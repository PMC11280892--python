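"""Per-cohort feature container and the extraction drivers.

A :class:`FeatureTable` holds, for every (subject, eye-state), an array of
shape (channels × segments × bands × features) for one extraction method,
plus subject labels.  It flattens to one stable-ordered vector per subject
(eye-state, then channel, segment, band, feature — all in canonical order),
exports the long-format CSV used by the CLI, and backs both channel scoring
and classification.

The drivers are vectorized across channels and segments (one filter or DWT
call per band per recording) but produce bit-identical values to the
per-segment functions in ``features_iir`` / ``features_wavelet``; that
equivalence is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats

from pdeeg.bands import BANDS, BROADBAND, WPT_NODE_PATHS
from pdeeg.features_iir import IIR_FEATURE_NAMES, sample_entropy, subband_filter
from pdeeg.features_wavelet import DEFAULT_MODE, DEFAULT_WAVELET, WPT_FEATURE_NAMES, parse_node_path
from pdeeg.preprocessing import PreprocessConfig, segment_array
from pdeeg.synthetic import Recording

METHODS = ("iir", "wavelet")


@dataclass
class FeatureTable:
    method: str
    channels: tuple[str, ...]
    band_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    n_segments: int
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    invalid: set[tuple[str, str, str]] = field(default_factory=set)  # (subject, eye_state, channel)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted({sid for sid, _ in self.data}))

    @property
    def eye_states(self) -> tuple[str, ...]:
        return tuple(sorted({st for _, st in self.data}))

    def labels(self, subjects: Sequence[str] | None = None) -> np.ndarray:
        subjects = self.subjects if subjects is None else subjects
        return np.array([int(self.groups[s] == "pd") for s in subjects])

    def flatten(self, subject: str, channels: Sequence[str] | None = None,
                eye_states: Sequence[str] | None = None) -> np.ndarray:
        """One feature vector for a subject: (eye-state, channel, segment, band, feature)."""
        channels = tuple(channels) if channels is not None else self.channels
        eye_states = tuple(eye_states) if eye_states is not None else self.eye_states
        idx = [self.channels.index(c) for c in channels]
        parts = []
        for st in eye_states:
            arr = self.data[(subject, st)]
            parts.append(arr[idx].ravel())
        return np.concatenate(parts)

    def matrix(self, subjects: Sequence[str] | None = None,
               channels: Sequence[str] | None = None,
               eye_states: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (X, y) over subjects; rows align with ``subjects`` order."""
        subjects = self.subjects if subjects is None else tuple(subjects)
        X = np.stack([self.flatten(s, channels, eye_states) for s in subjects])
        return X, self.labels(subjects)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: subject_id, group, eye_state, channel, segment, band, feature, method, value."""
        rows = []
        n_b, n_f = len(self.band_names), len(self.feature_names)
        seg_idx = np.arange(self.n_segments)
        for (sid, st), arr in sorted(self.data.items()):
            for ci, ch in enumerate(self.channels):
                block = arr[ci].reshape(self.n_segments * n_b * n_f)
                mi = pd.MultiIndex.from_product([seg_idx, self.band_names, self.feature_names])
                df = pd.DataFrame({"value": block}, index=mi).reset_index()
                df.columns = ["segment", "band", "feature", "value"]
                df.insert(0, "channel", ch)
                df.insert(0, "eye_state", st)
                df.insert(0, "group", self.groups[sid])
                df.insert(0, "subject_id", sid)
                df["method"] = self.method
                rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        """Rebuild a table from the long-format CSV layout (inverse of to_long_frame)."""
        methods = df["method"].unique()
        if len(methods) != 1:
            raise ValueError(f"expected a single method, found {list(methods)}")
        method = methods[0]
        band_names = tuple(b.name for b in BANDS) if method == "iir" else WPT_NODE_PATHS
        feat_names = IIR_FEATURE_NAMES if method == "iir" else WPT_FEATURE_NAMES
        channels = tuple(sorted(df["channel"].unique()))
        n_seg = int(df["segment"].max()) + 1
        table = cls(method=method, channels=channels, band_names=band_names,
                    feature_names=feat_names, n_segments=n_seg)
        band_idx = {b: i for i, b in enumerate(band_names)}
        feat_idx = {f: i for i, f in enumerate(feat_names)}
        chan_idx = {c: i for i, c in enumerate(channels)}
        for (sid, st), sub in df.groupby(["subject_id", "eye_state"]):
            arr = np.full((len(channels), n_seg, len(band_names), len(feat_names)), np.nan)
            ci = sub["channel"].map(chan_idx).to_numpy()
            si = sub["segment"].to_numpy(dtype=int)
            bi = sub["band"].map(band_idx).to_numpy()
            fi = sub["feature"].map(feat_idx).to_numpy()
            arr[ci, si, bi, fi] = sub["value"].to_numpy()
            table.data[(sid, st)] = arr
            table.groups[sid] = sub["group"].iloc[0]
            for c in np.flatnonzero(np.isnan(arr).any(axis=(1, 2, 3))):
                table.invalid.add((sid, st, channels[c]))
        return table

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_long_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Vectorized statistic kernels (rows = independent vectors)


def _stats_rows(a: np.ndarray) -> np.ndarray:
    """The eight time-domain statistics along the last axis → (..., 8)."""
    mean = a.mean(axis=-1)
    abs_mean = np.abs(a).mean(axis=-1)
    power = np.mean(a**2, axis=-1)
    std = a.std(axis=-1, ddof=0)
    ok = std > 0
    kurt = np.zeros_like(std)
    skew = np.zeros_like(std)
    if ok.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            k = stats.kurtosis(a, axis=-1, fisher=True, bias=True)
            s = stats.skew(a, axis=-1, bias=True)
        kurt[ok] = k[ok]
        skew[ok] = s[ok]
    q75 = np.percentile(a, 75.0, axis=-1)
    q25 = np.percentile(a, 25.0, axis=-1)
    madv = np.abs(a - mean[..., None]).mean(axis=-1)
    return np.stack([mean, abs_mean, power, std, kurt, skew, madv, q75 - q25], axis=-1)


def _rmav_rows(abs_num: np.ndarray, abs_den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bad = abs_den == 0
    out = np.full_like(abs_num, np.nan)
    out[~bad] = abs_num[~bad] / abs_den[~bad]
    return out, bad


# ---------------------------------------------------------------------------
# Drivers


def _extract_iir_recording(segs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(n_ch, n_seg, L) → values (n_ch, n_seg, 6, 13), invalid mask (n_ch, n_seg)."""
    n_ch, n_seg, L = segs.shape
    flat = segs.reshape(n_ch * n_seg, L)
    band_sigs = []
    for b in BANDS:
        sos = signal.butter(4, [b.f_lo, b.f_hi], btype="bandpass", fs=fs, output="sos")
        band_sigs.append(signal.sosfiltfilt(sos, flat, axis=-1))
    sos_bb = signal.butter(4, list(BROADBAND), btype="bandpass", fs=fs, output="sos")
    broadband = signal.sosfiltfilt(sos_bb, flat, axis=-1)

    n = flat.shape[0]
    values = np.full((n, len(BANDS), len(IIR_FEATURE_NAMES)), np.nan)
    invalid = np.zeros(n, dtype=bool)
    abs_means = [np.abs(s).mean(axis=-1) for s in band_sigs]
    abs_bb = np.abs(broadband).mean(axis=-1)
    for k, sig in enumerate(band_sigs):
        values[:, k, :8] = _stats_rows(sig)
        den = abs_means[k + 1] if k + 1 < len(BANDS) else abs_bb
        rm, bad = _rmav_rows(abs_means[k], den)
        values[:, k, 8] = rm
        invalid |= bad
        freqs, psd = signal.periodogram(sig, fs=fs, axis=-1)
        total = psd.sum(axis=-1)
        zero = total <= 0
        invalid |= zero
        with np.errstate(invalid="ignore", divide="ignore"):
            values[:, k, 9] = (psd * freqs).sum(axis=-1) / total
            values[:, k, 10] = psd.mean(axis=-1)
            values[:, k, 11] = np.sqrt((psd * freqs**2).sum(axis=-1) / total)
        for i in range(n):
            se = sample_entropy(sig[i])
            if np.isinf(se):
                invalid[i] = True
                se = np.nan
            values[i, k, 12] = se
    return values.reshape(n_ch, n_seg, len(BANDS), -1), invalid.reshape(n_ch, n_seg)


def _node_rows(flat: np.ndarray, paths: Sequence[str], wavelet: str, mode: str) -> list[np.ndarray]:
    """Cascade DWT along the last axis for all rows at once."""
    cache: dict[str, np.ndarray] = {"": flat}

    def resolve(prefix: str) -> np.ndarray:
        if prefix in cache:
            return cache[prefix]
        parent = resolve(prefix[:-1])
        ca, cd = pywt.dwt(parent, wavelet, mode=mode, axis=-1)
        cache[prefix[:-1] + "A"] = ca
        cache[prefix[:-1] + "D"] = cd
        return cache[prefix]

    return [resolve(parse_node_path(p)[0]) for p in paths]


def _extract_wpt_recording(segs: np.ndarray, paths: Sequence[str] = WPT_NODE_PATHS,
                           wavelet: str = DEFAULT_WAVELET, mode: str = DEFAULT_MODE
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(n_ch, n_seg, L) → values (n_ch, n_seg, 6, 9), invalid mask (n_ch, n_seg)."""
    n_ch, n_seg, L = segs.shape
    flat = segs.reshape(n_ch * n_seg, L)
    coeffs = _node_rows(flat, paths, wavelet, mode)
    n = flat.shape[0]
    values = np.full((n, len(paths), len(WPT_FEATURE_NAMES)), np.nan)
    invalid = np.zeros(n, dtype=bool)
    abs_sums = np.stack([np.abs(c).sum(axis=-1) for c in coeffs])
    lengths = np.array([c.shape[-1] for c in coeffs], dtype=float)
    abs_means = abs_sums / lengths[:, None]
    concat_abs_mean = abs_sums.sum(axis=0) / lengths.sum()
    for k, c in enumerate(coeffs):
        values[:, k, :8] = _stats_rows(c)
        den = abs_means[k + 1] if k + 1 < len(coeffs) else concat_abs_mean
        rm, bad = _rmav_rows(abs_means[k], den)
        values[:, k, 8] = rm
        invalid |= bad
    return values.reshape(n_ch, n_seg, len(paths), -1), invalid.reshape(n_ch, n_seg)


def extract_features(recordings: Iterable[Recording], method: str,
                     config: PreprocessConfig | None = None) -> FeatureTable:
    """Segment every recording and extract one method's feature table.

    Recordings must already be harmonized (identical channel lists) and
    filtered.  A (subject, eye-state, channel) whose any segment block is
    degenerate is listed in ``table.invalid`` and treated as missing by
    channel scoring.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    config = config or PreprocessConfig()
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings given")
    channels = recordings[0].channel_names
    band_names = tuple(b.name for b in BANDS) if method == "iir" else WPT_NODE_PATHS
    feat_names = IIR_FEATURE_NAMES if method == "iir" else WPT_FEATURE_NAMES
    table = FeatureTable(method=method, channels=channels, band_names=band_names,
                         feature_names=feat_names, n_segments=config.n_segments)
    for rec in recordings:
        if rec.channel_names != channels:
            raise ValueError(f"recording {rec.subject_id!r} has a different channel list")
        segs = segment_array(rec, config)
        if method == "iir":
            values, bad = _extract_iir_recording(segs, rec.fs)
        else:
            values, bad = _extract_wpt_recording(segs)
        table.data[(rec.subject_id, rec.eye_state)] = values
        table.groups[rec.subject_id] = rec.group
        for ci in np.flatnonzero(bad.any(axis=1)):
            table.invalid.add((rec.subject_id, rec.eye_state, channels[ci]))
    return table
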