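"""Montage harmonization, broadband/notch filtering and event segmentation.

Filtering is zero-phase (forward-backward) so group delay never misaligns
channels: a 4th-order Butterworth band-pass (0.1-100 Hz by default) plus
2nd-order IIR notches (Q=30) at the power-line frequency and its harmonic
(60/180 Hz).  Each 60 s event is then cut into 15 consecutive
non-overlapping 2000-sample segments; trailing samples are dropped.

Ocular-artifact removal (e.g. ICA) is intentionally not part of this stage;
``apply_filters`` accepts a ``pre_filter_hook`` callable where an external
cleaner can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from pdeeg.montages import Montage, common_channels
from pdeeg.synthetic import Recording


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering and segmentation parameters."""

    f_lo: float = 0.1
    f_hi: float = 100.0
    notch_freqs: tuple[float, ...] = (60.0, 180.0)
    notch_q: float = 30.0
    seg_len: int = 2000
    n_segments: int = 15

    def validate(self, fs: float) -> None:
        if not 0 < self.f_lo < self.f_hi < fs / 2:
            raise ValueError(f"band [{self.f_lo}, {self.f_hi}] invalid for fs={fs}")
        for f0 in self.notch_freqs:
            if f0 >= fs / 2:
                raise ValueError(f"notch frequency {f0} Hz is at/above Nyquist ({fs / 2} Hz)")


@dataclass(frozen=True)
class Segment:
    """One fixed-length analysis window of a single channel."""

    subject_id: str
    channel: str
    segment_index: int
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be 1-D")


def harmonize_channels(recording: Recording, montage_a: Montage, montage_b: Montage) -> Recording:
    """Restrict a recording to the two montages' common channels, canonically ordered.

    The output channel order (lexicographic) is identical regardless of
    which montage the recording came from, so flattened feature vectors from
    different sites align column-for-column.
    """
    if recording.montage.name not in (montage_a.name, montage_b.name):
        raise ValueError(
            f"recording montage {recording.montage.name!r} is neither "
            f"{montage_a.name!r} nor {montage_b.name!r}"
        )
    common = common_channels(montage_a, montage_b)
    missing = [c for c in common if c not in recording.channel_names]
    if missing:
        raise ValueError(f"recording lacks common channels: {missing}")
    idx = [recording.channel_names.index(c) for c in common]
    harmonized = Montage(
        name=f"common({montage_a.name},{montage_b.name})",
        channel_names=common,
        online_reference=recording.montage.online_reference,
    )
    return Recording(
        recording.subject_id, recording.group, recording.eye_state,
        recording.fs, harmonized, recording.data[idx],
    )


def apply_filters(
    recording: Recording,
    config: PreprocessConfig | None = None,
    pre_filter_hook: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> Recording:
    """Zero-phase band-pass plus notch filtering of every channel."""
    config = config or PreprocessConfig()
    config.validate(recording.fs)
    data = recording.data
    if pre_filter_hook is not None:
        data = np.asarray(pre_filter_hook(data, recording.fs), dtype=np.float64)
        if data.shape != recording.data.shape:
            raise ValueError("pre_filter_hook must preserve the data shape")
    sos = signal.butter(
        4, [config.f_lo, config.f_hi], btype="bandpass", fs=recording.fs, output="sos"
    )
    out = signal.sosfiltfilt(sos, data, axis=1)
    for f0 in config.notch_freqs:
        b, a = signal.iirnotch(f0, config.notch_q, fs=recording.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return Recording(
        recording.subject_id, recording.group, recording.eye_state,
        recording.fs, recording.montage, out,
    )


def segment_array(recording: Recording, config: PreprocessConfig | None = None) -> np.ndarray:
    """Segment every channel into (n_channels, n_segments, seg_len); tail dropped."""
    config = config or PreprocessConfig()
    needed = config.n_segments * config.seg_len
    if recording.n_samples < needed:
        raise ValueError(
            f"event has {recording.n_samples} samples but "
            f"{config.n_segments} × {config.seg_len} = {needed} are required"
        )
    trimmed = recording.data[:, :needed]
    return trimmed.reshape(recording.montage.n_channels, config.n_segments, config.seg_len)


def segment_event(recording: Recording, config: PreprocessConfig | None = None) -> list[Segment]:
    """Cut one event into fixed-length per-channel segments.

    Returns n_channels × n_segments Segment objects, channel-major, covering
    samples [0, n_segments·seg_len); any trailing samples are unused.
    """
    config = config or PreprocessConfig()
    arr = segment_array(recording, config)
    segments: list[Segment] = []
    for ci, ch in enumerate(recording.channel_names):
        for si in range(config.n_segments):
            segments.append(Segment(recording.subject_id, ch, si, arr[ci, si], recording.fs))
    return segments


def preprocess_recordings(
    recordings: Sequence[Recording],
    montage_a: Montage,
    montage_b: Montage,
    config: PreprocessConfig | None = None,
) -> list[Recording]:
    """harmonize → filter every recording (the standard pre-extraction path)."""
    config = config or PreprocessConfig()
    return [apply_filters(harmonize_channels(r, montage_a, montage_b), config) for r in recordings]
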