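"""Synthetic two-class resting-state EEG cohorts.

The generator emulates the statistical structure the downstream analysis
relies on: each channel is 1/f-weighted broadband background noise plus
band-limited oscillators in the four classic rhythms (delta, theta, alpha,
beta), synthesized in the frequency domain with random phases.  A planted
class effect multiplies spectral power inside one sub-band on a chosen
subset of channels for the disease group, so "informative channels" exist
by construction and their recovery can be measured.

Defaults: 64-channel montage, 500 Hz, 60 s eyes-open/eyes-closed events,
cohort sizes 27 PD + 26 control (site A) and 14 + 14 (site B).

Heterogeneity: every subject draws a log-normal multiplier per rhythm
(``per_subject_sd`` on the log-power scale, shared across channels), and
every channel a smaller independent log-normal jitter, so that single
subjects are not trivially classifiable from one segment.  Eyes-closed
recordings boost alpha power by a configurable gain (closed > open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from pdeeg.bands import get_band
from pdeeg.montages import Montage

#: Expected total band power of each background rhythm oscillator (µV²).
RHYTHM_POWERS: dict[str, float] = {"delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 5.0}

#: Log-scale sd of the per-channel band-power jitter.
CHANNEL_JITTER_SD = 0.1

#: Multiplier on alpha-band power for eyes-closed recordings.
DEFAULT_ALPHA_CLOSED_GAIN = 1.5

#: Upper edge of the 1/f background spectrum (Hz).
_BACKGROUND_F_HI = 100.0

SEGMENT_SAMPLES = 2000  # minimum event length, in samples

GROUPS = ("pd", "control")
EYE_STATES = ("open", "closed")


@dataclass(frozen=True)
class EffectProfile:
    """Planted class contrast: band-power ratio (PD vs control) on target channels.

    ``power_ratio`` multiplies expected spectral power inside ``band`` on
    ``target_channels`` for PD subjects; 1.0 plants no effect (null cohort).
    ``background_sd`` is the total sd (µV) of the 1/f background;
    ``per_subject_sd`` the log-scale sd of subject-level band-power
    multipliers.
    """

    target_channels: tuple[str, ...] = ()
    band: str = "beta"
    power_ratio: float = 1.0
    background_sd: float = 10.0
    per_subject_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.power_ratio <= 0:
            raise ValueError(f"power_ratio must be > 0, got {self.power_ratio}")
        get_band(self.band)  # raises on unknown band


@dataclass
class Recording:
    """One subject/eye-state EEG event: channels × samples matrix in µV."""

    subject_id: str
    group: str
    eye_state: str
    fs: float
    montage: Montage
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage "
                f"{self.montage.name!r} has {self.montage.n_channels} channels"
            )
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.eye_state not in EYE_STATES:
            raise ValueError(f"eye_state must be one of {EYE_STATES}, got {self.eye_state!r}")
        if self.fs <= 60.0:  # 2 × highest analysis band edge (30 Hz)
            raise ValueError(f"fs={self.fs} too low for 30 Hz analysis bands")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.montage.channel_names

    @property
    def label(self) -> int:
        """Binary class label: 1 for PD, 0 for control."""
        return int(self.group == "pd")


def _rhythm_ranges() -> dict[str, tuple[float, float]]:
    return {name: (get_band(name).f_lo, get_band(name).f_hi) for name in RHYTHM_POWERS}


def generate_recording(
    subject_id: str,
    group: str,
    eye_state: str,
    montage: Montage,
    effect: EffectProfile | None = None,
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
    alpha_closed_gain: float = DEFAULT_ALPHA_CLOSED_GAIN,
) -> Recording:
    """Synthesize one multi-channel EEG event; deterministic given ``seed``.

    Per channel the signal is the inverse real FFT of a target one-sided
    power spectrum (1/f background + flat-topped rhythm bumps) with
    i.i.d. uniform random phases, so expected band powers are controlled
    exactly.  For PD subjects, spectral power inside ``effect.band`` is
    multiplied by ``effect.power_ratio`` on ``effect.target_channels``.
    """
    effect = effect if effect is not None else EffectProfile()
    unknown = [c for c in effect.target_channels if c not in montage.channel_names]
    if unknown:
        raise ValueError(f"effect target channel(s) not in montage {montage.name!r}: {unknown}")
    n = int(round(duration_s * fs))
    if n < SEGMENT_SAMPLES:
        raise ValueError(
            f"duration {duration_s} s gives {n} samples; at least one "
            f"{SEGMENT_SAMPLES}-sample segment is required"
        )

    rng = np.random.default_rng(seed)
    n_ch = montage.n_channels
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    n_bins = freqs.size
    rhythms = list(RHYTHM_POWERS)

    # Subject-level log-normal multipliers (background, then per rhythm, shared
    # across channels), per-channel jitter, then phases — fixed draw order for
    # determinism.  The background multiplier makes overall amplitude vary
    # between subjects, so band powers are not trivially separable.
    bg_mult = float(np.exp(rng.normal(0.0, effect.per_subject_sd)))
    subj_mult = np.exp(rng.normal(0.0, effect.per_subject_sd, size=len(rhythms)))
    chan_jitter = np.exp(rng.normal(0.0, CHANNEL_JITTER_SD, size=(n_ch, len(rhythms))))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, n_bins))

    # Per-bin variance contribution V[ch, k]; total signal variance = sum_k V.
    V = np.zeros((n_ch, n_bins))
    bg_mask = (freqs > 0) & (freqs <= _BACKGROUND_F_HI)
    bg_shape = np.zeros(n_bins)
    bg_shape[bg_mask] = 1.0 / np.maximum(freqs[bg_mask], 1.0)
    bg_shape *= bg_mult * effect.background_sd**2 / bg_shape.sum()
    V += bg_shape[None, :]

    ranges = _rhythm_ranges()
    for j, name in enumerate(rhythms):
        lo, hi = ranges[name]
        mask = (freqs >= lo) & (freqs < hi)
        power = RHYTHM_POWERS[name] * subj_mult[j]
        if name == "alpha" and eye_state == "closed":
            power *= alpha_closed_gain
        V[:, mask] += (power / mask.sum()) * chan_jitter[:, j][:, None]

    if group == "pd" and effect.power_ratio != 1.0 and effect.target_channels:
        band = get_band(effect.band)
        bmask = (freqs >= band.f_lo) & (freqs < band.f_hi)
        idx = [montage.channel_names.index(c) for c in effect.target_channels]
        V[np.ix_(idx, np.flatnonzero(bmask))] *= effect.power_ratio

    amp = n * np.sqrt(V / 2.0)
    amp[:, 0] = 0.0  # no DC component
    spectrum = amp * np.exp(1j * phases)
    data = np.fft.irfft(spectrum, n=n, axis=1)
    return Recording(subject_id, group, eye_state, fs, montage, data)


def generate_cohort(
    n_pd: int,
    n_control: int,
    montage: Montage,
    effect: EffectProfile | None = None,
    eye_states: tuple[str, ...] = ("open", "closed"),
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
    cohort_name: str = "cohort",
    alpha_closed_gain: float = DEFAULT_ALPHA_CLOSED_GAIN,
) -> list[Recording]:
    """Generate a full two-group cohort: one Recording per subject per eye state.

    Per-subject seeds are derived from ``seed`` via a SeedSequence, so any
    single recording can be regenerated in isolation from its own seed.
    """
    if n_pd < 1 or n_control < 1:
        raise ValueError("need at least one subject per group")
    groups = ["pd"] * n_pd + ["control"] * n_control
    ids = [f"{cohort_name}-pd{i + 1:02d}" for i in range(n_pd)] + [
        f"{cohort_name}-ct{i + 1:02d}" for i in range(n_control)
    ]
    n_rec = len(groups) * len(eye_states)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_rec, dtype=np.uint32)
    recordings: list[Recording] = []
    k = 0
    for sid, grp in zip(ids, groups):
        for state in eye_states:
            recordings.append(
                generate_recording(
                    sid, grp, state, montage, effect,
                    duration_s=duration_s, fs=fs, seed=int(child_seeds[k]),
                    alpha_closed_gain=alpha_closed_gain,
                )
            )
            k += 1
    return recordings


def band_power(recording: Recording, channel: str, f_lo: float, f_hi: float) -> float:
    """Welch-integrated power (µV²) of one channel over [f_lo, f_hi).

    Serves as the independent spectral oracle for the generator and the
    filtering stages; approximately additive over disjoint bands.
    """
    if channel not in recording.channel_names:
        raise ValueError(f"unknown channel {channel!r}")
    x = recording.data[recording.channel_names.index(channel)]
    return band_power_1d(x, recording.fs, f_lo, f_hi)


def band_power_1d(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    """Welch band power of a 1-D signal over [f_lo, f_hi)."""
    if not 0 <= f_lo < f_hi <= fs / 2:
        raise ValueError(f"invalid band [{f_lo}, {f_hi}) for fs={fs}")
    x = np.asarray(x, dtype=np.float64)
    nperseg = min(x.size, 2048)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    mask = (freqs >= f_lo) & (freqs < f_hi)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}) contains no spectral bins")
    # rectangular integration keeps band power additive over disjoint bands
    return float(psd[mask].sum() * (freqs[1] - freqs[0]))
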