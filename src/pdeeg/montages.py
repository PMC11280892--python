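"""Scalp-electrode montages (10-10 nomenclature) and the shipped defaults.

Two 64-channel montages are shipped, modelled on the two acquisition sites
of the public PD/control EEG cohorts this package emulates: one referenced
online to CPz and one to Pz.  After dropping the reference-affected labels,
their channel lists share exactly 59 names, which form the harmonized
channel universe used by the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Montage:
    """An ordered set of electrode labels plus the online reference.

    Invariants: labels are unique and the reference is not itself a
    recorded channel.
    """

    name: str
    channel_names: tuple[str, ...]
    online_reference: str

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"montage {self.name!r} has duplicate channel labels")
        if self.online_reference in self.channel_names:
            raise ValueError(
                f"reference {self.online_reference!r} must not appear in channel_names"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


# 59 labels common to both shipped montages (all 10-10 positions).
_COMMON_59 = (
    "Fp1", "Fp2", "Fpz",
    "AF3", "AF4", "AF7", "AF8",
    "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "Fz",
    "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7", "FT8",
    "C1", "C2", "C3", "C4", "C5", "C6", "Cz", "T7", "T8",
    "CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
    "TP7", "TP8", "TP9", "TP10",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    "PO3", "PO4", "PO7", "PO8", "POz",
    "O1", "O2", "Oz",
)

_UNM_EXTRA = ("AFz", "F9", "F10", "Iz", "Pz")
_IOWA_EXTRA = ("CPz", "P9", "P10", "PO9", "PO10")


def unm_like_montage() -> Montage:
    """64-channel montage referenced to CPz (CPz therefore not recorded)."""
    return Montage("unm64", _COMMON_59 + _UNM_EXTRA, online_reference="CPz")


def iowa_like_montage() -> Montage:
    """64-channel montage referenced to Pz (Pz therefore not recorded)."""
    return Montage("iowa64", _COMMON_59 + _IOWA_EXTRA, online_reference="Pz")


def common_channels(a: Montage, b: Montage) -> tuple[str, ...]:
    """Channels present in both montages, in canonical (lexicographic) order.

    Reference-affected labels drop out automatically: each montage's online
    reference is absent from its own channel list, so it cannot survive the
    intersection.
    """
    common = set(a.channel_names) & set(b.channel_names)
    if not common:
        raise ValueError(f"montages {a.name!r} and {b.name!r} share no channels")
    return tuple(sorted(common))
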