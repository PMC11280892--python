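"""Canonical EEG sub-band definitions shared by both feature-extraction paths.

Six sub-bands are analysed: delta (1-4 Hz), theta (4-8), alpha1 (8-10),
alpha2 (10-13), alpha (8-13) and beta (13-30).  Boundary frequencies are
shared between adjacent bands (each boundary belongs to both neighbours),
and alpha deliberately nests alpha1/alpha2.  Each band also names the
wavelet-packet node whose natural-order frequency range approximates it.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SubBand:
    """A named EEG frequency band with IIR edges and a wavelet-packet node path.

    ``wpt_path`` is a string over {A, D} (approximation/detail branches) and
    ``wpt_level`` its depth in the packet tree.
    """

    name: str
    f_lo: float
    f_hi: float
    wpt_path: str
    wpt_level: int

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges [{self.f_lo}, {self.f_hi}]")
        if len(self.wpt_path) != self.wpt_level:
            raise ValueError(f"path {self.wpt_path!r} does not match level {self.wpt_level}")


#: The six analysis sub-bands, in canonical order.  The wavelet-packet node
#: paths are the six coefficient sets used by the wavelet feature path.
BANDS: tuple[SubBand, ...] = (
    SubBand("delta", 1.0, 4.0, "AAAAAA", 6),
    SubBand("theta", 4.0, 8.0, "AAAAAD", 6),
    SubBand("alpha1", 8.0, 10.0, "AAAADA", 6),
    SubBand("alpha2", 10.0, 13.0, "AAAADD", 6),
    SubBand("alpha", 8.0, 13.0, "AAAAD", 5),
    SubBand("beta", 13.0, 30.0, "AAAD", 4),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

#: Broadband range spanned by the analysis bands; used as the RMAV partner
#: of the last band.
BROADBAND: tuple[float, float] = (1.0, 30.0)

#: Default wavelet-packet node paths (with level suffix) in printed order.
WPT_NODE_PATHS: tuple[str, ...] = tuple(f"{b.wpt_path}{b.wpt_level}" for b in BANDS)


def get_band(name: str) -> SubBand:
    for b in BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown sub-band {name!r}; known: {', '.join(BAND_NAMES)}")
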