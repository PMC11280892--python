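"""Reference channel-selection results shipped with the package.

These are the channel lists reported for the original two-cohort PD study
this pipeline reimplements: 11 channels selected from the Butterworth-filter
feature path and 22 from the wavelet-packet path (R² threshold 0.7).  They
are shipped as plain-text fixtures under ``pdeeg/data`` and exposed here for
set arithmetic (their intersection has 4 channels, their union 29).
"""

from __future__ import annotations

from importlib import resources


def _load(name: str) -> tuple[str, ...]:
    text = resources.files("pdeeg").joinpath("data", name).read_text(encoding="utf-8")
    return tuple(line.strip() for line in text.splitlines() if line.strip())


IIR_SELECTED_CHANNELS: tuple[str, ...] = _load("iir_selected_channels.txt")
WAVELET_SELECTED_CHANNELS: tuple[str, ...] = _load("wavelet_selected_channels.txt")
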