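"""Wavelet-packet coefficient features (db5, depth-6 tree).

Each 2000-sample segment is decomposed with the Daubechies-5 wavelet into a
packet tree of depth 6; six named nodes approximate the analysis sub-bands
(AAAAAA6, AAAAAD6, AAAADA6, AAAADD6, AAAAD5, AAAD4, in printed order).
Nine statistics are computed from each node's coefficient vector — the same
eight time-domain kernels as the band-pass path plus RMAV between adjacent
nodes (the last node is paired with the concatenation of all six nodes'
coefficients).

Boundary handling uses zero-padding extension, under which the orthogonal
filter bank conserves energy exactly (every level's leaves sum to the
segment energy), at the cost of a few extra boundary coefficients per node.
Note that node tree-paths (natural order) and ascending frequency differ by
a Gray-code permutation; ``node_frequency_band`` exposes both mappings
rather than silently reordering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from pdeeg.bands import WPT_NODE_PATHS
from pdeeg.features_iir import rmav, time_stats

#: The 9 per-node feature names, in column order.
WPT_FEATURE_NAMES: tuple[str, ...] = (
    "mean", "abs_mean", "power_mean", "std", "kurtosis", "skewness", "mad", "iqr", "rmav",
)

DEFAULT_WAVELET = "db5"
DEFAULT_MODE = "zero"
_PATH_RE = re.compile(r"^([AD]+)(\d*)$")


def parse_node_path(path: str) -> tuple[str, int]:
    """Split 'AAAD4' into ('AAAD', 4); a missing level suffix defaults to the letter count."""
    m = _PATH_RE.match(path.upper())
    if not m:
        raise ValueError(f"malformed wavelet-packet path {path!r}")
    letters, level = m.group(1), m.group(2)
    lvl = int(level) if level else len(letters)
    if lvl != len(letters):
        raise ValueError(f"path {path!r}: level suffix {lvl} does not match {len(letters)} letters")
    return letters, lvl


@dataclass
class WPTDecomposition:
    """Full wavelet-packet tree of one segment; nodes addressed by path string."""

    wp: pywt.WaveletPacket
    max_level: int

    def node(self, path: str) -> np.ndarray:
        letters, lvl = parse_node_path(path)
        if lvl > self.max_level:
            raise ValueError(f"path {path!r} deeper than decomposition level {self.max_level}")
        return np.asarray(self.wp[letters.lower()].data, dtype=np.float64)

    def level_nodes(self, level: int) -> dict[str, np.ndarray]:
        """All nodes at one depth, keyed by upper-case path, in natural order."""
        nodes = self.wp.get_level(level, order="natural")
        return {n.path.upper(): np.asarray(n.data, dtype=np.float64) for n in nodes}


def wpt_decompose(segment: np.ndarray, wavelet: str = DEFAULT_WAVELET,
                  max_level: int = 6, mode: str = DEFAULT_MODE) -> WPTDecomposition:
    """Decompose one segment into the full packet tree down to ``max_level``."""
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("segment must be 1-D")
    if pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet)) < max_level:
        raise ValueError(f"segment of {x.size} samples too short for level {max_level}")
    wp = pywt.WaveletPacket(x, wavelet=wavelet, mode=mode, maxlevel=max_level)
    return WPTDecomposition(wp=wp, max_level=max_level)


def node_frequency_band(path: str, fs: float, ordering: str = "natural") -> tuple[float, float]:
    """Nominal frequency range [f_lo, f_hi) of a packet node.

    'natural' reads the path as a binary index (A=0, D=1); 'frequency'
    first Gray-decodes that index, undoing the down-sampling-induced
    frequency inversion of the detail branches.
    """
    letters, level = parse_node_path(path)
    k = 0
    for ch in letters:
        k = (k << 1) | (1 if ch == "D" else 0)
    if ordering == "frequency":
        g = k
        while g:
            g >>= 1
            k ^= g
    elif ordering != "natural":
        raise ValueError(f"ordering must be 'natural' or 'frequency', got {ordering!r}")
    width = fs / 2 ** (level + 1)
    return (k * width, (k + 1) * width)


def node_coefficients(segment: np.ndarray, paths: Sequence[str],
                      wavelet: str = DEFAULT_WAVELET, mode: str = DEFAULT_MODE
                      ) -> list[np.ndarray]:
    """Coefficient vectors of the requested nodes via shared-prefix cascade.

    Only the filter-bank branches on the way to the requested nodes are
    computed (the default six nodes share a single approximation chain), so
    this is much cheaper than building the full tree.
    """
    x = np.asarray(segment, dtype=np.float64)
    cache: dict[str, np.ndarray] = {"": x}

    def resolve(prefix: str) -> np.ndarray:
        if prefix in cache:
            return cache[prefix]
        parent = resolve(prefix[:-1])
        ca, cd = pywt.dwt(parent, wavelet, mode=mode)
        cache[prefix[:-1] + "A"] = ca
        cache[prefix[:-1] + "D"] = cd
        return cache[prefix]

    return [resolve(parse_node_path(p)[0]) for p in paths]


@dataclass
class WPTFeatureBlock:
    """6 nodes × 9 features for one (channel, segment); ``valid`` flags degeneracy."""

    values: np.ndarray  # (n_nodes, 9)
    node_paths: tuple[str, ...]
    feature_names: tuple[str, ...] = WPT_FEATURE_NAMES
    valid: bool = True


def extract_wpt_features(segment: np.ndarray, node_paths: Sequence[str] = WPT_NODE_PATHS,
                         wavelet: str = DEFAULT_WAVELET) -> WPTFeatureBlock:
    """Extract the 6×9 coefficient-statistics block from one segment.

    Statistic kernels are shared with the band-pass path; RMAV pairs node k
    with node k+1, the last node with the concatenation of all nodes'
    coefficients.  A zero segment yields all-zero statistics with the RMAV
    column flagged (``valid=False``).
    """
    coeffs = node_coefficients(segment, node_paths, wavelet=wavelet)
    concat = np.concatenate(coeffs)
    n = len(coeffs)
    values = np.full((n, len(WPT_FEATURE_NAMES)), np.nan)
    valid = True
    for k, c in enumerate(coeffs):
        values[k, :8] = time_stats(c)
        partner = coeffs[k + 1] if k + 1 < n else concat
        try:
            values[k, 8] = rmav(c, partner)
        except ZeroDivisionError:
            valid = False
    return WPTFeatureBlock(values=values, node_paths=tuple(node_paths), valid=valid)
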