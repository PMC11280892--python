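"""Readers/writers for the formats the pipeline touches.

Two interchange representations are supported for recordings:

* the *fixture* format — a ``.npy`` channels×samples matrix (µV, float64)
  next to a JSON sidecar carrying subject id, group, eye state, sampling
  rate, channel names, reference and the generator seed; lossless and
  diff-friendly, used for all intermediate artifacts;
* EDF (European Data Format) — written by a minimal built-in 16-bit EDF
  writer and read back through mne's EDF reader, so the write path and the
  read path are independent implementations.  EDF storage is quantized to
  the per-channel physical range / 2¹⁶.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from pdeeg.montages import Montage
from pdeeg.synthetic import Recording

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


# ---------------------------------------------------------------------------
# Fixture format


def write_fixture(recording: Recording, directory: str | Path, seed: int | None = None) -> Path:
    """Write matrix + JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{recording.subject_id}_{recording.eye_state}"
    np.save(directory / f"{stem}.npy", recording.data)
    sidecar = {
        "subject_id": recording.subject_id,
        "group": recording.group,
        "eye_state": recording.eye_state,
        "fs": recording.fs,
        "channel_names": list(recording.channel_names),
        "online_reference": recording.montage.online_reference,
        "montage_name": recording.montage.name,
        "seed": seed,
    }
    path = directory / f"{stem}.json"
    path.write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    return path


def read_fixture(sidecar_path: str | Path) -> Recording:
    """Read a recording back from its JSON sidecar (matrix loaded from the twin .npy)."""
    sidecar_path = Path(sidecar_path)
    try:
        meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed fixture sidecar {sidecar_path}: {exc}") from exc
    for key in ("subject_id", "group", "eye_state", "fs", "channel_names"):
        if key not in meta:
            raise ValueError(f"fixture sidecar {sidecar_path} missing field {key!r}")
    data = np.load(sidecar_path.with_suffix(".npy"))
    montage = Montage(meta.get("montage_name", "fixture"), tuple(meta["channel_names"]),
                      meta.get("online_reference", "REF"))
    return Recording(meta["subject_id"], meta["group"], meta["eye_state"],
                     float(meta["fs"]), montage, data)


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (1 s data records; zero-padded to whole records)."""
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    # Use the header's truncated ASCII physical range for the affine encode so
    # that any standards-compliant reader inverts it exactly (to the 16-bit step).
    raw_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    max_str = [f"{m:.6g}"[:8] for m in raw_max]
    min_str = [f"{-m:.6g}"[:8] for m in raw_max]
    phys_max = np.array([float(s) for s in max_str])
    phys_min = np.array([float(s) for s in min_str])
    span = phys_max - phys_min
    digital = np.clip(
        np.round((padded - phys_min[:, None]) / span[:, None] * 65535) + _EDF_DIG_MIN,
        _EDF_DIG_MIN, _EDF_DIG_MAX,
    ).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),
        _edf_field(f"{recording.subject_id} {recording.group}", 80),
        _edf_field(f"eye_state {recording.eye_state}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    fields = []
    for spec, width in [
        (lambda c: recording.channel_names[c], 16),
        (lambda c: "", 80),
        (lambda c: "uV", 8),
        (lambda c: min_str[c], 8),
        (lambda c: max_str[c], 8),
        (lambda c: _EDF_DIG_MIN, 8),
        (lambda c: _EDF_DIG_MAX, 8),
        (lambda c: "", 80),
        (lambda c: spr, 8),
        (lambda c: "", 32),
    ]:
        fields.extend(_edf_field(spec(c), width) for c in range(n_ch))
    with open(path, "wb") as fh:
        fh.write(header + b"".join(fields))
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path, group: str = "control", eye_state: str = "open",
             reference: str = "REF") -> Recording:
    """Read an EDF file through mne; amplitudes returned in µV.

    Group and eye-state labels are taken from an adjacent fixture sidecar
    (same stem, ``.json``) when present, else from the arguments.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"malformed EDF file {path}: {exc}") from exc
    fs = raw.info["sfreq"]
    if not fs or fs <= 0:
        raise ValueError(f"EDF file {path} has no valid sampling rate")
    subject_id = path.stem
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        subject_id = meta.get("subject_id", subject_id)
        group = meta.get("group", group)
        eye_state = meta.get("eye_state", eye_state)
        reference = meta.get("online_reference", reference)
    montage = Montage(f"edf:{path.stem}", tuple(raw.ch_names), reference)
    return Recording(subject_id, group, eye_state, float(fs), montage,
                     raw.get_data() * 1e6)


def read_eeg(path: str | Path, format: str = "fixture") -> Recording:
    """Dispatching reader for the two supported on-disk formats."""
    if format == "fixture":
        return read_fixture(path)
    if format == "edf":
        return read_edf(path)
    raise ValueError(f"format must be 'fixture' or 'edf', got {format!r}")
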