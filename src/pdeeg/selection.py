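"""Single-channel evaluation and R²-thresholded channel selection.

Every channel is scored by training a linear-kernel SVM on that channel's
features alone (one flattened vector per training subject, z-scored with
training statistics) and computing the R² score — the coefficient of
determination of the 0/1 predictions against the 0/1 labels — on held-out
subjects.  For balanced labels R² = 4·accuracy − 3, so the conventional
threshold of 0.7 demands held-out accuracy ≥ 0.925.  Channels scoring below
the threshold are rejected; per-method selections can be combined by set
union or intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from pdeeg.feature_table import FeatureTable


@dataclass(frozen=True)
class SplitSpec:
    """Subject-level stratified train/validation split."""

    train_fraction: float = 0.7
    seed: int = 0

    def split(self, subjects: Sequence[str], labels: np.ndarray) -> tuple[list[str], list[str]]:
        train, val = train_test_split(
            list(subjects), train_size=self.train_fraction, stratify=labels,
            random_state=self.seed,
        )
        return list(train), list(val)


@dataclass(frozen=True)
class ChannelScore:
    channel: str
    method: str
    r2: float | None
    split_seed: int
    missing_reason: str | None = None


@dataclass(frozen=True)
class SelectionScheme:
    """A named channel subset with its provenance and threshold."""

    name: str
    channels: tuple[str, ...]
    provenance: str  # iir | wavelet | union | intersection | manual
    threshold: float | None = 0.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(sorted(set(self.channels))))

    def __len__(self) -> int:
        return len(self.channels)


def r2_binary(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot of binary predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length with ≥ 2 elements")
    if np.all(y_true == y_true[0]):
        raise ValueError("R² is undefined for constant y_true")
    return float(r2_score(y_true, y_pred))


def single_channel_scores(table: FeatureTable, split: SplitSpec | None = None,
                          eye_states: Sequence[str] | None = None) -> list[ChannelScore]:
    """Score each channel by held-out single-channel linear-SVM classification.

    Channels with any invalid feature block are reported with
    ``missing_reason`` instead of a score.  Deterministic given the split
    seed.
    """
    split = split or SplitSpec()
    subjects = table.subjects
    labels = table.labels(subjects)
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    train, val = split.split(subjects, labels)
    states = tuple(eye_states) if eye_states is not None else table.eye_states
    bad_channels = {ch for (_, st, ch) in table.invalid if st in states}
    scores: list[ChannelScore] = []
    for ch in table.channels:
        if ch in bad_channels:
            scores.append(ChannelScore(ch, table.method, None, split.seed,
                                       missing_reason="invalid feature block"))
            continue
        X_tr, y_tr = table.matrix(train, channels=[ch], eye_states=states)
        X_va, y_va = table.matrix(val, channels=[ch], eye_states=states)
        scaler = StandardScaler().fit(X_tr)
        clf = SVC(kernel="linear")
        clf.fit(scaler.transform(X_tr), y_tr)
        pred = clf.predict(scaler.transform(X_va))
        scores.append(ChannelScore(ch, table.method, r2_binary(y_va, pred), split.seed))
    return scores


def select_channels(scores: Iterable[ChannelScore], threshold: float = 0.7,
                    name: str | None = None) -> SelectionScheme:
    """Keep channels whose R² score meets the threshold (score ≥ threshold)."""
    scores = list(scores)
    if not scores:
        raise ValueError("no channel scores given")
    method = scores[0].method
    kept = tuple(s.channel for s in scores if s.r2 is not None and s.r2 >= threshold)
    if not kept:
        warnings.warn(f"no channel reached R² ≥ {threshold}; selection is empty", stacklevel=2)
    return SelectionScheme(name or f"{method}-r2ge{threshold:g}", kept, provenance=method,
                           threshold=threshold)


def combine_schemes(a: SelectionScheme, b: SelectionScheme, mode: str) -> SelectionScheme:
    """Set union or intersection of two selections over the same channel universe."""
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    sa, sb = set(a.channels), set(b.channels)
    combined = sa | sb if mode == "union" else sa & sb
    return SelectionScheme(f"{mode}({a.name},{b.name})", tuple(combined),
                           provenance=mode, threshold=None)
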