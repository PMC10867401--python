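"""Sliding-window segmentation, majority labeling, and stratified splitting.

A 0.6 s window (120 samples) slides in 0.15 s steps (30 samples) over the
8-channel stream; each window becomes one classifier sample.  With circular
padding (default) a window starts at every multiple of the step, windows that
overrun the end wrap around to the start, and a single-posture record of
L samples yields exactly L/step windows — 18,000 samples -> 600 windows.
The strict non-wrapping mode drops incomplete windows instead
(floor((L - window)/step) + 1).

A window covering a posture change takes the label occupying more than half
of it; an exact tie goes to the later-occurring class (the more recent
evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .series import PressureSeries
from .synthetic import Posture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    window: int = 120
    step: int = 30
    majority_fraction: float = 0.5
    circular_pad: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("need 0 < step <= window")
        if not 0 < self.majority_fraction < 1:
            raise ValueError("majority_fraction must lie in (0, 1)")


@dataclass
class WindowSample:
    """One segmented window: (8, window) matrix, label, and provenance."""

    matrix: np.ndarray
    label: int
    origin: tuple[str, int]  # (series id, start index)


def label_window(annotations: np.ndarray, cfg: SegmentationConfig | None = None) -> int:
    """Majority label of a fully annotated window.

    The class covering more than ``majority_fraction`` of the window wins; on
    an exact tie (or several equally modal classes) the class whose last
    occurrence is latest in the window is chosen and the event is logged.
    """
    cfg = cfg or SegmentationConfig()
    annotations = np.asarray(annotations, dtype=int)
    if annotations.size == 0:
        raise ValueError("window has no annotations")
    codes, counts = np.unique(annotations, return_counts=True)
    top = counts.max()
    if top > cfg.majority_fraction * annotations.size and (counts == top).sum() == 1:
        return int(codes[np.argmax(counts)])
    modal = codes[counts == top]
    last_seen = {
        int(c): int(np.flatnonzero(annotations == c)[-1]) for c in modal
    }
    winner = max(last_seen, key=last_seen.get)
    logger.debug(
        "no single majority in window (modal classes %s); taking later class %d",
        sorted(last_seen),
        winner,
    )
    return winner


def segment(
    series: PressureSeries,
    cfg: SegmentationConfig | None = None,
    series_id: str = "series",
) -> list[WindowSample]:
    """Cut a series into labelled windows.

    Window matrices are (8, window) channel-major slices.  Requires the series
    to be at least one window long.
    """
    cfg = cfg or SegmentationConfig()
    n = series.n_samples
    if n < cfg.window:
        raise ValueError(f"series of {n} samples is shorter than the window")
    if cfg.circular_pad:
        starts = range(0, n, cfg.step)
    else:
        starts = range(0, n - cfg.window + 1, cfg.step)
    ann = series.annotation
    out = []
    for start in starts:
        idx = np.arange(start, start + cfg.window)
        if cfg.circular_pad:
            idx = idx % n
        matrix = series.values[idx].T.copy()
        label = label_window(ann[idx], cfg) if ann is not None else -1
        out.append(WindowSample(matrix=matrix, label=label, origin=(series_id, start)))
    return out


def windows_to_arrays(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, 8, window) data and (n,) label arrays."""
    X = np.stack([s.matrix for s in samples])
    y = np.array([s.label for s in samples])
    return X, y


@dataclass
class DatasetSplit:
    """Stratified 80/20 split plus 5 stratified folds over the training part.

    All index arrays refer to positions in the original sample list; folds are
    (train_part, validation_part) pairs partitioning ``train``.
    """

    train: np.ndarray
    test: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]


def make_split(
    labels: np.ndarray,
    seed: int,
    test_fraction: float = 0.2,
    n_folds: int = 5,
) -> DatasetSplit:
    """Deterministic stratified split: per-class 80/20 plus 5-fold CV folds.

    600 windows per class yield 480 training / 120 testing windows per class
    and five folds of 96 per class.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < n_folds):
        small = classes[counts < n_folds].tolist()
        raise ValueError(f"classes {small} have fewer than {n_folds} samples")
    rs = int(seed) % (2**31)
    idx = np.arange(labels.size)
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=rs
    )
    train = np.sort(train)
    test = np.sort(test)
    train_counts = np.unique(labels[train], return_counts=True)[1]
    if np.any(train_counts < n_folds):
        raise ValueError("a class has fewer training samples than folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
    folds = [
        (train[tr], train[va]) for tr, va in skf.split(train, labels[train])
    ]
    return DatasetSplit(train=train, test=test, folds=folds)
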