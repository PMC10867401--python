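"""Long-term foot-usage statistics.

Pressure exposure is partitioned into four clinical zones — low 0-50 kPa,
medium 50-200 kPa, high 200-400 kPa, very high >400 kPa — as left-closed
half-open intervals so every sample lands in exactly one zone and per-channel
zone times sum to the record duration exactly.  Mean regional load is reported
excluding the low zone (an unloaded-in-shoe sensor would otherwise drag the
average toward zero), and daily activity (steps, jumps, run steps, distance,
calories) is derived from heel-channel peak counting within annotated
movement bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .series import N_CHANNELS, PressureSeries
from .synthetic import Posture, base_posture

ZONE_NAMES = ("LOW", "MEDIUM", "HIGH", "VERY_HIGH")


@dataclass(frozen=True)
class PressureZoneScheme:
    """Zone boundaries in kPa; intervals are [0,b0), [b0,b1), [b1,b2), [b2,inf)."""

    boundaries: tuple[float, float, float] = (50.0, 200.0, 400.0)
    zone_names: tuple[str, ...] = ZONE_NAMES

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(self.boundaries) or len(
            set(self.boundaries)
        ) != 3:
            raise ValueError("boundaries must be strictly increasing")
        if len(self.zone_names) != 4:
            raise ValueError("exactly four zones")


def zone_assign(p, scheme: PressureZoneScheme | None = None):
    """Zone index (0=LOW .. 3=VERY_HIGH) of a pressure or array of pressures."""
    scheme = scheme or PressureZoneScheme()
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative")
    idx = np.searchsorted(np.asarray(scheme.boundaries), p, side="right")
    return int(idx) if idx.ndim == 0 else idx


@dataclass
class ZoneStats:
    """Per-channel zone occupancy (seconds) plus derived summaries."""

    per_channel_per_zone_time: np.ndarray  # (8, 4) seconds
    high_pressure_time: np.ndarray  # (8,) seconds, HIGH + VERY_HIGH
    mean_pressure_excl_low: np.ndarray  # (8,) kPa
    low_only_channels: np.ndarray  # (8,) bool, no sample ever left the low zone
    scheme: PressureZoneScheme = field(default_factory=PressureZoneScheme)


def zone_histogram(
    series: PressureSeries, scheme: PressureZoneScheme | None = None
) -> ZoneStats:
    """Time spent by each channel in each pressure zone.

    Durations are sample counts over the sampling rate; for every channel the
    four zone times sum exactly to the record duration.
    """
    scheme = scheme or PressureZoneScheme()
    zones = zone_assign(series.values, scheme)  # (n, 8)
    counts = np.stack(
        [(zones == z).sum(axis=0) for z in range(4)], axis=1
    )  # (8, 4)
    times = counts / series.sample_rate
    means, flags = mean_pressure_excluding_low(series, scheme.boundaries[0])
    return ZoneStats(
        per_channel_per_zone_time=times,
        high_pressure_time=times[:, 2] + times[:, 3],
        mean_pressure_excl_low=means,
        low_only_channels=flags,
        scheme=scheme,
    )


def high_pressure_time(series: PressureSeries, threshold: float = 200.0) -> np.ndarray:
    """Per-channel seconds at or above ``threshold`` kPa.

    The comparison is left-closed (>=) to match the zone partition, so at the
    default threshold this equals the HIGH + VERY_HIGH zone time exactly.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (series.values >= threshold).sum(axis=0) / series.sample_rate


def mean_pressure_excluding_low(
    series: PressureSeries, low_boundary: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean over samples outside the low zone (>= 50 kPa).

    Returns ``(means, flags)``; a channel with no qualifying sample reports a
    mean of 0 and is flagged.
    """
    qualifying = series.values >= low_boundary
    counts = qualifying.sum(axis=0)
    sums = np.where(qualifying, series.values, 0.0).sum(axis=0)
    flags = counts == 0
    means = np.divide(sums, counts, out=np.zeros(N_CHANNELS), where=~flags)
    return means, flags


def posture_time(series: PressureSeries) -> dict[Posture, float]:
    """Seconds annotated per posture; sums to the record duration."""
    if series.annotation is None:
        raise ValueError(
            "series carries no posture annotation; classify or annotate first"
        )
    codes, counts = np.unique(series.annotation, return_counts=True)
    return {Posture(int(c)): n / series.sample_rate for c, n in zip(codes, counts)}


@dataclass(frozen=True)
class UserProfile:
    """Wearer anthropometrics used by the activity report."""

    body_mass: float  # kg
    stride_length: float  # m
    foot_length: float = 0.26  # m

    def __post_init__(self) -> None:
        if min(self.body_mass, self.stride_length, self.foot_length) <= 0:
            raise ValueError("profile values must be strictly positive")


#: Metabolic equivalents per movement, used in the kcal estimate.
MET = {Posture.STAND: 1.3, Posture.WALK: 3.5, Posture.RUN: 8.0, Posture.JUMP: 10.0}

# heel channels S7, S8
_HEEL = (6, 7)


@dataclass
class ActivityReport:
    steps: int
    jumps: int
    run_steps: int
    distance: float  # m
    calories: float  # kcal
    posture_time: dict[Posture, float]


def _count_peaks_in_bouts(
    heel: np.ndarray,
    labels: np.ndarray,
    target: Posture,
    fs: float,
    height: float,
    refractory_s: float,
) -> int:
    """Heel-strike count within contiguous bouts of one movement class
    (fatigued variants count toward their base movement)."""
    mapped = np.array([int(base_posture(Posture(v))) for v in labels])
    mask = mapped == int(target)
    if not mask.any():
        return 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    distance = max(int(round(refractory_s * fs)), 1)
    total = 0
    for start, stop in zip(edges[::2], edges[1::2]):
        peaks, _ = find_peaks(heel[start:stop], height=height, distance=distance)
        total += len(peaks)
    return total


def activity_report(
    series: PressureSeries,
    profile: UserProfile,
    labels: np.ndarray | None = None,
    peak_height: float = 100.0,
    refractory_s: float = 0.3,
) -> ActivityReport:
    """Daily activity metrics from an annotated (or classified) record.

    Steps / run steps / jumps are local maxima of the stronger heel channel
    above ``peak_height`` kPa, at least ``refractory_s`` apart, inside bouts
    labelled WALK / RUN / JUMP respectively.  Distance is
    (steps + run_steps) * stride_length; calories use a MET model
    (kcal = MET * mass * hours * 1.05) and are an estimate, not a measurement.
    """
    if profile is None:
        raise ValueError("a UserProfile is required")
    if labels is None:
        labels = series.annotation
    if labels is None:
        raise ValueError("series must be annotated or labels supplied")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (series.n_samples,):
        raise ValueError("labels length must match the series")

    heel = series.values[:, list(_HEEL)].max(axis=1)
    fs = series.sample_rate
    steps = _count_peaks_in_bouts(
        heel, labels, Posture.WALK, fs, peak_height, refractory_s
    )
    run_steps = _count_peaks_in_bouts(
        heel, labels, Posture.RUN, fs, peak_height, refractory_s
    )
    jumps = _count_peaks_in_bouts(
        heel, labels, Posture.JUMP, fs, peak_height, refractory_s
    )

    annotated = PressureSeries(series.values, fs, labels)
    times = posture_time(annotated)
    calories = 0.0
    for posture, seconds in times.items():
        met = MET.get(base_posture(posture))
        if met is not None:
            calories += met * profile.body_mass * (seconds / 3600.0) * 1.05
    return ActivityReport(
        steps=steps,
        jumps=jumps,
        run_steps=run_steps,
        distance=(steps + run_steps) * profile.stride_length,
        calories=calories,
        posture_time=times,
    )
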