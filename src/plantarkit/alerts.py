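"""Rule-based foot-health alerts, offline and streaming.

Rules (thresholds configurable via :class:`AlertRuleSet`):

* HIGH_PRESSURE_SPIKE — any channel exceeds 500 kPa; one event per maximal
  run of offending frames.
* HIGH_PRESSURE_SUSTAINED — a channel stays above 200 kPa for more than 30 s
  continuously (a run of exactly 30 s raises nothing).
* UNEVEN_PRESSURE — the left/right imbalance |P_L - P_R| / max(P_L, P_R) of
  the metatarsal+heel pairs (S6, S7) vs (S1, S8) exceeds 45 % for at least
  1 s.  Larger-side normalization is the default denominator.
* OVERUSE — the foot stays loaded (any channel at or above the 0.4 kPa
  detection limit) for more than 30 min without a break.
* FATIGUE — the window classifier reports a fatigued class for at least
  3 consecutive windows.

Two independent evaluation routes are provided: :func:`scan_alerts` is a
vectorized offline pass over a whole record, while :class:`AlertMonitor` /
:func:`monitor_stream` keep bounded per-frame state and emit the same events
incrementally (an event is emitted once its run ends, or at end of stream).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .mapping import LEFT_PAIR, RIGHT_PAIR
from .series import PressureSeries
from .synthetic import Posture, is_fatigued


class AlertKind(enum.Enum):
    HIGH_PRESSURE_SPIKE = "HIGH_PRESSURE_SPIKE"
    HIGH_PRESSURE_SUSTAINED = "HIGH_PRESSURE_SUSTAINED"
    UNEVEN_PRESSURE = "UNEVEN_PRESSURE"
    OVERUSE = "OVERUSE"
    FATIGUE = "FATIGUE"


@dataclass(frozen=True)
class AlertRuleSet:
    spike_threshold: float = 500.0  # kPa
    sustained_threshold: float = 200.0  # kPa
    sustained_duration: float = 30.0  # s, strictly-more-than
    asymmetry_fraction: float = 0.45
    asymmetry_min_duration: float = 1.0  # s, at-least
    overuse_duration: float = 1800.0  # s, strictly-more-than
    activity_threshold: float = 0.4  # kPa, the sensor detection limit
    fatigue_min_windows: int = 3
    fatigue_classes: frozenset = frozenset(
        {Posture.WALK_FATIGUED, Posture.RUN_FATIGUED, Posture.JUMP_FATIGUED}
    )

    def __post_init__(self) -> None:
        if self.sustained_threshold >= self.spike_threshold:
            raise ValueError("sustained threshold must lie below the spike threshold")
        if not 0 < self.asymmetry_fraction < 1:
            raise ValueError("asymmetry fraction must lie in (0, 1)")
        if min(
            self.spike_threshold,
            self.sustained_duration,
            self.overuse_duration,
            self.activity_threshold,
        ) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class AlertEvent:
    kind: AlertKind
    onset: float  # s
    duration: float  # s
    channels: tuple[int, ...]  # involved sensor indices (0-based)
    peak_value: float  # kPa, or imbalance fraction for UNEVEN_PRESSURE

    def sort_key(self):
        return (self.onset, self.kind.value, self.channels)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as [start, stop) pairs."""
    edges = np.flatnonzero(
        np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    )
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _imbalance(values: np.ndarray) -> np.ndarray:
    """Per-frame left/right imbalance fraction (larger-side denominator)."""
    left = values[:, list(LEFT_PAIR)].mean(axis=1)
    right = values[:, list(RIGHT_PAIR)].mean(axis=1)
    denom = np.maximum(left, right)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.abs(left - right) / denom
    ratio[denom == 0] = 0.0
    return ratio


def scan_alerts(
    series: PressureSeries,
    rules: AlertRuleSet | None = None,
    window_labels: np.ndarray | None = None,
    window_step: int = 30,
    window_length: int = 120,
) -> list[AlertEvent]:
    """Offline alert scan over a calibrated record (vectorized).

    ``window_labels`` optionally supplies the classifier's per-window posture
    codes (window ``i`` starting at sample ``i * window_step``), enabling the
    FATIGUE rule.  Events are returned ordered by onset.
    """
    rules = rules or AlertRuleSet()
    if series.unit != "kPa":
        raise ValueError("series must be calibrated to kPa before alert scanning")
    fs = series.sample_rate
    v = series.values
    events: list[AlertEvent] = []

    # spikes: any-channel exceedance, one event per maximal frame run
    spike_mask = (v > rules.spike_threshold).any(axis=1)
    for start, stop in _runs(spike_mask):
        seg = v[start:stop]
        chans = np.flatnonzero((seg > rules.spike_threshold).any(axis=0))
        events.append(
            AlertEvent(
                AlertKind.HIGH_PRESSURE_SPIKE,
                onset=start / fs,
                duration=(stop - start) / fs,
                channels=tuple(int(c) for c in chans),
                peak_value=float(seg.max()),
            )
        )

    # sustained high pressure, per channel
    for ch in range(v.shape[1]):
        for start, stop in _runs(v[:, ch] > rules.sustained_threshold):
            if (stop - start) / fs > rules.sustained_duration:
                events.append(
                    AlertEvent(
                        AlertKind.HIGH_PRESSURE_SUSTAINED,
                        onset=start / fs,
                        duration=(stop - start) / fs,
                        channels=(ch,),
                        peak_value=float(v[start:stop, ch].max()),
                    )
                )

    # uneven left/right loading
    ratio = _imbalance(v)
    for start, stop in _runs(ratio > rules.asymmetry_fraction):
        if (stop - start) / fs >= rules.asymmetry_min_duration:
            events.append(
                AlertEvent(
                    AlertKind.UNEVEN_PRESSURE,
                    onset=start / fs,
                    duration=(stop - start) / fs,
                    channels=tuple(sorted(LEFT_PAIR + RIGHT_PAIR)),
                    peak_value=float(ratio[start:stop].max()),
                )
            )

    # overuse: continuous loading beyond the rest limit
    loaded = (v >= rules.activity_threshold).any(axis=1)
    for start, stop in _runs(loaded):
        if (stop - start) / fs > rules.overuse_duration:
            events.append(
                AlertEvent(
                    AlertKind.OVERUSE,
                    onset=start / fs,
                    duration=(stop - start) / fs,
                    channels=tuple(range(v.shape[1])),
                    peak_value=float(v[start:stop].max()),
                )
            )

    # fatigue: consecutive fatigued window labels
    if window_labels is not None:
        codes = np.asarray(window_labels, dtype=int)
        fatigued = np.array(
            [is_fatigued(Posture(int(c))) for c in codes], dtype=bool
        )
        for start, stop in _runs(fatigued):
            if stop - start >= rules.fatigue_min_windows:
                onset = start * window_step / fs
                dur = ((stop - 1 - start) * window_step + window_length) / fs
                events.append(
                    AlertEvent(
                        AlertKind.FATIGUE,
                        onset=onset,
                        duration=dur,
                        channels=(),
                        peak_value=float(stop - start),
                    )
                )

    events.sort(key=AlertEvent.sort_key)
    return events


class AlertMonitor:
    """Streaming rule engine with bounded per-frame state.

    Feed frames through :meth:`process_frame`; each call returns the events
    whose runs just ended.  Call :meth:`finalize` at end of stream to flush
    still-open runs.  On identical data the emitted set equals
    :func:`scan_alerts`.
    """

    def __init__(self, rules: AlertRuleSet | None = None, sample_rate: float = 200.0):
        self.rules = rules or AlertRuleSet()
        self.fs = sample_rate
        self._i = 0
        self._last_t: float | None = None
        # open-run state: start index, peak, and involved channels
        self._spike: list | None = None
        self._sust: list[list | None] = [None] * 8
        self._uneven: list | None = None
        self._overuse: list | None = None

    # -- helpers -------------------------------------------------------
    def _close_spike(self) -> AlertEvent:
        start, peak, chans = self._spike
        self._spike = None
        return AlertEvent(
            AlertKind.HIGH_PRESSURE_SPIKE,
            onset=start / self.fs,
            duration=(self._i - start) / self.fs,
            channels=tuple(sorted(chans)),
            peak_value=peak,
        )

    def _close_sustained(self, ch: int) -> AlertEvent | None:
        start, peak = self._sust[ch]
        self._sust[ch] = None
        if (self._i - start) / self.fs > self.rules.sustained_duration:
            return AlertEvent(
                AlertKind.HIGH_PRESSURE_SUSTAINED,
                onset=start / self.fs,
                duration=(self._i - start) / self.fs,
                channels=(ch,),
                peak_value=peak,
            )
        return None

    def _close_uneven(self) -> AlertEvent | None:
        start, peak = self._uneven
        self._uneven = None
        if (self._i - start) / self.fs >= self.rules.asymmetry_min_duration:
            return AlertEvent(
                AlertKind.UNEVEN_PRESSURE,
                onset=start / self.fs,
                duration=(self._i - start) / self.fs,
                channels=tuple(sorted(LEFT_PAIR + RIGHT_PAIR)),
                peak_value=peak,
            )
        return None

    def _close_overuse(self) -> AlertEvent | None:
        start, peak = self._overuse
        self._overuse = None
        if (self._i - start) / self.fs > self.rules.overuse_duration:
            return AlertEvent(
                AlertKind.OVERUSE,
                onset=start / self.fs,
                duration=(self._i - start) / self.fs,
                channels=tuple(range(8)),
                peak_value=peak,
            )
        return None

    # ------------------------------------------------------------------
    def process_frame(self, t: float, frame: np.ndarray) -> list[AlertEvent]:
        if self._last_t is not None and t <= self._last_t:
            raise ValueError(f"out-of-order timestamp {t} after {self._last_t}")
        self._last_t = t
        frame = np.asarray(frame, dtype=float)
        rules = self.rules
        out: list[AlertEvent] = []

        over = frame > rules.spike_threshold
        if over.any():
            if self._spike is None:
                self._spike = [self._i, float(frame.max()), set()]
            self._spike[1] = max(self._spike[1], float(frame.max()))
            self._spike[2].update(int(c) for c in np.flatnonzero(over))
        elif self._spike is not None:
            out.append(self._close_spike())

        for ch in range(frame.size):
            if frame[ch] > rules.sustained_threshold:
                if self._sust[ch] is None:
                    self._sust[ch] = [self._i, float(frame[ch])]
                else:
                    self._sust[ch][1] = max(self._sust[ch][1], float(frame[ch]))
            elif self._sust[ch] is not None:
                evt = self._close_sustained(ch)
                if evt:
                    out.append(evt)

        ratio = float(_imbalance(frame[None, :])[0])
        if ratio > rules.asymmetry_fraction:
            if self._uneven is None:
                self._uneven = [self._i, ratio]
            self._uneven[1] = max(self._uneven[1], ratio)
        elif self._uneven is not None:
            evt = self._close_uneven()
            if evt:
                out.append(evt)

        if (frame >= rules.activity_threshold).any():
            if self._overuse is None:
                self._overuse = [self._i, float(frame.max())]
            self._overuse[1] = max(self._overuse[1], float(frame.max()))
        elif self._overuse is not None:
            evt = self._close_overuse()
            if evt:
                out.append(evt)

        self._i += 1
        return out

    def finalize(self) -> list[AlertEvent]:
        out: list[AlertEvent] = []
        if self._spike is not None:
            out.append(self._close_spike())
        for ch in range(8):
            if self._sust[ch] is not None:
                evt = self._close_sustained(ch)
                if evt:
                    out.append(evt)
        if self._uneven is not None:
            evt = self._close_uneven()
            if evt:
                out.append(evt)
        if self._overuse is not None:
            evt = self._close_overuse()
            if evt:
                out.append(evt)
        return out


def monitor_stream(
    frames: Iterable[tuple[float, np.ndarray]],
    rules: AlertRuleSet | None = None,
    sample_rate: float = 200.0,
) -> Iterator[AlertEvent]:
    """Incremental alert emission over ``(timestamp, frame)`` pairs.

    Yields each event as its run ends; flushes open runs when the iterator is
    exhausted.  Timestamps must be strictly increasing.
    """
    monitor = AlertMonitor(rules, sample_rate)
    for t, frame in frames:
        yield from monitor.process_frame(t, frame)
    yield from monitor.finalize()
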