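"""Seeded synthetic 8-channel plantar-pressure gait generator.

Stands in for the insole hardware: each locomotor posture is a periodic
template of 120 samples per gait cycle (200 Hz), with per-cycle amplitude and
phase jitter and additive Gaussian noise.  Load is concentrated in the
metatarsal (S1, S3, S6) and heel (S7, S8) channels, midfoot (S4) and toe
(S2, S5) channels carry less — the qualitative pattern seen on a real sole.

Fatigued variants of walking, running and jumping keep the waveform shape but
lose peak amplitude (0.8x) and gain cycle-timing variability (1.5x phase
jitter): a tired gait is flatter and less regular.  Standing has no cycle
structure at all — constant load plus noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .config import CYCLE_LENGTH, SAMPLE_RATE_HZ
from .series import N_CHANNELS, PressureSeries, concatenate


class Posture(enum.IntEnum):
    """Posture codes.  STAND is generator/statistics-only; the six locomotor
    codes (normal and fatigued walking/running/jumping) are the classifier's
    label set."""

    STAND = 0
    WALK = 1
    RUN = 2
    JUMP = 3
    WALK_FATIGUED = 4
    RUN_FATIGUED = 5
    JUMP_FATIGUED = 6


#: The six classes that participate in classification.
CLASSIFICATION_POSTURES: tuple[Posture, ...] = (
    Posture.WALK,
    Posture.RUN,
    Posture.JUMP,
    Posture.WALK_FATIGUED,
    Posture.RUN_FATIGUED,
    Posture.JUMP_FATIGUED,
)

_FATIGUE_OF = {
    Posture.WALK_FATIGUED: Posture.WALK,
    Posture.RUN_FATIGUED: Posture.RUN,
    Posture.JUMP_FATIGUED: Posture.JUMP,
}

#: Amplitude attenuation of the fatigued variants.
FATIGUE_AMPLITUDE = 0.8
#: Phase-jitter inflation of the fatigued variants.
FATIGUE_PHASE_FACTOR = 1.5


def base_posture(posture: Posture) -> Posture:
    """Map a fatigued code to its underlying movement (WALK_FATIGUED -> WALK)."""
    return _FATIGUE_OF.get(posture, posture)


def is_fatigued(posture: Posture) -> bool:
    return posture in _FATIGUE_OF


@dataclass
class GaitTemplate:
    """One posture's noise-free cycle waveform plus its stochastic parameters.

    ``waveform`` is (8, cycle_length) in kPa; ``phase_jitter`` is the standard
    deviation of the per-cycle circular shift as a fraction of the cycle.
    """

    posture: Posture
    waveform: np.ndarray
    amplitude_jitter: float = 0.05
    phase_jitter: float = 0.02
    noise_sd: float = 5.0
    cycle_length: int = CYCLE_LENGTH

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.shape != (N_CHANNELS, self.cycle_length):
            raise ValueError(
                f"waveform must be ({N_CHANNELS}, {self.cycle_length})"
            )
        if np.any(self.waveform < 0) or np.any(self.waveform > 500):
            raise ValueError("template pressures must lie in [0, 500] kPa")


# Peak channel load (kPa) per posture, channels S1..S8.  Metatarsal (S1,S3,S6)
# and heel (S7,S8) dominate; midfoot (S4) and toes (S2,S5) stay light.
_PEAKS = {
    Posture.STAND: (90.0, 30.0, 95.0, 40.0, 35.0, 85.0, 110.0, 105.0),
    Posture.WALK: (220.0, 80.0, 240.0, 60.0, 90.0, 210.0, 260.0, 250.0),
    Posture.RUN: (330.0, 120.0, 360.0, 80.0, 130.0, 310.0, 380.0, 370.0),
    Posture.JUMP: (400.0, 140.0, 420.0, 90.0, 150.0, 390.0, 430.0, 420.0),
}

# (burst start, burst width) as cycle fractions, per channel group: the
# stance rolls heel -> midfoot -> metatarsus -> toe.
_TIMING = {
    Posture.WALK: {
        "heel": (0.05, 0.35),
        "midfoot": (0.25, 0.35),
        "meta": (0.45, 0.35),
        "toe": (0.62, 0.30),
    },
    Posture.RUN: {
        "heel": (0.02, 0.22),
        "midfoot": (0.14, 0.22),
        "meta": (0.26, 0.24),
        "toe": (0.38, 0.22),
    },
    # jump: take-off push on forefoot, airborne gap, landing spike everywhere
    Posture.JUMP: None,
}

_GROUP = {
    0: "meta",  # S1
    1: "toe",  # S2
    2: "meta",  # S3
    3: "midfoot",  # S4
    4: "toe",  # S5
    5: "meta",  # S6
    6: "heel",  # S7
    7: "heel",  # S8
}


def _half_sine(t: np.ndarray, start: float, width: float, amp: float) -> np.ndarray:
    """Half-sine burst of height ``amp`` on cycle fraction [start, start+width]."""
    phase = (t - start) / width
    burst = np.sin(np.pi * np.clip(phase, 0.0, 1.0))
    burst[(phase < 0) | (phase > 1)] = 0.0
    return amp * burst


def default_template(posture: Posture, noise_sd: float = 5.0) -> GaitTemplate:
    """Build the default cycle template for a posture."""
    posture = Posture(posture)
    base = base_posture(posture)
    peaks = np.array(_PEAKS[base])
    if is_fatigued(posture):
        peaks = peaks * FATIGUE_AMPLITUDE
    wave = np.zeros((N_CHANNELS, CYCLE_LENGTH))
    t = (np.arange(CYCLE_LENGTH) + 0.5) / CYCLE_LENGTH

    if base is Posture.STAND:
        wave[:] = peaks[:, None]
    elif base is Posture.JUMP:
        for ch in range(N_CHANNELS):
            takeoff = 1.0 if _GROUP[ch] in ("meta", "toe") else 0.45
            wave[ch] = _half_sine(t, 0.10, 0.16, 0.75 * peaks[ch] * takeoff)
            wave[ch] += _half_sine(t, 0.55, 0.18, peaks[ch])
    else:
        timing = _TIMING[base]
        for ch in range(N_CHANNELS):
            start, width = timing[_GROUP[ch]]
            wave[ch] = _half_sine(t, start, width, peaks[ch])

    phase_jitter = 0.02 * (FATIGUE_PHASE_FACTOR if is_fatigued(posture) else 1.0)
    return GaitTemplate(
        posture=posture,
        waveform=np.clip(wave, 0.0, 500.0),
        phase_jitter=phase_jitter,
        noise_sd=noise_sd,
    )


def default_templates(noise_sd: float = 5.0) -> dict[Posture, GaitTemplate]:
    return {p: default_template(p, noise_sd) for p in Posture}


def _render_cycles(
    template: GaitTemplate, n_cycles: int, rng: np.random.Generator
) -> np.ndarray:
    """Stack jittered cycles; returns (n_cycles * cycle_length, 8)."""
    L = template.cycle_length
    out = np.empty((n_cycles * L, N_CHANNELS))
    is_static = template.posture is Posture.STAND
    for c in range(n_cycles):
        cyc = template.waveform
        if not is_static:
            amp = 1.0 + template.amplitude_jitter * rng.standard_normal()
            shift = int(round(template.phase_jitter * L * rng.standard_normal()))
            cyc = np.roll(cyc * max(amp, 0.0), shift, axis=1)
        out[c * L : (c + 1) * L] = cyc.T
    if template.noise_sd > 0:
        out += rng.normal(0.0, template.noise_sd, out.shape)
    return np.clip(out, 0.0, None)


def generate_posture_series(
    posture: Posture,
    n_cycles: int,
    seed: int | np.random.Generator,
    template: GaitTemplate | None = None,
    sample_rate: float = SAMPLE_RATE_HZ,
) -> PressureSeries:
    """Generate ``n_cycles`` gait cycles of one posture (annotated, seeded).

    The output has exactly ``n_cycles * 120`` frames.  Equal (inputs, seed)
    give bit-identical arrays.
    """
    posture = Posture(posture)
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if template is None:
        template = default_template(posture)
    if template.posture != posture:
        raise ValueError(
            f"template is for {template.posture.name}, not {posture.name}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = _render_cycles(template, n_cycles, rng)
    ann = np.full(values.shape[0], int(posture))
    return PressureSeries(values, sample_rate, ann)


def generate_mixed_session(
    schedule: list[tuple[Posture, float]],
    seed: int | np.random.Generator,
    templates: dict[Posture, GaitTemplate] | None = None,
    sample_rate: float = SAMPLE_RATE_HZ,
) -> PressureSeries:
    """Concatenate posture segments of given durations (seconds).

    Each segment contributes ``round(duration * sample_rate)`` frames with its
    posture annotation; cyclic postures are tiled from whole cycles and
    truncated to the exact frame count.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if templates is None:
        templates = default_templates()
    parts = []
    for posture, duration in schedule:
        posture = Posture(posture)
        if duration <= 0:
            raise ValueError("durations must be positive")
        n = int(round(duration * sample_rate))
        tpl = templates[posture]
        n_cycles = max(1, -(-n // tpl.cycle_length))  # ceil
        seg = _render_cycles(tpl, n_cycles, rng)[:n]
        parts.append(
            PressureSeries(seg, sample_rate, np.full(n, int(posture)))
        )
    return concatenate(parts)


class EventKind(enum.Enum):
    """Injectable anomalies used to exercise the alert rules."""

    SPIKE_500 = "SPIKE_500"
    SUSTAINED_200 = "SUSTAINED_200"
    ASYMMETRY_45 = "ASYMMETRY_45"


# channel indices used by the asymmetry rule: S6,S7 vs S1,S8
_LEFT = (5, 6)
_RIGHT = (0, 7)


def inject_event(
    series: PressureSeries,
    event: EventKind | str,
    at: float,
    duration: float = 0.0,
) -> PressureSeries:
    """Return a copy of ``series`` with an anomaly written into it.

    SPIKE_500 sets one heel channel above 500 kPa for a single frame;
    SUSTAINED_200 holds one channel at 210 kPa for ``duration`` seconds;
    ASYMMETRY_45 triples the S6/S7 pair (and floors it at 150 kPa against a
    50 kPa opposite side) so the left/right imbalance exceeds 45 %.
    """
    event = EventKind(event)
    fs = series.sample_rate
    start = int(round(at * fs))
    n_frames = 1 if event is EventKind.SPIKE_500 else int(round(duration * fs))
    if duration < 0 or at < 0 or start + n_frames > series.n_samples:
        raise ValueError("event window out of series range")
    if n_frames == 0 and event is not EventKind.SPIKE_500:
        return series
    values = series.values.copy()
    if event is EventKind.SPIKE_500:
        values[start, 6] = 520.0
    elif event is EventKind.SUSTAINED_200:
        sl = slice(start, start + n_frames)
        values[sl, 6] = np.maximum(values[sl, 6], 210.0)
    else:  # ASYMMETRY_45
        sl = slice(start, start + n_frames)
        left = np.maximum(values[sl][:, _LEFT] * 3.0, 150.0)
        values[np.arange(start, start + n_frames)[:, None], _LEFT] = left
        values[np.arange(start, start + n_frames)[:, None], _RIGHT] = np.minimum(
            values[sl][:, _RIGHT], 50.0
        )
    return PressureSeries(
        values, series.sample_rate, series.annotation, series.unit, series.channels
    )
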