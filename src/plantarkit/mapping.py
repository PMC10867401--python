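"""Full-foot pressure surfaces from 8 discrete sensors, and static pronation.

Eight scattered points cannot parameterize a tensor-product spline directly,
so the surface is built in two stages: a thin-plate-spline scattered
interpolant (exact at the sensor sites) is evaluated onto a rectilinear
auxiliary grid whose lines pass through every sensor coordinate, and a cubic
B-spline surface is then fitted through that grid (``s=0``, interpolating).
Because each sensor sits on an auxiliary grid node, the spline surface
reproduces every sensor reading exactly while staying smooth in between.
The fine evaluation grid is clipped at 0 kPa and masked to an insole-shaped
silhouette.

Static standing posture is classified from left/right load balance of the
metatarsal+heel sensor pairs (S6, S7) vs (S1, S8):

    asymmetry_index = (P_left - P_right) / (P_left + P_right)

|index| <= threshold (default 0.15) is a normal stance; beyond that, the side
convention in the layout decides underpronation (lateral overload) vs
overpronation (medial overload).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import RBFInterpolator, RectBivariateSpline
from shapely.geometry import Polygon

from .config import CHANNELS, DEFAULT_CONFIG
from .series import N_CHANNELS, PressureSeries

# anatomical region of each channel, S1..S8
_REGIONS = (
    "metatarsus",
    "toe",
    "metatarsus",
    "midfoot",
    "toe",
    "metatarsus",
    "heel",
    "heel",
)


class Side(enum.Enum):
    LEFT_OF_AXIS = "LEFT_OF_AXIS"
    RIGHT_OF_AXIS = "RIGHT_OF_AXIS"


_SIDES = (
    Side.RIGHT_OF_AXIS,  # S1
    Side.RIGHT_OF_AXIS,  # S2
    Side.RIGHT_OF_AXIS,  # S3
    Side.LEFT_OF_AXIS,  # S4
    Side.LEFT_OF_AXIS,  # S5
    Side.LEFT_OF_AXIS,  # S6
    Side.LEFT_OF_AXIS,  # S7
    Side.RIGHT_OF_AXIS,  # S8
)

# channel indices entering the pronation / uneven-load comparison
LEFT_PAIR = (5, 6)  # S6 (metatarsal), S7 (heel)
RIGHT_PAIR = (0, 7)  # S1 (metatarsal), S8 (heel)

# insole silhouette in the normalized frame (x across sole, y heel -> toe)
_OUTLINE = np.array(
    [
        (0.50, 0.02),
        (0.68, 0.05),
        (0.76, 0.15),
        (0.74, 0.30),
        (0.70, 0.45),
        (0.76, 0.58),
        (0.80, 0.72),
        (0.74, 0.88),
        (0.58, 0.97),
        (0.40, 0.96),
        (0.26, 0.88),
        (0.22, 0.72),
        (0.28, 0.58),
        (0.34, 0.45),
        (0.30, 0.30),
        (0.32, 0.12),
    ]
)


@dataclass
class SensorLayout:
    """Identities, anatomical regions, sides, and 2-D insole coordinates."""

    xy: np.ndarray
    sensor_ids: tuple[str, ...] = CHANNELS
    regions: tuple[str, ...] = _REGIONS
    sides: tuple[Side, ...] = _SIDES
    left_is_medial: bool = False
    outline: np.ndarray = field(default_factory=lambda: _OUTLINE.copy())

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (N_CHANNELS, 2):
            raise ValueError(f"xy must be ({N_CHANNELS}, 2)")
        if np.any(self.xy < 0) or np.any(self.xy > 1):
            raise ValueError("coordinates must lie in the unit square")
        if len(set(self.sensor_ids)) != N_CHANNELS:
            raise ValueError("sensor ids must be unique")


def default_layout(config: dict | None = None) -> SensorLayout:
    cfg = (config or DEFAULT_CONFIG)["layout"]
    xy = np.array([cfg["coordinates"][ch] for ch in CHANNELS])
    return SensorLayout(xy=xy, left_is_medial=bool(cfg["left_is_medial"]))


@dataclass
class PressureMap:
    """A dense pressure surface over the insole silhouette.

    ``grid[i, j]`` holds the pressure at x = xs[j], y = ys[i]; cells outside
    the mask are zero.  ``value_at`` evaluates the underlying spline surface
    continuously (clipped at 0 kPa).
    """

    grid: np.ndarray
    mask: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    resolution: int
    ceiling: float = np.inf
    _spline: RectBivariateSpline | None = None

    def value_at(self, x: float, y: float) -> float:
        if self._spline is None:
            raise ValueError("map does not carry its surface")
        return float(np.clip(self._spline(x, y)[0, 0], 0.0, self.ceiling))

    @property
    def mask_fraction(self) -> float:
        return float(self.mask.mean())


def _mask_for(layout: SensorLayout, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    poly = Polygon(layout.outline)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    return inside.reshape(gy.shape)


def _aux_axis(coords: np.ndarray, n_base: int = 17) -> np.ndarray:
    """Uniform axis nodes merged with sensor coordinates (near-duplicates of a
    sensor coordinate are dropped so the spline knots stay well separated)."""
    base = np.linspace(0.0, 1.0, n_base)
    keep = base[np.min(np.abs(base[:, None] - coords[None, :]), axis=1) > 1e-6]
    return np.unique(np.concatenate([keep, coords]))


def interpolate_map(
    frame: np.ndarray,
    layout: SensorLayout | None = None,
    resolution: int = 60,
) -> PressureMap:
    """Interpolate one 8-sensor frame to a full-foot surface.

    The returned surface equals each sensor reading at the sensor's
    coordinate and is masked to the insole outline.  Away from the sensors
    the scattered interpolant can over- and undershoot, so the rendered
    surface is clamped to [0, 1.25 x max reading]: a physical floor and an
    explicit ceiling on extrapolation overshoot near the insole rim.
    """
    layout = layout or default_layout()
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (N_CHANNELS,):
        raise ValueError(f"frame must have {N_CHANNELS} values")
    if not np.all(np.isfinite(frame)) or np.any(frame < 0):
        raise ValueError("pressures must be finite and non-negative")
    if resolution < 8:
        raise ValueError("resolution must be >= 8 cells")
    d2 = np.sum((layout.xy[:, None] - layout.xy[None, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    if np.min(d2) < 1e-12:
        raise ValueError("coincident sensor coordinates")

    rbf = RBFInterpolator(layout.xy, frame, kernel="thin_plate_spline")
    ax_x = _aux_axis(layout.xy[:, 0])
    ax_y = _aux_axis(layout.xy[:, 1])
    gx, gy = np.meshgrid(ax_x, ax_y, indexing="ij")
    aux = rbf(np.column_stack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    spline = RectBivariateSpline(ax_x, ax_y, aux, kx=3, ky=3, s=0)

    xs = np.linspace(0.0, 1.0, resolution)
    ys = np.linspace(0.0, 1.0, resolution)
    ceiling = 1.25 * float(frame.max()) if frame.max() > 0 else 0.0
    grid = np.clip(spline(xs, ys).T, 0.0, ceiling)  # (y, x) orientation
    mask = _mask_for(layout, xs, ys)
    grid = np.where(mask, grid, 0.0)
    return PressureMap(grid, mask, xs, ys, resolution, ceiling, spline)


class PronationLabel(enum.Enum):
    NORMAL = "NORMAL"
    UNDERPRONATION = "UNDERPRONATION"
    OVERPRONATION = "OVERPRONATION"


@dataclass(frozen=True)
class PronationResult:
    label: PronationLabel
    asymmetry_index: float


def classify_pronation(
    frame: np.ndarray,
    layout: SensorLayout | None = None,
    threshold: float = 0.15,
) -> PronationResult:
    """Classify a static standing frame as normal / under- / overpronation.

    An unloaded foot (both pair sums zero) is NORMAL with index 0.
    """
    layout = layout or default_layout()
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (N_CHANNELS,):
        raise ValueError(f"frame must have {N_CHANNELS} values")
    p_left = float(frame[list(LEFT_PAIR)].mean())
    p_right = float(frame[list(RIGHT_PAIR)].mean())
    total = p_left + p_right
    if total == 0:
        return PronationResult(PronationLabel.NORMAL, 0.0)
    index = (p_left - p_right) / total
    if abs(index) <= threshold:
        return PronationResult(PronationLabel.NORMAL, index)
    left_loaded = index > 0
    left_medial = layout.left_is_medial
    if left_loaded == left_medial:
        label = PronationLabel.OVERPRONATION  # medial overload
    else:
        label = PronationLabel.UNDERPRONATION  # lateral overload
    return PronationResult(label, index)


def map_sequence(
    series: PressureSeries,
    layout: SensorLayout | None = None,
    resolution: int = 60,
    stride: int = 1,
) -> list[PressureMap]:
    """One surface per ``stride``-th frame; count = ceil(n_samples / stride)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    layout = layout or default_layout()
    return [
        interpolate_map(series.values[i], layout, resolution)
        for i in range(0, series.n_samples, stride)
    ]
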