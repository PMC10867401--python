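"""Capacitive-sensor physics and the pressure <-> capacitance calibration.

A parallel-plate capacitive pressure sensor reads C = eps * A / d; compressing
the porous dielectric shrinks d and raises the effective permittivity, which is
the volume-weighted mixture of air (eps = 1) and the elastomer composite.

The sensor's measured response is summarized by two regional sensitivities of
the relative capacitance change DC/C0 per kPa: a steep low-pressure regime and
a flatter high-pressure regime where the pores are mostly collapsed.  The
calibration curve is modeled as two exact linear segments joined at the
breakpoint — the simplest form consistent with the two printed slopes:

    DC/C0(p) = S_low * p                                    p <= p_b
             = S_low * p_b + S_high * (p - p_b)             p  > p_b

with defaults S_low = 0.0126 kPa^-1, S_high = 0.0038 kPa^-1, p_b = 200 kPa,
valid over 0-500 kPa with a 0.4 kPa detection limit.  The inverse is the exact
piecewise-linear inverse; readings mapping below the detection limit are
censored to 0 rather than raising, which keeps streaming conversion robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def parallel_plate_capacitance(
    permittivity: float, area: float, thickness: float
) -> float:
    """C = eps * A / d (any consistent unit system).

    Linear in permittivity and plate area, strictly decreasing in dielectric
    thickness.
    """
    if permittivity <= 0 or area <= 0:
        raise ValueError("permittivity and area must be positive")
    if thickness <= 0:
        raise ValueError("dielectric thickness must be positive")
    return permittivity * area / thickness


def mixture_permittivity(
    eps_composite: float,
    vol_air: float,
    vol_composite: float | None = None,
    eps_air: float = 1.0,
) -> float:
    """Volume-weighted permittivity of the porous dielectric.

    eps = eps_air * V_air + eps_composite * V_composite, with the two volume
    fractions summing to 1 (checked to 1e-9).  Air is fixed at eps = 1.
    """
    if vol_composite is None:
        vol_composite = 1.0 - vol_air
    if not (0.0 <= vol_air <= 1.0 and 0.0 <= vol_composite <= 1.0):
        raise ValueError("volume fractions must lie in [0, 1]")
    if abs(vol_air + vol_composite - 1.0) > 1e-9:
        raise ValueError("volume fractions must sum to 1")
    if eps_composite <= 0:
        raise ValueError("permittivity must be positive")
    return eps_air * vol_air + eps_composite * vol_composite


@dataclass(frozen=True)
class CalibrationCurve:
    """Two-segment linear DC/C0 vs pressure response."""

    sensitivity_low: float = 0.0126  # kPa^-1, 0 - breakpoint
    sensitivity_high: float = 0.0038  # kPa^-1, breakpoint - max_pressure
    breakpoint: float = 200.0  # kPa
    detection_limit: float = 0.4  # kPa
    max_pressure: float = 500.0  # kPa
    baseline_capacitance: float = 100.0  # pF

    def __post_init__(self) -> None:
        if not self.sensitivity_low > self.sensitivity_high > 0:
            raise ValueError("need S_low > S_high > 0")
        if not 0 < self.detection_limit < self.breakpoint < self.max_pressure:
            raise ValueError("need 0 < detection_limit < breakpoint < max_pressure")
        if self.baseline_capacitance <= 0:
            raise ValueError("baseline capacitance must be positive")

    @property
    def max_relcap(self) -> float:
        """DC/C0 at the top of the validated range."""
        return (
            self.sensitivity_low * self.breakpoint
            + self.sensitivity_high * (self.max_pressure - self.breakpoint)
        )


def pressure_to_relcap(p, curve: CalibrationCurve | None = None):
    """Forward calibration: pressure (kPa) -> relative capacitance change.

    Accepts scalars or arrays; input outside [0, max_pressure] raises.
    """
    curve = curve or CalibrationCurve()
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > curve.max_pressure):
        raise ValueError(
            f"pressure outside validated range [0, {curve.max_pressure}] kPa"
        )
    low = curve.sensitivity_low * np.minimum(p, curve.breakpoint)
    high = curve.sensitivity_high * np.maximum(p - curve.breakpoint, 0.0)
    out = low + high
    return float(out) if out.ndim == 0 else out


def relcap_to_pressure(relcap, curve: CalibrationCurve | None = None):
    """Inverse calibration: relative capacitance change -> pressure (kPa).

    Exact piecewise-linear inverse; results below the detection limit are
    censored to 0.  Readings above the validated range raise.
    """
    curve = curve or CalibrationCurve()
    rc = np.asarray(relcap, dtype=float)
    if np.any(rc < 0) or np.any(rc > curve.max_relcap * (1 + 1e-12)):
        raise ValueError(
            f"relative capacitance outside [0, {curve.max_relcap:.6g}]"
        )
    knee = curve.sensitivity_low * curve.breakpoint
    p = np.where(
        rc <= knee,
        rc / curve.sensitivity_low,
        curve.breakpoint + (rc - knee) / curve.sensitivity_high,
    )
    p = np.where(p < curve.detection_limit, 0.0, p)
    return float(p) if p.ndim == 0 else p


class CapacitanceCalibrator(TransformerMixin, BaseEstimator):
    """sklearn-style transformer converting raw DC/C0 readings to kPa.

    ``transform`` maps relative capacitance to pressure; ``inverse_transform``
    applies the forward sensor model.  The curve is fixed by construction
    parameters (the calibration is a bench property, not fitted from the
    stream), so ``fit`` only validates them.  One shared curve serves all
    channels unless ``per_channel_curves`` supplies overrides.
    """

    def __init__(
        self,
        sensitivity_low: float = 0.0126,
        sensitivity_high: float = 0.0038,
        breakpoint: float = 200.0,
        detection_limit: float = 0.4,
        max_pressure: float = 500.0,
        baseline_capacitance: float = 100.0,
        per_channel_curves: dict[int, CalibrationCurve] | None = None,
    ):
        self.sensitivity_low = sensitivity_low
        self.sensitivity_high = sensitivity_high
        self.breakpoint = breakpoint
        self.detection_limit = detection_limit
        self.max_pressure = max_pressure
        self.baseline_capacitance = baseline_capacitance
        self.per_channel_curves = per_channel_curves

    def _build_curve(self) -> CalibrationCurve:
        return CalibrationCurve(
            self.sensitivity_low,
            self.sensitivity_high,
            self.breakpoint,
            self.detection_limit,
            self.max_pressure,
            self.baseline_capacitance,
        )

    def fit(self, X=None, y=None):
        self.curve_ = self._build_curve()
        return self

    def transform(self, X):
        check_is_fitted(self, "curve_")
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        overrides = self.per_channel_curves or {}
        if X.ndim == 2 and overrides:
            for ch in range(X.shape[1]):
                curve = overrides.get(ch, self.curve_)
                out[:, ch] = relcap_to_pressure(X[:, ch], curve)
        else:
            out = np.asarray(relcap_to_pressure(X, self.curve_))
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "curve_")
        X = np.asarray(X, dtype=float)
        overrides = self.per_channel_curves or {}
        if X.ndim == 2 and overrides:
            out = np.empty_like(X)
            for ch in range(X.shape[1]):
                curve = overrides.get(ch, self.curve_)
                out[:, ch] = pressure_to_relcap(X[:, ch], curve)
            return out
        return np.asarray(pressure_to_relcap(X, self.curve_))
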