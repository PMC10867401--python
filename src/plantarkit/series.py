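"""Timestamped multichannel plantar-pressure records and their on-disk format.

The interchange format is UTF-8 CSV with header ``time_s,S1,...,S8`` (one row
per frame, times strictly increasing, pressures in kPa).  A leading comment
line ``# unit=relcap`` marks a raw relative-capacitance file that still needs
calibration; an optional trailing ``posture`` column carries per-sample
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHANNELS, SAMPLE_RATE_HZ

N_CHANNELS = len(CHANNELS)


class SeriesFormatError(ValueError):
    """Raised for malformed series files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class PressureSeries:
    """An 8-channel pressure record at a fixed sampling rate.

    Parameters
    ----------
    values : ndarray of shape (n_samples, 8)
        Per-frame channel readings.  Non-negative when ``unit == "kPa"``.
    sample_rate : float
        Frames per second.
    annotation : ndarray of int, optional
        Per-sample posture code (see :class:`plantarkit.synthetic.Posture`).
    unit : {"kPa", "relcap"}
        Physical pressure or raw relative capacitance change.
    """

    values: np.ndarray
    sample_rate: float = SAMPLE_RATE_HZ
    annotation: np.ndarray | None = None
    unit: str = "kPa"
    channels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(
                f"values must be (n_samples, {N_CHANNELS}), got {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise ValueError("series must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.unit not in ("kPa", "relcap"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit == "kPa" and np.any(self.values < 0):
            raise ValueError("pressures must be non-negative")
        if self.annotation is not None:
            self.annotation = np.asarray(self.annotation, dtype=int)
            if self.annotation.shape != (self.values.shape[0],):
                raise ValueError("annotation length must match n_samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def slice(self, start: int, stop: int) -> "PressureSeries":
        ann = None if self.annotation is None else self.annotation[start:stop]
        return PressureSeries(
            self.values[start:stop], self.sample_rate, ann, self.unit, self.channels
        )


def concatenate(parts: list[PressureSeries]) -> PressureSeries:
    if not parts:
        raise ValueError("nothing to concatenate")
    rate = parts[0].sample_rate
    unit = parts[0].unit
    if any(p.sample_rate != rate or p.unit != unit for p in parts):
        raise ValueError("all parts must share sample_rate and unit")
    values = np.concatenate([p.values for p in parts])
    if all(p.annotation is not None for p in parts):
        ann = np.concatenate([p.annotation for p in parts])
    else:
        ann = None
    return PressureSeries(values, rate, ann, unit)


def write_series(series: PressureSeries, path: str | Path) -> None:
    """Write a series as ``time_s,S1..S8[,posture]`` CSV (lossless round-trip)."""
    frame = pd.DataFrame(series.values, columns=list(series.channels))
    frame.insert(0, "time_s", series.times)
    if series.annotation is not None:
        frame["posture"] = series.annotation
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if series.unit != "kPa":
            fh.write(f"# unit={series.unit}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_series(path: str | Path) -> PressureSeries:
    """Parse a series file, validating structure frame by frame.

    Raises
    ------
    SeriesFormatError
        On wrong column count, non-monotone timestamps, or negative pressure;
        the message names the offending 1-based file line.
    """
    path = Path(path)
    unit = "kPa"
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise SeriesFormatError(f"{path} is empty")
        if first.startswith("#"):
            skip = 1
            flag = first.lstrip("#").strip()
            if flag.startswith("unit="):
                unit = flag.split("=", 1)[1]
    try:
        table = pd.read_csv(path, skiprows=skip)
    except pd.errors.EmptyDataError:
        raise SeriesFormatError(f"{path} is empty") from None
    except pd.errors.ParserError as exc:
        raise SeriesFormatError(str(exc)) from None

    expected = ["time_s", *CHANNELS]
    has_posture = list(table.columns) == expected + ["posture"]
    if not has_posture and list(table.columns) != expected:
        raise SeriesFormatError(
            f"expected columns {expected} (optionally + 'posture'), "
            f"got {list(table.columns)}",
            line=1 + skip,
        )
    if len(table) == 0:
        raise SeriesFormatError(f"{path} contains a header but no frames")

    data_start = 2 + skip  # 1-based line of the first data row
    values = table[list(CHANNELS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        row = int(np.argwhere(~np.isfinite(values).all(axis=1))[0, 0])
        raise SeriesFormatError("non-numeric channel value", line=data_start + row)
    if unit == "kPa" and np.any(values < 0):
        row = int(np.argwhere((values < 0).any(axis=1))[0, 0])
        raise SeriesFormatError("negative pressure", line=data_start + row)

    times = table["time_s"].to_numpy(dtype=float)
    if len(times) > 1:
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise SeriesFormatError(
                "timestamps must be strictly increasing",
                line=data_start + int(bad[0]) + 1,
            )
    if len(times) > 1:
        rate = 1.0 / float(np.median(np.diff(times)))
    else:
        rate = SAMPLE_RATE_HZ
    ann = table["posture"].to_numpy(dtype=int) if has_posture else None
    return PressureSeries(values, rate, ann, unit)
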