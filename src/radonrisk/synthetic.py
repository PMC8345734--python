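"""Synthetic radon series and occupancy schedules for hermetic testing.

Concentrations are log-normal on the natural scale — ln(c) is Gaussian with
optional diurnal and seasonal sinusoidal modulation — which matches how
indoor radon data behave statistically.  Schedules come as presets
(office ≈ 2000 h·yr⁻¹, dwelling ≈ 7000 h·yr⁻¹, continuous 24/7) or custom
weekly patterns.  Everything is seedable and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Dict, Optional, Tuple

import numpy as np

from .dose_model import ValidationError
from .exposure_timeseries import (
    OccupancySchedule,
    RadonReading,
    RadonSeries,
)

__all__ = ["SeriesSpec", "generate_series", "generate_schedule", "scenario"]

# Phases chosen so concentration peaks at 03:00 and in mid-winter (early
# January) — closed buildings at night and in cold months run higher.
_DIURNAL_PEAK_HOUR = 3.0
_SEASONAL_PEAK_DAY = 15.0


@dataclass(frozen=True)
class SeriesSpec:
    """Parameters of a synthetic log-normal radon series."""

    gm: float = 100.0  # geometric mean, Bq·m⁻³
    gsd: float = 1.0  # geometric standard deviation, >= 1
    diurnal_amplitude: float = 0.0  # fraction of ln(gm), [0, 1)
    seasonal_amplitude: float = 0.0  # fraction of ln(gm), [0, 1)
    sampling_interval_min: int = 60
    span_days: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gm > 0):
            raise ValidationError(f"gm must be > 0, got {self.gm!r}")
        if not (self.gsd >= 1):
            raise ValidationError(f"gsd must be >= 1, got {self.gsd!r}")
        for name in ("diurnal_amplitude", "seasonal_amplitude"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValidationError(f"{name} must be in [0, 1), got {v!r}")
        if not (self.sampling_interval_min > 0):
            raise ValidationError("sampling interval must be positive")
        if not (self.span_days > 0):
            raise ValidationError("span must be positive")


def generate_series(
    spec: SeriesSpec, start: datetime, compartment_id: str = "synthetic"
) -> RadonSeries:
    """Generate a seeded log-normal series sampled on a regular grid.

    ln(c_t) = ln(gm) + A·sin(2π·hour/24 + φ_d) + B·sin(2π·day/365 + φ_s) + ε
    with ε ~ Normal(0, ln(gsd)), A and B scaled from ln(gm) by the spec's
    amplitude fractions.  Identical seed ⇒ bit-identical output.
    """
    n = int(round(spec.span_days * 1440 / spec.sampling_interval_min))
    rng = np.random.default_rng(spec.seed)
    step = timedelta(minutes=spec.sampling_interval_min)
    timestamps = [start + i * step for i in range(n)]
    log_gm = math.log(spec.gm)
    hours = np.array(
        [(t - start).total_seconds() / 3600.0 for t in timestamps]
    )
    hour_of_day = np.array([t.hour + t.minute / 60.0 for t in timestamps])
    day_of_year = np.array([t.timetuple().tm_yday - 1 + h / 24.0
                            for t, h in zip(timestamps, hour_of_day)])
    phi_d = math.pi / 2 - 2 * math.pi * _DIURNAL_PEAK_HOUR / 24.0
    phi_s = math.pi / 2 - 2 * math.pi * _SEASONAL_PEAK_DAY / 365.0
    log_c = (
        log_gm
        + spec.diurnal_amplitude * abs(log_gm)
        * np.sin(2 * math.pi * hour_of_day / 24.0 + phi_d)
        + spec.seasonal_amplitude * abs(log_gm)
        * np.sin(2 * math.pi * day_of_year / 365.0 + phi_s)
        + rng.normal(0.0, math.log(spec.gsd), size=n)
    )
    readings = tuple(
        RadonReading(t, float(c)) for t, c in zip(timestamps, np.exp(log_c))
    )
    return RadonSeries(readings, compartment_id)


_OFFICE = {
    "weekly": [
        {"day": d, "start": "09:00", "end": "17:00"}
        for d in ("Mon", "Tue", "Wed", "Thu", "Fri")
    ],
    "exceptions": [],
}

# 19 h/day every day (away 12:00–17:00): 365 × 19 = 6935 h ≈ the 7000 h
# annual-occupancy convention for dwellings.
_DWELLING = {
    "weekly": [
        iv
        for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
        for iv in (
            {"day": d, "start": "00:00", "end": "12:00"},
            {"day": d, "start": "17:00", "end": "24:00"},
        )
    ],
    "exceptions": [],
}

_CONTINUOUS = {
    "weekly": [
        {"day": d, "start": "00:00", "end": "24:00"}
        for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
    ],
    "exceptions": [],
}


def generate_schedule(kind: str, params: Optional[dict] = None) -> OccupancySchedule:
    """Build a preset or custom occupancy schedule.

    ``office`` = weekdays 09:00–17:00 (≈2000 h·yr⁻¹); ``dwelling`` = daily
    except 12:00–17:00 (≈7000 h·yr⁻¹); ``continuous`` = 24/7; ``custom``
    takes the canonical schedule dict in ``params``.
    """
    if kind == "office":
        return OccupancySchedule.from_dict(_OFFICE)
    if kind == "dwelling":
        return OccupancySchedule.from_dict(_DWELLING)
    if kind == "continuous":
        return OccupancySchedule.from_dict(_CONTINUOUS)
    if kind == "custom":
        if not params:
            raise ValidationError("custom schedule requires a schedule dict")
        return OccupancySchedule.from_dict(params)
    raise ValidationError(
        f"unknown schedule kind {kind!r}; use office/dwelling/continuous/custom"
    )


def scenario(
    name: str, seed: int = 0
) -> Tuple[RadonSeries, OccupancySchedule, Dict]:
    """Deterministic fixture bundles with expected outcomes attached.

    Returns ``(series, schedule, expected)`` where ``expected`` carries the
    anticipated per-window indicator levels and flags for test assertion.
    """
    start = datetime(2021, 1, 4)  # a Monday
    if name == "worked_example_yellow":
        # DAO 8 h at a constant 300 Bq·m⁻³ — annualizes into the yellow band.
        spec = SeriesSpec(gm=300.0, gsd=1.0, span_days=95, seed=seed)
        series = generate_series(spec, start, "worked_example")
        schedule = generate_schedule(
            "custom",
            {
                "weekly": [
                    {"day": d, "start": "09:00", "end": "17:00"}
                    for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
                ],
                "exceptions": [],
            },
        )
        expected = {
            "irrei": {"VST": 2, "ST": 2, "LT": 2},
            "dao": {"VST": 8.0, "ST": 8.0, "LT": 8.0},
            "amrc": 300.0,
        }
    elif name == "baseline_green":
        spec = SeriesSpec(gm=20.0, gsd=1.2, span_days=95, seed=seed)
        series = generate_series(spec, start, "baseline")
        schedule = generate_schedule("office")
        expected = {"irrei": {"VST": 1, "ST": 1, "LT": 1}}
    elif name == "mitigation_drop":
        # Concentration drops sharply halfway through: short windows should
        # read low while the long window still remembers the high spell.
        spec_hi = SeriesSpec(gm=800.0, gsd=1.1, span_days=46, seed=seed)
        spec_lo = SeriesSpec(gm=50.0, gsd=1.1, span_days=49, seed=seed + 1)
        hi = generate_series(spec_hi, start, "mitigation")
        lo = generate_series(
            spec_lo, start + timedelta(days=46), "mitigation"
        )
        series = RadonSeries(hi.readings + lo.readings, "mitigation")
        schedule = generate_schedule("dwelling")
        expected = {"short_below_long": True}
    elif name == "data_gap":
        spec = SeriesSpec(gm=300.0, gsd=1.0, span_days=95, seed=seed)
        base = generate_series(spec, start, "data_gap")
        gap_start = start + timedelta(days=94)
        gap_end = start + timedelta(days=94, hours=12)
        readings = tuple(
            r for r in base.readings if not (gap_start <= r.timestamp < gap_end)
        )
        marker = RadonReading(gap_start, float("nan"), "missing")
        series = RadonSeries(
            tuple(sorted(readings + (marker,), key=lambda r: r.timestamp)),
            "data_gap",
        )
        schedule = generate_schedule("continuous")
        expected = {"coverage_below_one": ["VST"]}
    else:
        raise ValidationError(f"unknown scenario {name!r}")
    return series, schedule, expected
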