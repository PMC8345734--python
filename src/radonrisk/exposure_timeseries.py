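"""Occupancy-conditioned aggregation of continuous radon time series.

Implements the monitoring pipeline: ingest timestamped readings, apply the
building's occupancy schedule (SOP), compute windowed arithmetic-mean radon
concentration (AMRC) over the standard assessment windows (RT = last hour,
VST = last 24 h, ST = last week, LT = at least the last 90 days), derive the
window effective dose (IED), annualize it to an IAED estimate, and classify
the four-level risk indicator per window.

Semantics
---------
Readings are treated as interval averages: the series is piecewise-constant,
holding each value from its timestamp until the next reading (the final
reading holds for the median inter-reading interval).  All intervals are
half-open ``[start, end)`` in local wall-clock time.  Means are
time-weighted; sample-based AM/SD/GM/GSD are available separately in
:func:`summary_stats` for comparability with survey-style reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dose_model import (
    DoseModelConfig,
    IrreiLevel,
    ValidationError,
    classify_irrei,
    effective_dose,
    iaed_from_dao,
)

__all__ = [
    "NoDataError",
    "NoOccupancyError",
    "OccupancySchedule",
    "RadonReading",
    "RadonSeries",
    "RiskAssessment",
    "WindowDataError",
    "WindowSpec",
    "annualize",
    "assess",
    "occupancy_mask",
    "read_series",
    "standard_windows",
    "summary_stats",
    "window_amrc",
    "window_ied",
]

Interval = Tuple[datetime, datetime]

QUALITY_FLAGS = ("ok", "suspect", "missing")

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


class WindowDataError(ValueError):
    """Base for window-aggregation failures."""


class NoOccupancyError(WindowDataError):
    """The occupancy mask is empty within the requested window."""


class NoDataError(WindowDataError):
    """No observed readings overlap the masked window."""


# ---------------------------------------------------------------------------
# Readings and series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadonReading:
    timestamp: datetime
    concentration: float
    quality_flag: str = "ok"

    def __post_init__(self) -> None:
        if self.quality_flag not in QUALITY_FLAGS:
            raise ValidationError(
                f"quality_flag must be one of {QUALITY_FLAGS}, got {self.quality_flag!r}"
            )
        if self.quality_flag != "missing" and not (self.concentration >= 0):
            raise ValidationError(
                f"concentration must be >= 0, got {self.concentration!r} "
                f"at {self.timestamp.isoformat()}"
            )


@dataclass(frozen=True)
class RadonSeries:
    """Time-ordered readings from one detector/compartment."""

    readings: Tuple[RadonReading, ...]
    compartment_id: str = "default"

    def __post_init__(self) -> None:
        readings = tuple(self.readings)
        object.__setattr__(self, "readings", readings)
        for a, b in zip(readings, readings[1:]):
            if not a.timestamp < b.timestamp:
                raise ValidationError(
                    f"timestamps must be strictly increasing; "
                    f"{a.timestamp.isoformat()} !< {b.timestamp.isoformat()}"
                )
        if readings and all(r.quality_flag == "missing" for r in readings):
            raise ValidationError("series has no non-missing reading")

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def hold_interval(self) -> timedelta:
        """How long the final reading is held: the median sampling step."""
        if len(self.readings) < 2:
            return timedelta(hours=1)
        diffs = [
            (b.timestamp - a.timestamp).total_seconds()
            for a, b in zip(self.readings, self.readings[1:])
        ]
        return timedelta(seconds=float(np.median(diffs)))

    def segments(self) -> List[Tuple[datetime, datetime, float]]:
        """Piecewise-constant (start, end, value) segments, gaps where the
        quality flag is ``missing``."""
        out: List[Tuple[datetime, datetime, float]] = []
        n = len(self.readings)
        for i, r in enumerate(self.readings):
            end = (
                self.readings[i + 1].timestamp
                if i + 1 < n
                else r.timestamp + self.hold_interval
            )
            if r.quality_flag != "missing":
                out.append((r.timestamp, end, r.concentration))
        return out

    def shift(self, offset: timedelta) -> "RadonSeries":
        """Translate every timestamp by ``offset`` (testing aid)."""
        return RadonSeries(
            tuple(replace(r, timestamp=r.timestamp + offset) for r in self.readings),
            self.compartment_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": [r.timestamp for r in self.readings],
                "concentration": [r.concentration for r in self.readings],
                "quality_flag": [r.quality_flag for r in self.readings],
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
        df.to_csv(path, index=False)


def read_series(path, compartment_id: Optional[str] = None) -> RadonSeries:
    """Read a readings CSV (columns: timestamp, concentration, optional
    quality_flag) into a validated, sorted :class:`RadonSeries`.

    Duplicate timestamps, unparseable timestamps and negative concentrations
    are rejected with the offending row named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"timestamp", "concentration"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing_cols)}")
    readings = []
    for row in df.itertuples(index=True):
        try:
            ts = datetime.fromisoformat(str(row.timestamp))
        except ValueError as exc:
            raise ValidationError(
                f"{path} row {row.Index + 2}: unparseable timestamp {row.timestamp!r}"
            ) from exc
        flag = getattr(row, "quality_flag", "ok")
        if flag is None or (isinstance(flag, float) and np.isnan(flag)):
            flag = "ok"
        try:
            conc = float(row.concentration) if flag != "missing" else float("nan")
            readings.append(RadonReading(ts, conc, flag))
        except (ValidationError, TypeError) as exc:
            raise ValidationError(f"{path} row {row.Index + 2}: {exc}") from exc
    readings.sort(key=lambda r: r.timestamp)
    for a, b in zip(readings, readings[1:]):
        if a.timestamp == b.timestamp:
            raise ValidationError(
                f"{path}: duplicate timestamp {a.timestamp.isoformat()}"
            )
    return RadonSeries(
        tuple(readings), compartment_id or path.stem
    )


# ---------------------------------------------------------------------------
# Occupancy schedule (SOP)
# ---------------------------------------------------------------------------


def _parse_hhmm(s: str) -> int:
    """'HH:MM' → minutes since midnight; '24:00' allowed as day end."""
    hh, mm = s.split(":")
    minutes = int(hh) * 60 + int(mm)
    if not (0 <= minutes <= 1440):
        raise ValidationError(f"time of day out of range: {s!r}")
    return minutes


def _merge_minute_intervals(
    intervals: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class OccupancySchedule:
    """The Specific Occupation Period: a recurring weekly pattern plus dated
    exceptions.

    ``weekly`` maps weekday index (0 = Monday) to merged, disjoint
    ``(start_minute, end_minute)`` half-open intervals.  Exceptions either
    remove occupancy on a date (holiday) or add it (special event); each may
    carry a sub-day interval, defaulting to the whole day.
    """

    weekly: Dict[int, Tuple[Tuple[int, int], ...]] = field(default_factory=dict)
    exceptions: Tuple[Tuple[date, bool, int, int], ...] = ()

    def __post_init__(self) -> None:
        norm: Dict[int, Tuple[Tuple[int, int], ...]] = {}
        for day, ivals in self.weekly.items():
            if not (0 <= int(day) <= 6):
                raise ValidationError(f"weekday index out of range: {day!r}")
            for s, e in ivals:
                if not (0 <= s < e <= 1440):
                    raise ValidationError(
                        f"invalid interval ({s}, {e}) on weekday {day}"
                    )
            norm[int(day)] = tuple(_merge_minute_intervals(list(ivals)))
        object.__setattr__(self, "weekly", norm)
        object.__setattr__(self, "exceptions", tuple(self.exceptions))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, payload: dict) -> "OccupancySchedule":
        """Build from the canonical JSON dialect::

            {"weekly": [{"day": "Mon", "start": "09:00", "end": "17:00"}, ...],
             "exceptions": [{"date": "2021-01-01", "occupied": false}, ...]}

        Intervals crossing midnight (end <= start) are split into two.
        """
        weekly: Dict[int, List[Tuple[int, int]]] = {}
        for item in payload.get("weekly", []):
            day_name = item["day"]
            if day_name not in WEEKDAY_NAMES:
                raise ValidationError(
                    f"unknown weekday {day_name!r}; use one of {WEEKDAY_NAMES}"
                )
            day = WEEKDAY_NAMES.index(day_name)
            s = _parse_hhmm(item["start"])
            e = _parse_hhmm(item["end"])
            if s == e:
                raise ValidationError(f"zero-length interval on {day_name}")
            if e > s:
                weekly.setdefault(day, []).append((s, e))
            else:  # crosses midnight: split at 24:00
                weekly.setdefault(day, []).append((s, 1440))
                weekly.setdefault((day + 1) % 7, []).append((0, e))
        exceptions = []
        for item in payload.get("exceptions", []):
            d = date.fromisoformat(item["date"])
            occupied = bool(item["occupied"])
            s = _parse_hhmm(item.get("start", "00:00"))
            e = _parse_hhmm(item.get("end", "24:00"))
            if not s < e:
                raise ValidationError(f"invalid exception interval on {d}")
            exceptions.append((d, occupied, s, e))
        return cls({d: tuple(v) for d, v in weekly.items()}, tuple(exceptions))

    @classmethod
    def from_json(cls, path) -> "OccupancySchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        weekly = [
            {
                "day": WEEKDAY_NAMES[day],
                "start": f"{s // 60:02d}:{s % 60:02d}",
                "end": f"{e // 60:02d}:{e % 60:02d}",
            }
            for day in sorted(self.weekly)
            for s, e in self.weekly[day]
        ]
        exceptions = [
            {
                "date": d.isoformat(),
                "occupied": occ,
                "start": f"{s // 60:02d}:{s % 60:02d}",
                "end": f"{e // 60:02d}:{e % 60:02d}",
            }
            for d, occ, s, e in self.exceptions
        ]
        return {"weekly": weekly, "exceptions": exceptions}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    # -- evaluation ---------------------------------------------------------

    def day_intervals(self, d: date) -> List[Tuple[int, int]]:
        """Occupied minute intervals for one calendar date, exceptions applied."""
        base = list(self.weekly.get(d.weekday(), ()))
        for ex_date, occupied, s, e in self.exceptions:
            if ex_date != d:
                continue
            if occupied:
                base = _merge_minute_intervals(base + [(s, e)])
            else:
                clipped: List[Tuple[int, int]] = []
                for bs, be in base:
                    if bs < s:
                        clipped.append((bs, min(be, s)))
                    if be > e:
                        clipped.append((max(bs, e), be))
                base = [iv for iv in clipped if iv[0] < iv[1]]
        return _merge_minute_intervals(base)


def occupancy_mask(
    schedule: OccupancySchedule, t0: datetime, t1: datetime
) -> List[Interval]:
    """Occupied half-open intervals of ``schedule`` within ``[t0, t1)``,
    disjoint and sorted."""
    if not t0 < t1:
        raise ValidationError(f"t0 must precede t1, got {t0} >= {t1}")
    out: List[Interval] = []
    d = t0.date()
    while datetime.combine(d, time.min) < t1:
        midnight = datetime.combine(d, time.min)
        for s, e in schedule.day_intervals(d):
            start = midnight + timedelta(minutes=s)
            end = midnight + timedelta(minutes=e)
            start, end = max(start, t0), min(end, t1)
            if start < end:
                if out and out[-1][1] == start:
                    out[-1] = (out[-1][0], end)
                else:
                    out.append((start, end))
        d += timedelta(days=1)
    return out


def _intervals_hours(intervals: Sequence[Interval]) -> float:
    return sum((e - s).total_seconds() for s, e in intervals) / 3600.0


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """One assessment window: its name, span, and whether the occupancy
    mask conditions the mean."""

    name: str
    span: timedelta
    occupancy_conditioned: bool

    def __post_init__(self) -> None:
        if self.name not in ("RT", "VST", "ST", "LT"):
            raise ValidationError(f"window name must be RT/VST/ST/LT, got {self.name!r}")
        if not self.span > timedelta(0):
            raise ValidationError("window span must be positive")
        if self.name == "LT" and self.span < timedelta(days=90):
            raise ValidationError("LT span must be at least 90 days")


def standard_windows(lt_days: int = 90) -> Tuple[WindowSpec, ...]:
    """RT = 1 h (unconditioned), VST = 24 h, ST = 7 d, LT = ``lt_days`` d."""
    return (
        WindowSpec("RT", timedelta(hours=1), False),
        WindowSpec("VST", timedelta(hours=24), True),
        WindowSpec("ST", timedelta(days=7), True),
        WindowSpec("LT", timedelta(days=lt_days), True),
    )


def _masked_mean(
    series: RadonSeries, mask: Sequence[Interval]
) -> Tuple[float, float, float]:
    """Time-weighted mean of the piecewise-constant series over the mask.

    Returns (mean, observed_hours, masked_hours); raises NoDataError when
    nothing overlaps.
    """
    masked_hours = _intervals_hours(mask)
    wsum = 0.0
    observed = 0.0
    for seg_start, seg_end, value in series.segments():
        for m_start, m_end in mask:
            lo, hi = max(seg_start, m_start), min(seg_end, m_end)
            if lo < hi:
                h = (hi - lo).total_seconds() / 3600.0
                wsum += value * h
                observed += h
    if observed == 0.0:
        raise NoDataError("no observed readings overlap the masked window")
    return wsum / observed, observed, masked_hours


def window_amrc(
    series: RadonSeries,
    window: WindowSpec,
    schedule: Optional[OccupancySchedule],
    asof: datetime,
) -> Tuple[float, float]:
    """Arithmetic mean radon concentration over ``[asof − span, asof)``.

    The mean is time-weighted over occupied time when the window is
    occupancy-conditioned (the schedule is then required), over all time
    otherwise.  Returns ``(amrc, coverage_fraction)`` where coverage is
    observed masked time over total masked time.
    """
    t0 = asof - window.span
    if window.occupancy_conditioned:
        if schedule is None:
            raise ValidationError(f"{window.name} window requires a schedule")
        mask = occupancy_mask(schedule, t0, asof)
        if not mask:
            raise NoOccupancyError(f"no occupancy within the {window.name} window")
    else:
        mask = [(t0, asof)]
    mean, observed, masked = _masked_mean(series, mask)
    return mean, observed / masked


def summary_stats(
    series: RadonSeries,
    window: WindowSpec,
    schedule: Optional[OccupancySchedule],
    asof: datetime,
) -> Dict[str, float]:
    """Sample-based AM, SD, GM, GSD of masked readings in the window.

    SD/GSD use the n−1 convention.  If any masked concentration is zero,
    GM and GSD are reported as NaN (undefined on the log scale) while AM/SD
    are still returned.
    """
    t0 = asof - window.span
    if window.occupancy_conditioned:
        if schedule is None:
            raise ValidationError(f"{window.name} window requires a schedule")
        mask = occupancy_mask(schedule, t0, asof)
    else:
        mask = [(t0, asof)]
    values = np.array(
        [
            r.concentration
            for r in series.readings
            if r.quality_flag != "missing"
            and any(s <= r.timestamp < e for s, e in mask)
        ]
    )
    if values.size == 0:
        raise NoDataError("no masked readings in window")
    am = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if np.any(values <= 0):
        gm = gsd = float("nan")
    else:
        logs = np.log(values)
        gm = float(np.exp(np.mean(logs)))
        gsd = float(np.exp(np.std(logs, ddof=1))) if values.size > 1 else 1.0
    return {"AM": am, "SD": sd, "GM": gm, "GSD": gsd}


def window_ied(
    amrc: float, occupied_hours: float, config: DoseModelConfig
) -> float:
    """Indoor effective dose over a window, in mSv."""
    if not (occupied_hours >= 0):
        raise ValidationError(f"occupied_hours must be >= 0, got {occupied_hours!r}")
    return effective_dose(amrc * occupied_hours, config) * 1e3


def annualize(amrc: float, dao: float, config: DoseModelConfig) -> float:
    """IAED estimate (mSv·year⁻¹) by extrapolating the window's AMRC and
    daily average occupation to a full year."""
    return iaed_from_dao(amrc, dao, config)


# ---------------------------------------------------------------------------
# Full assessment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskAssessment:
    """Per-window pipeline outputs.  ``status`` is one of ``ok``,
    ``no_occupancy``, ``no_data``, ``unavailable``; numeric fields are None
    when the status precludes them (and IRREI is never computed for RT)."""

    window: str
    status: str = "ok"
    amrc: Optional[float] = None
    occupied_hours: Optional[float] = None
    dao: Optional[float] = None
    ied_mSv: Optional[float] = None
    iaed_mSv: Optional[float] = None
    irrei: Optional[IrreiLevel] = None
    coverage_fraction: Optional[float] = None
    low_confidence: bool = False

    def to_dict(self) -> dict:
        d = {
            "window": self.window,
            "status": self.status,
            "amrc_Bq_m3": self.amrc,
            "occupied_hours": self.occupied_hours,
            "dao_hours": self.dao,
            "ied_mSv": self.ied_mSv,
            "iaed_mSv_per_year": self.iaed_mSv,
            "irrei_level": int(self.irrei) if self.irrei else None,
            "irrei_color": self.irrei.color if self.irrei else None,
            "coverage_fraction": self.coverage_fraction,
            "low_confidence": self.low_confidence,
        }
        return d


def assess(
    series: RadonSeries,
    schedule: OccupancySchedule,
    config: DoseModelConfig,
    asof: datetime,
    windows: Optional[Sequence[WindowSpec]] = None,
    min_coverage: float = 0.5,
) -> Dict[str, RiskAssessment]:
    """Run the full pipeline for each standard window as of ``asof``.

    RT reports the unconditioned mean only (it drives mitigation, not the
    indicator).  VST/ST/LT carry AMRC, DAO, window IED, annualized IAED and
    the IRREI level; windows with data coverage below ``min_coverage`` are
    flagged low-confidence but still reported.  Readings at or after
    ``asof`` never affect the result.
    """
    if len(series) == 0:
        raise ValidationError("cannot assess an empty series")
    if windows is None:
        windows = standard_windows()
    results: Dict[str, RiskAssessment] = {}
    for w in windows:
        try:
            amrc, coverage = window_amrc(series, w, schedule, asof)
        except NoOccupancyError:
            results[w.name] = RiskAssessment(w.name, status="no_occupancy")
            continue
        except NoDataError:
            status = "unavailable" if w.name == "LT" else "no_data"
            results[w.name] = RiskAssessment(w.name, status=status)
            continue
        if not w.occupancy_conditioned:
            results[w.name] = RiskAssessment(
                w.name,
                amrc=amrc,
                coverage_fraction=coverage,
                low_confidence=coverage < min_coverage,
            )
            continue
        mask = occupancy_mask(schedule, asof - w.span, asof)
        occupied_hours = _intervals_hours(mask)
        days = w.span.total_seconds() / 86400.0
        dao = occupied_hours / days
        ied = window_ied(amrc, occupied_hours, config)
        iaed = annualize(amrc, dao, config)
        results[w.name] = RiskAssessment(
            w.name,
            amrc=amrc,
            occupied_hours=occupied_hours,
            dao=dao,
            ied_mSv=ied,
            iaed_mSv=iaed,
            irrei=classify_irrei(iaed, config),
            coverage_fraction=coverage,
            low_confidence=coverage < min_coverage,
        )
    return results
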