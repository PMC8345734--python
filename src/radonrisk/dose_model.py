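"""Closed-form radon dose and risk arithmetic.

Exposure integrals, effective dose, annualized dose (IAED), the four-level
IRREI classification, excess relative risk, and dose-coefficient conversions.

Two dose-coefficient conventions exist in the literature and both are
supported, distinguished by :class:`CoefficientBasis`:

* ``EEC`` — the coefficient applies to equilibrium-equivalent exposure, so
  the equilibrium factor F multiplies the gas exposure (e.g. 9 nSv per
  Bq·m⁻³·h with F = 0.4).
* ``GAS`` — the coefficient applies directly to radon-gas exposure with F
  already embedded (e.g. 6.7×10⁻⁹ Sv per Bq·m⁻³·h, derived from the ICRP-137
  3 mSv per mJ·h·m⁻³ value at F = 0.4).

The basis is carried in the type, so F can never be applied twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, Tuple

__all__ = [
    "CoefficientBasis",
    "DoseCoefficient",
    "DoseModelConfig",
    "ExposureSegment",
    "IrreiLevel",
    "LEVEL_COLORS",
    "ValidationError",
    "classify_irrei",
    "cumulative_exposure",
    "default_config",
    "effective_dose",
    "err_from_rr",
    "gas_coefficient_from_paec",
    "iaed_from_aao",
    "iaed_from_dao",
    "occupancy_percent",
    "worked_example_gas_config",
]

#: mJ·m⁻³ of potential alpha energy per Bq·m⁻³ of equilibrium-equivalent
#: radon concentration (standard PAEC conversion constant).
PAEC_PER_EEC = 5.56e-6

LEVEL_COLORS = {1: "green", 2: "yellow", 3: "orange", 4: "red"}

#: Hex codes used for figures; fixed here for reproducibility.
LEVEL_HEX = {1: "#2ca02c", 2: "#ffd700", 3: "#ff8c00", 4: "#d62728"}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class CoefficientBasis(str, Enum):
    EEC = "EEC"
    GAS = "GAS"


@dataclass(frozen=True)
class ExposureSegment:
    """A spell of constant radon concentration.

    Parameters
    ----------
    concentration:
        Radon activity concentration in Bq·m⁻³ (non-negative).
    duration:
        Exposure time in hours (non-negative).
    """

    concentration: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.concentration >= 0):
            raise ValidationError(
                f"concentration must be >= 0, got {self.concentration!r}"
            )
        if not (self.duration >= 0):
            raise ValidationError(f"duration must be >= 0, got {self.duration!r}")

    @property
    def exposure(self) -> float:
        """Gas exposure of this segment, Bq·m⁻³·h."""
        return self.concentration * self.duration


@dataclass(frozen=True)
class DoseCoefficient:
    """Dose per unit exposure, Sv per Bq·m⁻³·h, with its convention."""

    value: float
    basis: CoefficientBasis

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValidationError(f"coefficient value must be > 0, got {self.value!r}")
        object.__setattr__(self, "basis", CoefficientBasis(self.basis))


@dataclass(frozen=True)
class DoseModelConfig:
    """Everything needed to turn exposures into doses and risk levels."""

    equilibrium_factor: float = 0.4
    coefficient: DoseCoefficient = field(
        default_factory=lambda: DoseCoefficient(9e-9, CoefficientBasis.EEC)
    )
    days_per_year: float = 365.0
    hours_per_year_full: float = 8760.0
    thresholds_mSv: Tuple[float, float, float] = (1.0, 5.0, 20.0)

    def __post_init__(self) -> None:
        if not (0 < self.equilibrium_factor <= 1):
            raise ValidationError(
                f"equilibrium factor must be in (0, 1], got {self.equilibrium_factor!r}"
            )
        t = tuple(float(x) for x in self.thresholds_mSv)
        if len(t) != 3 or not (0 < t[0] < t[1] < t[2]):
            raise ValidationError(
                f"thresholds must be a strictly increasing positive triple, got {t!r}"
            )
        object.__setattr__(self, "thresholds_mSv", t)


def default_config() -> DoseModelConfig:
    """Default convention: EEC 9 nSv per Bq·m⁻³·h with F = 0.4."""
    return DoseModelConfig()


def worked_example_gas_config() -> DoseModelConfig:
    """Gas-basis convention with 6.7×10⁻⁹ Sv per Bq·m⁻³·h (F embedded)."""
    return DoseModelConfig(
        coefficient=DoseCoefficient(6.7e-9, CoefficientBasis.GAS)
    )


@dataclass(frozen=True)
class IrreiLevel:
    """Integer risk level 1–4 with its bijective color name."""

    level: int

    def __post_init__(self) -> None:
        if self.level not in LEVEL_COLORS:
            raise ValidationError(f"level must be in 1..4, got {self.level!r}")

    @property
    def color(self) -> str:
        return LEVEL_COLORS[self.level]

    @property
    def hex_color(self) -> str:
        return LEVEL_HEX[self.level]

    def __int__(self) -> int:
        return self.level


def cumulative_exposure(segments: Iterable[ExposureSegment]) -> float:
    """Total gas exposure, Bq·m⁻³·h: Σ concentrationᵢ × durationᵢ.

    Additive over any partition of the segment list; the empty list is 0.
    """
    return float(sum(s.exposure for s in segments))


def effective_dose(exposure: float, config: DoseModelConfig) -> float:
    """Effective dose in Sv from a gas exposure in Bq·m⁻³·h.

    GAS basis: ``exposure × value``.  EEC basis: ``exposure × F × value``.
    Linear in exposure.
    """
    if not (exposure >= 0):
        raise ValidationError(f"exposure must be >= 0, got {exposure!r}")
    coeff = config.coefficient
    if coeff.basis is CoefficientBasis.GAS:
        return exposure * coeff.value
    return exposure * config.equilibrium_factor * coeff.value


def iaed_from_aao(aamrc: float, aao_hours: float, config: DoseModelConfig) -> float:
    """Indoor annual effective dose (mSv·year⁻¹) from annual mean
    concentration (Bq·m⁻³) and annual average occupancy (hours)."""
    if not (aamrc >= 0):
        raise ValidationError(f"aamrc must be >= 0, got {aamrc!r}")
    if not (0 <= aao_hours <= config.hours_per_year_full):
        raise ValidationError(
            f"aao_hours must be in [0, {config.hours_per_year_full}], got {aao_hours!r}"
        )
    return effective_dose(aamrc * aao_hours, config) * 1e3


def iaed_from_dao(aamrc: float, dao: float, config: DoseModelConfig) -> float:
    """IAED (mSv·year⁻¹) from annual mean concentration and daily average
    occupation (hours per day); AAO = days_per_year × DAO."""
    if not (0 <= dao <= 24):
        raise ValidationError(f"dao must be in [0, 24] hours, got {dao!r}")
    return iaed_from_aao(aamrc, config.days_per_year * dao, config)


def classify_irrei(iaed: float, config: DoseModelConfig) -> IrreiLevel:
    """Map an IAED (mSv·year⁻¹) to the four-level indicator.

    Intervals: (−∞, τ₁] → 1 green; (τ₁, τ₂) → 2 yellow; [τ₂, τ₃] → 3 orange;
    (τ₃, ∞) → 4 red, with default thresholds (1, 5, 20) mSv·year⁻¹.
    """
    if not (iaed >= 0):
        raise ValidationError(f"iaed must be >= 0, got {iaed!r}")
    t1, t2, t3 = config.thresholds_mSv
    if iaed <= t1:
        return IrreiLevel(1)
    if iaed < t2:
        return IrreiLevel(2)
    if iaed <= t3:
        return IrreiLevel(3)
    return IrreiLevel(4)


def err_from_rr(rr: float) -> float:
    """Excess relative risk from relative risk: ERR = RR − 1."""
    if not (rr >= 0):
        raise ValidationError(f"relative risk must be >= 0, got {rr!r}")
    return rr - 1.0


def gas_coefficient_from_paec(paec_coeff: float, f: float) -> DoseCoefficient:
    """Convert a PAEC dose coefficient (Sv per mJ·h·m⁻³) into a gas-basis
    coefficient (Sv per Bq·m⁻³·h) at equilibrium factor ``f``.

    Returns ``paec_coeff × 5.56e-6 × f`` wrapped as a GAS-basis coefficient,
    so downstream dose math will not apply ``f`` a second time.
    """
    if not (paec_coeff > 0):
        raise ValidationError(f"paec_coeff must be > 0, got {paec_coeff!r}")
    if not (0 < f <= 1):
        raise ValidationError(f"equilibrium factor must be in (0, 1], got {f!r}")
    return DoseCoefficient(paec_coeff * PAEC_PER_EEC * f, CoefficientBasis.GAS)


def occupancy_percent(aao_hours: float, config: DoseModelConfig) -> float:
    """Annual occupancy as a percentage of the full calendar year."""
    if not (0 <= aao_hours <= config.hours_per_year_full):
        raise ValidationError(
            f"aao_hours must be in [0, {config.hours_per_year_full}], got {aao_hours!r}"
        )
    return 100.0 * aao_hours / config.hours_per_year_full


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
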