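"""Reference abacus: annual dose over an (AAMRC × DAO) lattice.

The grid evaluates the annualized-dose formula at every (concentration,
daily-occupation) cell, attaches the four-level classification, and exposes
the analytic level-boundary curves; it exports to long-format CSV and to a
color-banded figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .dose_model import (
    LEVEL_COLORS,
    LEVEL_HEX,
    CoefficientBasis,
    DoseModelConfig,
    IrreiLevel,
    ValidationError,
    classify_irrei,
    iaed_from_dao,
)

__all__ = ["AbacusGrid", "BoundaryResult", "build_grid", "boundary_dao", "lookup", "export"]


@dataclass(frozen=True)
class AbacusGrid:
    aamrc_axis: np.ndarray  # ascending, Bq·m⁻³
    dao_axis: np.ndarray  # ascending, hours in [0, 24]
    iaed: np.ndarray  # mSv·year⁻¹, shape (len(aamrc), len(dao))
    level: np.ndarray  # int 1..4, same shape
    config: DoseModelConfig

    def __post_init__(self) -> None:
        if self.iaed.shape != (len(self.aamrc_axis), len(self.dao_axis)):
            raise ValidationError("iaed matrix shape does not match axes")


@dataclass(frozen=True)
class BoundaryResult:
    """DAO at which the dose crosses a threshold for a given concentration."""

    dao_hours: float  # clipped to [0, 24]
    reachable: bool  # False when the unclipped boundary exceeds 24 h


def default_axes() -> Tuple[np.ndarray, np.ndarray]:
    """0–1270 Bq·m⁻³ in 10 Bq·m⁻³ steps × 0–24 h in 0.25 h steps."""
    return np.arange(0.0, 1270.0 + 1e-9, 10.0), np.arange(0.0, 24.0 + 1e-9, 0.25)


def build_grid(
    aamrc_axis=None, dao_axis=None, config: Optional[DoseModelConfig] = None
) -> AbacusGrid:
    """Evaluate IAED and the risk level over the lattice."""
    config = config or DoseModelConfig()
    if aamrc_axis is None or dao_axis is None:
        d_aamrc, d_dao = default_axes()
        aamrc_axis = d_aamrc if aamrc_axis is None else np.asarray(aamrc_axis, float)
        dao_axis = d_dao if dao_axis is None else np.asarray(dao_axis, float)
    else:
        aamrc_axis = np.asarray(aamrc_axis, float)
        dao_axis = np.asarray(dao_axis, float)
    for name, axis in (("aamrc_axis", aamrc_axis), ("dao_axis", dao_axis)):
        if axis.ndim != 1 or len(axis) == 0 or np.any(np.diff(axis) <= 0):
            raise ValidationError(f"{name} must be a non-empty ascending 1-D array")
    if np.any(aamrc_axis < 0):
        raise ValidationError("aamrc_axis must be non-negative")
    if np.any(dao_axis < 0) or np.any(dao_axis > 24):
        raise ValidationError("dao_axis must lie within [0, 24] hours")
    iaed = np.empty((len(aamrc_axis), len(dao_axis)))
    level = np.empty_like(iaed, dtype=int)
    for i, c in enumerate(aamrc_axis):
        for j, d in enumerate(dao_axis):
            iaed[i, j] = iaed_from_dao(float(c), float(d), config)
            level[i, j] = classify_irrei(iaed[i, j], config).level
    return AbacusGrid(aamrc_axis, dao_axis, iaed, level, config)


def boundary_dao(
    aamrc: float, threshold_mSv: float, config: Optional[DoseModelConfig] = None
) -> BoundaryResult:
    """Solve iaed_from_dao(aamrc, dao) = threshold for dao.

    The formula is linear in DAO, so the boundary is
    threshold / (aamrc × F × days_per_year × coefficient).  The result is
    clipped to [0, 24] with ``reachable=False`` when the true crossing lies
    beyond a full day.
    """
    config = config or DoseModelConfig()
    if not (aamrc > 0):
        raise ValidationError(
            f"boundary is undefined for aamrc <= 0, got {aamrc!r}"
        )
    if not (threshold_mSv > 0):
        raise ValidationError(f"threshold must be > 0, got {threshold_mSv!r}")
    coeff = config.coefficient
    per_hour = aamrc * coeff.value * config.days_per_year * 1e3
    if coeff.basis is CoefficientBasis.EEC:
        per_hour *= config.equilibrium_factor
    dao = threshold_mSv / per_hour
    if dao > 24:
        return BoundaryResult(24.0, reachable=False)
    return BoundaryResult(dao, reachable=True)


def lookup(
    grid: AbacusGrid, amrc: float, dao: float
) -> Tuple[float, IrreiLevel]:
    """Exact re-evaluation of the dose formula at an arbitrary in-range
    point (no interpolation); matches the grid cell on-lattice."""
    if not (grid.aamrc_axis[0] <= amrc <= grid.aamrc_axis[-1]):
        raise ValidationError(
            f"amrc {amrc!r} outside axis range "
            f"[{grid.aamrc_axis[0]}, {grid.aamrc_axis[-1]}]"
        )
    if not (grid.dao_axis[0] <= dao <= grid.dao_axis[-1]):
        raise ValidationError(
            f"dao {dao!r} outside axis range [{grid.dao_axis[0]}, {grid.dao_axis[-1]}]"
        )
    iaed = iaed_from_dao(amrc, dao, grid.config)
    return iaed, classify_irrei(iaed, grid.config)


def to_frame(grid: AbacusGrid) -> pd.DataFrame:
    """Long-format table: one row per (aamrc, dao) cell."""
    rows = []
    for i, c in enumerate(grid.aamrc_axis):
        for j, d in enumerate(grid.dao_axis):
            lvl = int(grid.level[i, j])
            rows.append(
                {
                    "aamrc_Bq_m3": float(c),
                    "dao_hours": float(d),
                    "iaed_mSv_per_year": float(grid.iaed[i, j]),
                    "level": lvl,
                    "color": LEVEL_COLORS[lvl],
                }
            )
    return pd.DataFrame(rows)


def export(grid: AbacusGrid, path, format: str = "csv") -> Path:
    """Write the grid as long-format CSV or as a color-banded figure."""
    path = Path(path)
    if format == "csv":
        try:
            to_frame(grid).to_csv(path, index=False, float_format="%.10g")
        except OSError as exc:
            raise OSError(f"cannot write abacus CSV to {path}: {exc}") from exc
        return path
    if format == "figure":
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        fig, ax = plt.subplots(figsize=(8, 5))
        cmap = ListedColormap([LEVEL_HEX[k] for k in (1, 2, 3, 4)])
        norm = BoundaryNorm([0.5, 1.5, 2.5, 3.5, 4.5], cmap.N)
        ax.pcolormesh(
            grid.dao_axis, grid.aamrc_axis, grid.level, cmap=cmap, norm=norm,
            shading="nearest",
        )
        for tau in grid.config.thresholds_mSv:
            cs = [c for c in grid.aamrc_axis if c > 0]
            daos, concs = [], []
            for c in cs:
                b = boundary_dao(float(c), tau, grid.config)
                if b.reachable:
                    daos.append(b.dao_hours)
                    concs.append(c)
            if daos:
                ax.plot(daos, concs, "k-", lw=1)
                ax.annotate(
                    f"{tau:g} mSv/y",
                    (daos[len(daos) // 2], concs[len(concs) // 2]),
                    fontsize=8,
                )
        ax.set_xlabel("Daily average occupation (h)")
        ax.set_ylabel("Annual mean radon concentration (Bq·m⁻³)")
        ax.set_title("Annual effective dose risk bands")
        try:
            fig.savefig(path, dpi=120)
        except OSError as exc:
            raise OSError(f"cannot write abacus figure to {path}: {exc}") from exc
        finally:
            plt.close(fig)
        return path
    raise ValidationError(f"unknown export format {format!r}; use 'csv' or 'figure'")
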