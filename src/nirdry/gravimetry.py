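"""Gravimetric reference analytics for drying studies.

Each dish is weighed three times: fresh (``m0``), after the scheduled air
drying (``m1``) and after complete oven drying (``m2``).  From these masses
two moisture quantities follow:

* initial moisture  ``M_init = (m0 - m2) / m0 * 100``  — total water content
  of the fresh sample as % of fresh mass;
* air-dry moisture  ``M_airdry = (m0 - m1) / m0 * 100`` — relative weight
  loss at measurement time, used interchangeably with "weight loss" since it
  is literally the lost water as % of fresh mass.

Combining the measured water with the manufacturer's declared composition
closes the mass balance; the remainder ("other") may be negative, which
flags an inconsistency between scale and declaration and is returned
unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CompositionDeclaration:
    """Manufacturer nutrition declaration, % per 100 g of product."""

    fat: float
    sugar: float
    CHO: float
    protein: float
    salt: float

    def __post_init__(self) -> None:
        for name in ("fat", "sugar", "CHO", "protein", "salt"):
            if getattr(self, name) < 0:
                raise ValueError(f"declared {name} must be non-negative")
        if self.total() > 100:
            raise ValueError("declared components exceed 100 g per 100 g")

    def total(self) -> float:
        return self.fat + self.sugar + self.CHO + self.protein + self.salt


@dataclass(frozen=True)
class SampleRecord:
    """One dish's identifying labels, masses (g) and air-drying time (h)."""

    sample_id: str
    food_type: str
    m0: float
    m1: float
    m2: float
    t_air: float = 0.0

    def __post_init__(self) -> None:
        if not (self.m0 >= self.m1 >= self.m2 > 0):
            raise ValueError(
                f"masses must satisfy m0 >= m1 >= m2 > 0, got "
                f"({self.m0}, {self.m1}, {self.m2})"
            )
        if self.t_air < 0:
            raise ValueError("air-drying time must be non-negative")


def _check_masses(m0: float, m_later: float) -> None:
    if m0 <= 0 or m_later <= 0:
        raise ValueError("masses must be positive")
    if m_later > m0:
        raise ValueError("dried mass cannot exceed fresh mass")


def initial_moisture(m0: float, m2: float) -> float:
    """Total water content of the fresh sample, % of fresh mass.

    ``m0`` is the fresh mass, ``m2`` the mass after complete oven drying.
    """
    _check_masses(m0, m2)
    return (m0 - m2) / m0 * 100.0


def airdry_moisture(m0: float, m1: float) -> float:
    """Relative weight loss after ambient air drying, % of fresh mass."""
    _check_masses(m0, m1)
    return (m0 - m1) / m0 * 100.0


# weight loss and air-dry moisture are the same computation under two names
weight_loss = airdry_moisture


def declared_drymatter(declaration: CompositionDeclaration) -> float:
    """Sum of the declared components (fat + sugar + CHO + protein + salt)."""
    return declaration.total()


def residual_other(declaration: CompositionDeclaration, water: float) -> float:
    """Undeclared remainder of the mass balance, % per 100 g.

    ``100 - (water + declared dry matter)``; negative values are returned
    as-is since they indicate an error in either the water measurement or
    the declaration and the caller decides how to treat them.
    """
    if not 0 <= water <= 100:
        raise ValueError(f"water content must be in [0, 100], got {water}")
    return 100.0 - (water + declaration.total())


def linear_window_fit(
    times_h: np.ndarray, weight_loss_pct: np.ndarray, window_h: float = 4.0
) -> tuple[float, float, float]:
    """Least-squares line through the early drying window.

    Fits ``weight_loss ~ slope * t + intercept`` using only points with
    ``t <= window_h`` (default 4 h, the span over which drying is close to
    proportional to time).  Returns ``(slope, intercept, r_squared)``.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(weight_loss_pct, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and weight losses must have equal length")
    mask = t <= window_h
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 points with t <= {window_h} h, got {int(mask.sum())}"
        )
    t, y = t[mask], y[mask]
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return float(slope), float(intercept), float(r2)


def mass_balance_report(
    declarations: dict[str, CompositionDeclaration],
    water_by_sample: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample mass-balance table.

    ``water_by_sample`` must have columns ``sample_id`` and ``water`` (one
    row per measured dish is fine; rows are aggregated per sample).  The
    output has one row per sample ID with the declared dry matter, the mean
    measured water, its standard deviation (SD, population) and the "other"
    residual computed from the mean water.
    """
    rows = []
    grouped = water_by_sample.groupby("sample_id")["water"]
    for sid, decl in declarations.items():
        if sid not in grouped.groups:
            continue
        vals = grouped.get_group(sid).to_numpy(dtype=float)
        water_mean = float(vals.mean())
        rows.append(
            {
                "sample_id": sid,
                "declared_drymatter": declared_drymatter(decl),
                "water_mean": water_mean,
                "water_sd": float(vals.std()),  # population SD, labelled SD
                "other": residual_other(decl, water_mean),
            }
        )
    return pd.DataFrame(rows)
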