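"""Minimal blister-card areas for rectangular alveolus grids and the savings
they yield over marketed cards.

The model: ``n`` chambers are placed on an r × c rectangular grid with a
uniform seal margin ``k`` between neighbouring chambers and between every
chamber and the card edge.  For round chambers of base diameter ``d`` the
card then measures (r·d + (r+1)·k) × (c·d + (c+1)·k); elongated chambers of
base e × f are oriented with f across the rows and e along them.  The
two-row closed form

    (2d + 3k) × (k + n/2 · (k + d))

is the r = 2 special case and is evaluated literally for odd n (fractional
columns); the grid form requires integer factorizations.

Seal margins are material-bound: cold-formed aluminum-aluminum laminates
need a 4 mm welding area, thermoformed plastic-containing laminates 2 mm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import (
    MM2_PER_CM2,
    AlveolusShape,
    AlveolusSpec,
    BlisterCardRecord,
    Material,
    alveolus_base_area,
    card_face_area,
)

logger = logging.getLogger(__name__)

#: Mean base diameter (mm) of the round alveoli among the 27 round-tablet
#: products, calibrated so the generalized grid formula reproduces the full
#: published 24-chamber arrangement table at printed precision.
MEAN_ROUND_ALVEOLUS_D_MM = 11.0

#: Seal margin applied to unknown materials (conservative: the Al-Al value).
FALLBACK_MARGIN_MM = 4.0

DEFAULT_MARGINS_MM: dict[Material, float] = {
    Material.al_al: 4.0,
    Material.al_plastic: 2.0,
    Material.plastic: 2.0,
}


class LayoutSpec(BaseModel):
    """A candidate arrangement: rows × columns with seal margin k."""

    model_config = ConfigDict(frozen=True)

    n_rows: int = Field(ge=1)
    n_cols: int = Field(ge=1)
    margin_k_mm: float = Field(ge=0)


class SealPolicy(BaseModel):
    """Material-dependent seal margins and the target number of rows."""

    margin_by_material: dict[Material, float] = Field(
        default_factory=lambda: dict(DEFAULT_MARGINS_MM)
    )
    n_rows: int = Field(default=2, ge=1)

    @model_validator(mode="after")
    def _non_negative(self) -> "SealPolicy":
        if any(v < 0 for v in self.margin_by_material.values()):
            raise ValueError("seal margins must be >= 0")
        return self


def min_seal_margin(
    material: Material | str, policy: Optional[SealPolicy] = None
) -> float:
    """Minimum welding margin (mm) for a blister material.

    Unknown materials fall back to the conservative 4 mm Al-Al margin with a
    logged warning.
    """
    margins = (policy or SealPolicy()).margin_by_material
    try:
        return margins[Material(material)]
    except (ValueError, KeyError):
        logger.warning(
            "unknown blister material %r: using conservative %.1f mm seal margin",
            material,
            FALLBACK_MARGIN_MM,
        )
        return FALLBACK_MARGIN_MM


def _base_dims(alv: AlveolusSpec) -> tuple[float, float]:
    """(across-row, along-row) chamber base dimensions in mm."""
    if alv.shape is AlveolusShape.round:
        return alv.d_mm, alv.d_mm
    return alv.f_mm, alv.e_mm


def grid_area(r: int, cols: int, alv: AlveolusSpec, k_mm: float) -> float:
    """Card area (cm²) for an r × cols chamber grid with seal margin k."""
    if r < 1 or cols < 1:
        raise ValueError("rows and columns must be >= 1")
    if k_mm < 0:
        raise ValueError("seal margin must be >= 0")
    across, along = _base_dims(alv)
    width = r * across + (r + 1) * k_mm
    length = cols * along + (cols + 1) * k_mm
    return width * length / MM2_PER_CM2


def n_row_area(alv: AlveolusSpec, n: int, k_mm: float, n_rows: int = 2) -> float:
    """Card area (cm²) for n chambers in ``n_rows`` rows, fractional columns.

    The closed form (r·dim + (r+1)k) × (k + n/r · (k + dim)) evaluates the
    two-row published equation at r = 2 and permits odd n via fractional
    columns; for integer n/r it coincides with :func:`grid_area`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k_mm < 0:
        raise ValueError("seal margin must be >= 0")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    across, along = _base_dims(alv)
    width = n_rows * across + (n_rows + 1) * k_mm
    length = k_mm + (n / n_rows) * (k_mm + along)
    return width * length / MM2_PER_CM2


def two_row_area(alv: AlveolusSpec, n: int, k_mm: float) -> float:
    """Minimal card area (cm²) with the chambers grouped into two rows."""
    return n_row_area(alv, n, k_mm, n_rows=2)


def interspace_area(r: int, cols: int, alv: AlveolusSpec, k_mm: float) -> float:
    """Card area not occupied by chamber bases (cm²) for an r × cols grid."""
    n = r * cols
    return grid_area(r, cols, alv, k_mm) - n * alveolus_base_area(alv) / MM2_PER_CM2


def savings_percent(measured_cm2: float, optimized_cm2: float) -> float:
    """Material saving of the optimized card relative to the marketed card.

    The marketed area is taken as 100%; negative savings indicate the
    optimization would enlarge the card.
    """
    if measured_cm2 <= 0:
        raise ValueError("measured area must be positive")
    return 100.0 * (measured_cm2 - optimized_cm2) / measured_cm2


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of re-arranging one card's chambers."""

    brand_id: str
    measured_cm2: float
    optimized_cm2: float
    savings_pct: float
    margin_mm: float
    n_rows: int


def optimize_card(
    card: BlisterCardRecord, policy: Optional[SealPolicy] = None
) -> OptimizationResult:
    """Re-arrange a card's chambers into the policy's row count with the
    material-appropriate seal margin and report the area saving."""
    policy = policy or SealPolicy()
    margin = min_seal_margin(card.material, policy)
    optimized = n_row_area(card.alveolus, card.n_sodf, margin, policy.n_rows)
    measured = card_face_area(card)
    return OptimizationResult(
        brand_id=card.brand_id,
        measured_cm2=measured,
        optimized_cm2=optimized,
        savings_pct=savings_percent(measured, optimized),
        margin_mm=margin,
        n_rows=policy.n_rows,
    )


def optimize_cohort(
    records: Sequence[BlisterCardRecord], policy: Optional[SealPolicy] = None
) -> pd.DataFrame:
    """Per-product optimization table for a measurement cohort.

    Columns: brand_id, shape, material, measured_cm2, margin_mm,
    optimized_cm2, savings_pct.  Cohort savings are means of per-product
    percentages (mean of ratios), matching the reporting convention used for
    the published cohort figures.
    """
    rows = []
    for card in records:
        res = optimize_card(card, policy)
        rows.append(
            {
                "brand_id": res.brand_id,
                "shape": card.sodf.shape.value,
                "material": card.material.value,
                "measured_cm2": res.measured_cm2,
                "margin_mm": res.margin_mm,
                "optimized_cm2": res.optimized_cm2,
                "savings_pct": res.savings_pct,
            }
        )
    return pd.DataFrame(rows)


def savings_by_class(per_product: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of measured/optimized areas and savings by shape class."""
    grouped = per_product.groupby("shape")
    out = grouped.agg(
        n=("brand_id", "size"),
        measured_mean_cm2=("measured_cm2", "mean"),
        measured_sd_cm2=("measured_cm2", "std"),
        optimized_mean_cm2=("optimized_cm2", "mean"),
        optimized_sd_cm2=("optimized_cm2", "std"),
        savings_mean_pct=("savings_pct", "mean"),
        savings_sd_pct=("savings_pct", "std"),
    )
    return out.reset_index()


def arrangement_sweep(
    n: int,
    alv: AlveolusSpec,
    k_list: Iterable[float],
    row_options: Iterable[int],
) -> pd.DataFrame:
    """Card areas for alternative row counts, normalized per margin column.

    For every (rows, k) pair with rows dividing n the grid area is computed;
    percentages are relative to the squarest listed feasible arrangement
    (minimal \\|rows − cols\\|), which defines 100%.  Row counts that do not
    divide n are flagged infeasible.  ``percent_of_squarest`` is rounded to
    integers, mirroring the published presentation; ``area_cm2`` stays at
    full precision.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows_list = sorted(set(int(r) for r in row_options))
    records = []
    for k in k_list:
        feasible = {}
        for r in rows_list:
            if r < 1 or n % r != 0:
                records.append(
                    {
                        "n_rows": r,
                        "n_cols": math.nan,
                        "k_mm": float(k),
                        "area_cm2": math.nan,
                        "percent_of_squarest": pd.NA,
                        "feasible": False,
                    }
                )
                continue
            cols = n // r
            feasible[r] = (cols, grid_area(r, cols, alv, k))
        if feasible:
            ref_rows = min(feasible, key=lambda r: abs(r - feasible[r][0]))
            ref_area = feasible[ref_rows][1]
            for r, (cols, area) in feasible.items():
                records.append(
                    {
                        "n_rows": r,
                        "n_cols": cols,
                        "k_mm": float(k),
                        "area_cm2": area,
                        "percent_of_squarest": round(100.0 * area / ref_area),
                        "feasible": True,
                    }
                )
    df = pd.DataFrame(records).sort_values(["k_mm", "n_rows"]).reset_index(drop=True)
    df["percent_of_squarest"] = df["percent_of_squarest"].astype("Int64")
    return df
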