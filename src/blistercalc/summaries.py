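"""Cohort descriptive statistics: shape-class summaries, generic-group
variability factors, and rank correlations.

Summaries follow the measurement study's reporting convention: mean ±
sample SD (n−1 denominator) and range per shape class; classes with n ≤ 2
(the capsules) list their raw values individually and never report a mean.
Correlations are Spearman's rho with mid-ranks for ties; the two-sided p
value is exact (full permutation enumeration) for n ≤ 9 and uses the
t-approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    BlisterCardRecord,
    alveolus_area_fraction,
    alveolus_base_area,
    alveolus_to_sodf_area_ratio,
    area_per_sodf,
    card_face_area,
    sodf_footprint_area,
    sodf_volume_estimate,
    tare_weight_percent,
)

#: Classes with at most this many members are reported individually.
SMALL_CLASS_MAX_N = 2


def card_metrics_frame(records: Sequence[BlisterCardRecord]) -> pd.DataFrame:
    """One row of derived metrics per card, the basis of every summary."""
    rows = []
    for card in records:
        volume = sodf_volume_estimate(card.sodf)
        face = card_face_area(card)
        rows.append(
            {
                "brand_id": card.brand_id,
                "shape": card.sodf.shape.value,
                "material": card.material.value,
                "strength_mg": card.sodf.strength_mg,
                "package_size": card.package_size,
                "cards_per_pack": card.cards_per_pack,
                "sodf_per_card": card.n_sodf,
                "card_area_cm2": face,
                "package_blister_area_cm2": face * card.cards_per_pack,
                "area_per_sodf_cm2": area_per_sodf(card),
                "alveolus_area_mm2": alveolus_base_area(card.alveolus),
                "alveolus_fraction_pct": alveolus_area_fraction(card),
                "sodf_footprint_mm2": sodf_footprint_area(card.sodf),
                "alveolus_sodf_ratio": alveolus_to_sodf_area_ratio(card),
                "sodf_volume_mm3": volume if volume is not None else math.nan,
                "sodf_mass_g": card.sodf.mass_g,
                "gross_weight_g": card.gross_weight_g,
                "tare_pct": tare_weight_percent(card),
            }
        )
    return pd.DataFrame(rows)


SUMMARY_METRICS = [
    "strength_mg",
    "package_size",
    "cards_per_pack",
    "sodf_per_card",
    "card_area_cm2",
    "package_blister_area_cm2",
    "area_per_sodf_cm2",
    "alveolus_area_mm2",
    "alveolus_fraction_pct",
    "sodf_volume_mm3",
    "sodf_mass_g",
    "gross_weight_g",
    "tare_pct",
]


def summarize_by_shape(records: Sequence[BlisterCardRecord]) -> pd.DataFrame:
    """Long-form shape-class summary of every cohort metric.

    Columns: shape_class ("all" plus each present class), metric, n, mean,
    sd, min, max, values.  For classes with n ≤ 2 the aggregate columns are
    NaN and ``values`` holds the individual measurements.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    df = card_metrics_frame(records)
    classes: list[tuple[str, pd.DataFrame]] = [("all", df)]
    classes += [(shape, sub) for shape, sub in df.groupby("shape", sort=True)]
    rows = []
    for name, sub in classes:
        small = name != "all" and len(sub) <= SMALL_CLASS_MAX_N
        for metric in SUMMARY_METRICS:
            vals = sub[metric].dropna()
            row = {
                "shape_class": name,
                "metric": metric,
                "n": int(len(vals)),
                "mean": math.nan,
                "sd": math.nan,
                "min": math.nan,
                "max": math.nan,
                "values": None,
            }
            if len(vals) == 0:
                rows.append(row)
                continue
            if small:
                row["values"] = [float(v) for v in vals]
            else:
                row.update(
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    min=float(vals.min()),
                    max=float(vals.max()),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def group_spread_factor(values: Iterable[float]) -> float:
    """Max/min ratio of a metric across the brands of one generic group."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty value set")
    if np.any(vals <= 0):
        raise ValueError("spread factor requires strictly positive values")
    return float(vals.max() / vals.min())


def generic_group_spreads(
    df: pd.DataFrame, metric: str, group_col: str = "active_ingredient"
) -> pd.DataFrame:
    """Per-group max/min spread factors of a metric across brands."""
    rows = [
        {"group": g, "n": len(sub), "factor": group_spread_factor(sub[metric])}
        for g, sub in df.groupby(group_col, sort=True)
    ]
    return pd.DataFrame(rows)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


#: Sample sizes up to which the permutation null is enumerated exactly.
EXACT_PERMUTATION_MAX_N = 9


def rank_correlation(
    x_values: Sequence[float], y_values: Sequence[float]
) -> tuple[float, float]:
    """Spearman's rho and its two-sided p value.

    For n ≤ 9 the p value enumerates all n! pairings of the rank vectors
    (exact under the null of no association); larger samples use the usual
    t-approximation with n − 2 degrees of freedom.  Constant input vectors
    leave the statistic undefined and raise ``ValueError``.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = _spearman_rho(x, y)
    if n <= EXACT_PERMUTATION_MAX_N:
        ry = stats.rankdata(y)
        observed = abs(rho)
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(stats.rankdata(x), ry[list(perm)])
            total += 1
            if abs(r) >= observed - 1e-12:
                hits += 1
        p = hits / total
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
        p = min(p, 1.0)
    return rho, p
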