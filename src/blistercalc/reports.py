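"""Report rendering: the five analysis tables as CSV and/or Markdown.

All upstream values are full precision; rounding happens here only, per the
conventions of the producing modules: areas to one decimal cm², savings and
arrangement percentages to integers, waste masses to integer tonnes, waste
areas to one decimal km², per-capita areas to two decimals, train lengths
to integer metres.  The CSV and Markdown renderings are produced from one
rounded frame, so they are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .geometry import BlisterCardRecord
from .layout import (
    MEAN_ROUND_ALVEOLUS_D_MM,
    SealPolicy,
    arrangement_sweep,
    optimize_cohort,
    savings_by_class,
)
from .geometry import AlveolusShape, AlveolusSpec
from .summaries import summarize_by_shape
from .waste import CohortWasteSummary, WasteEstimate

SUPPORTED_FORMATS = ("csv", "md")


@dataclass
class PipelineResults:
    """Everything the report renderer needs, computed upstream."""

    cards: Sequence[BlisterCardRecord]
    summary: pd.DataFrame
    savings_uniform: dict[float, pd.DataFrame]  # margin -> per-product table
    savings_policy: pd.DataFrame
    sweep: pd.DataFrame
    waste: Optional[CohortWasteSummary] = None


def build_results(
    cards: Sequence[BlisterCardRecord],
    ledger=None,
    constants=None,
    policy: Optional[SealPolicy] = None,
    market_ddd: Optional[float] = None,
    uniform_margins: Iterable[float] = (2.0, 3.0, 4.0),
) -> PipelineResults:
    """Run every analysis stage on a cohort."""
    from .waste import estimate_cohort_waste

    policy = policy or SealPolicy()
    savings_uniform = {}
    for k in uniform_margins:
        uniform = SealPolicy(
            margin_by_material={m: float(k) for m in policy.margin_by_material},
            n_rows=policy.n_rows,
        )
        savings_uniform[float(k)] = optimize_cohort(cards, uniform)
    waste = None
    if ledger is not None:
        waste = estimate_cohort_waste(cards, ledger, constants, market_ddd)
    return PipelineResults(
        cards=cards,
        summary=summarize_by_shape(cards),
        savings_uniform=savings_uniform,
        savings_policy=optimize_cohort(cards, policy),
        sweep=arrangement_sweep(
            24,
            AlveolusSpec(shape=AlveolusShape.round, d_mm=MEAN_ROUND_ALVEOLUS_D_MM),
            k_list=(2.0, 3.0, 4.0, 5.0),
            row_options=(1, 2, 3, 4),
        ),
        waste=waste,
    )


# ---------------------------------------------------------------------------
# table builders (rounded, presentation-ready)


def table1_summary(results: PipelineResults) -> pd.DataFrame:
    df = results.summary.copy()
    for col in ("mean", "sd", "min", "max"):
        df[col] = df[col].round(3)
    df["values"] = df["values"].map(
        lambda v: "/".join(f"{x:g}" for x in v) if isinstance(v, list) else ""
    )
    return df


def table2_waste(results: PipelineResults) -> pd.DataFrame:
    rows = []

    def add(scope: str, segment: str, est: WasteEstimate) -> None:
        rows.append(
            {
                "scope": scope,
                "segment": segment,
                "mass_t": round(est.mass_t),
                "train_m": round(est.train_m),
                "area_km2": round(est.area_km2, 1),
                "volume_m3": round(est.volume_m3),
                "per_capita_m2": round(est.per_capita_m2, 2),
            }
        )

    if results.waste is None:
        return pd.DataFrame(
            columns=[
                "scope",
                "segment",
                "mass_t",
                "train_m",
                "area_km2",
                "volume_m3",
                "per_capita_m2",
            ]
        )
    w = results.waste
    add("measured_cohort", "statutory", w.top_statutory)
    add("measured_cohort", "entire", w.top_entire)
    if w.market_statutory is not None:
        add("entire_market", "statutory", w.market_statutory)
        add("entire_market", "entire", w.market_entire)
    return pd.DataFrame(rows)


def table3_savings_by_margin(results: PipelineResults) -> pd.DataFrame:
    rows = []
    for k in sorted(results.savings_uniform):
        per_class = savings_by_class(results.savings_uniform[k])
        for _, r in per_class.iterrows():
            rows.append(
                {
                    "margin_mm": k,
                    "shape": r["shape"],
                    "n": int(r["n"]),
                    "measured_mean_cm2": round(r["measured_mean_cm2"], 1),
                    "measured_sd_cm2": round(r["measured_sd_cm2"], 1),
                    "optimized_mean_cm2": round(r["optimized_mean_cm2"], 1),
                    "optimized_sd_cm2": round(r["optimized_sd_cm2"], 1),
                    "savings_pct": round(r["savings_mean_pct"]),
                }
            )
    return pd.DataFrame(rows)


def table4_savings_policy(results: PipelineResults) -> pd.DataFrame:
    per_class = savings_by_class(results.savings_policy)
    out = per_class.copy()
    for col in (
        "measured_mean_cm2",
        "measured_sd_cm2",
        "optimized_mean_cm2",
        "optimized_sd_cm2",
    ):
        out[col] = out[col].round(1)
    out["savings_pct"] = out["savings_mean_pct"].round().astype(int)
    return out.drop(columns=["savings_mean_pct", "savings_sd_pct"])


def table5_arrangements(results: PipelineResults) -> pd.DataFrame:
    df = results.sweep.copy()
    df["area_cm2"] = df["area_cm2"].round(1)
    return df


TABLE_BUILDERS = {
    "table1_summary": table1_summary,
    "table2_waste": table2_waste,
    "table3_savings_by_margin": table3_savings_by_margin,
    "table4_savings_policy": table4_savings_policy,
    "table5_arrangements": table5_arrangements,
}


def _to_markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if pd.isna(v):
                cells.append("")
            elif isinstance(v, float):
                cells.append(f"{v:g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render_reports(
    results: PipelineResults,
    out_dir: Path | str,
    formats: Iterable[str] = ("csv", "md"),
) -> list[Path]:
    """Write every analysis table in the requested formats.

    Returns the written paths.  Unknown formats raise ``ValueError`` naming
    the supported ones.
    """
    formats = list(formats)
    for fmt in formats:
        if fmt not in SUPPORTED_FORMATS:
            raise ValueError(
                f"unknown format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, builder in TABLE_BUILDERS.items():
        df = builder(results)
        if "csv" in formats:
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        if "md" in formats:
            p = out_dir / f"{name}.md"
            p.write_text(_to_markdown(df), encoding="utf-8")
            written.append(p)
    return written
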