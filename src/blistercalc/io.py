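"""CSV and YAML I/O for measurement tables, DDD ledgers and constants.

Dialect: UTF-8, comma-separated, ``.`` decimal, mandatory header row.
Inapplicable shape fields (e.g. ``alv_d_mm`` for an elongated chamber) are
empty cells.  Reading is strict: a missing required column is a schema
error, and every malformed row is reported with its (1-based, data) row
number.  Writing preserves full precision so that write∘read is the
identity.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .geometry import (
    AlveolusShape,
    AlveolusSpec,
    BlisterCardRecord,
    Material,
    Shape,
    SodfSpec,
)
from .waste import DddLedgerEntry, MarketConstants

PathLike = Union[str, Path]

CARD_CSV_COLUMNS = [
    "brand_id",
    "material",
    "shape",
    "strength_mg",
    "n_sodf",
    "n_rows",
    "card_length_i_mm",
    "half_width_b_mm",
    "gross_weight_g",
    "gap_min_h_mm",
    "gap_max_g_mm",
    "alv_d_mm",
    "alv_e_mm",
    "alv_f_mm",
    "sodf_mass_g",
    "sodf_d_mm",
    "sodf_len_mm",
    "sodf_w_mm",
    "sodf_h_mm",
    "package_size",
    "cards_per_pack",
    "n_empty_fields",
    "empty_field_width_cprime_mm",
    "compartment_len_max_a_mm",
    "compartment_len_min_c_mm",
]

LEDGER_CSV_COLUMNS = ["brand_id", "ddd_dispensed", "who_ddd_mg", "include_in_market"]


class SchemaError(ValueError):
    """The file's header does not match the expected schema."""


class RowError(ValueError):
    """One or more data rows failed validation; messages carry row numbers."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def _record_to_row(card: BlisterCardRecord) -> dict:
    alv, sodf = card.alveolus, card.sodf
    return {
        "brand_id": card.brand_id,
        "material": card.material.value,
        "shape": sodf.shape.value,
        "strength_mg": sodf.strength_mg,
        "n_sodf": card.n_sodf,
        "n_rows": card.n_rows,
        "card_length_i_mm": card.card_length_i_mm,
        "half_width_b_mm": card.half_width_b_mm,
        "gross_weight_g": card.gross_weight_g,
        "gap_min_h_mm": card.gap_min_h_mm,
        "gap_max_g_mm": card.gap_max_g_mm,
        "alv_d_mm": alv.d_mm,
        "alv_e_mm": alv.e_mm,
        "alv_f_mm": alv.f_mm,
        "sodf_mass_g": sodf.mass_g,
        "sodf_d_mm": sodf.diameter_mm,
        "sodf_len_mm": sodf.length_mm,
        "sodf_w_mm": sodf.width_mm,
        "sodf_h_mm": sodf.height_mm,
        "package_size": card.package_size,
        "cards_per_pack": card.cards_per_pack,
        "n_empty_fields": card.n_empty_fields,
        "empty_field_width_cprime_mm": card.empty_field_width_cprime_mm,
        "compartment_len_max_a_mm": card.compartment_len_max_a_mm,
        "compartment_len_min_c_mm": card.compartment_len_min_c_mm,
    }


def _row_to_record(row: pd.Series) -> BlisterCardRecord:
    shape = Shape(str(row["shape"]))
    alv_d = _opt(row["alv_d_mm"])
    if alv_d is not None:
        alveolus = AlveolusSpec(shape=AlveolusShape.round, d_mm=alv_d)
    else:
        alveolus = AlveolusSpec(
            shape=AlveolusShape.elongated,
            e_mm=_opt(row["alv_e_mm"]),
            f_mm=_opt(row["alv_f_mm"]),
        )
    sodf = SodfSpec(
        shape=shape,
        strength_mg=float(row["strength_mg"]),
        diameter_mm=_opt(row["sodf_d_mm"]),
        length_mm=_opt(row["sodf_len_mm"]),
        width_mm=_opt(row["sodf_w_mm"]),
        height_mm=_opt(row["sodf_h_mm"]),
        mass_g=float(row["sodf_mass_g"]),
    )
    return BlisterCardRecord(
        brand_id=str(row["brand_id"]),
        material=Material(str(row["material"])),
        n_sodf=int(row["n_sodf"]),
        n_rows=int(row["n_rows"]),
        card_length_i_mm=float(row["card_length_i_mm"]),
        half_width_b_mm=float(row["half_width_b_mm"]),
        gross_weight_g=float(row["gross_weight_g"]),
        gap_min_h_mm=float(row["gap_min_h_mm"]),
        gap_max_g_mm=float(row["gap_max_g_mm"]),
        alveolus=alveolus,
        sodf=sodf,
        package_size=int(row["package_size"]),
        cards_per_pack=int(row["cards_per_pack"]),
        n_empty_fields=int(row["n_empty_fields"])
        if _opt(row["n_empty_fields"]) is not None
        else 0,
        empty_field_width_cprime_mm=_opt(row["empty_field_width_cprime_mm"]),
        compartment_len_max_a_mm=_opt(row["compartment_len_max_a_mm"]),
        compartment_len_min_c_mm=_opt(row["compartment_len_min_c_mm"]),
    )


def write_cards_csv(records: Sequence[BlisterCardRecord], path: PathLike) -> None:
    """Write a measurement table, one row per card, full precision."""
    df = pd.DataFrame([_record_to_row(c) for c in records], columns=CARD_CSV_COLUMNS)
    # %.17g guarantees read(write(x)) == x for every float
    df.to_csv(path, index=False, float_format="%.17g")


def read_cards_csv(path: PathLike) -> list[BlisterCardRecord]:
    """Read and validate a measurement table.

    Raises :class:`SchemaError` when required columns are missing and
    :class:`RowError` listing every rejected row with its row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CARD_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[BlisterCardRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValidationError, ValueError, KeyError) as exc:
            errors.append(f"row {int(idx) + 1}: {exc}")
    if errors:
        raise RowError(errors)
    return records


def write_ledger_csv(entries: Sequence[DddLedgerEntry], path: PathLike) -> None:
    """Write a DDD ledger (include flag as 0/1)."""
    df = pd.DataFrame(
        [
            {
                "brand_id": e.brand_id,
                "ddd_dispensed": e.ddd_dispensed,
                "who_ddd_mg": e.who_ddd_mg,
                "include_in_market": int(e.include_in_market),
            }
            for e in entries
        ],
        columns=LEDGER_CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_ledger_csv(path: PathLike) -> list[DddLedgerEntry]:
    """Read and validate a DDD ledger."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = [c for c in LEDGER_CSV_COLUMNS if c != "include_in_market"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_flag = "include_in_market" in df.columns
    entries: list[DddLedgerEntry] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            entries.append(
                DddLedgerEntry(
                    brand_id=str(row["brand_id"]),
                    ddd_dispensed=float(row["ddd_dispensed"]),
                    who_ddd_mg=float(row["who_ddd_mg"]),
                    include_in_market=bool(int(row["include_in_market"]))
                    if has_flag
                    else True,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {int(idx) + 1}: {exc}")
    if errors:
        raise RowError(errors)
    return entries


def read_constants_yaml(path: PathLike) -> MarketConstants:
    """Read market constants from YAML; absent keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError("constants file must be a YAML mapping")
    return MarketConstants(**data)


def write_constants_yaml(constants: MarketConstants, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(constants.model_dump(), fh, sort_keys=True)
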