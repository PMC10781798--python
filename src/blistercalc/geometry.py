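"""Measurement schema for marketed blister cards and per-card derived metrics.

A blister card of length ``i`` and full width ``2b`` carries ``n`` blister
chambers (alveoli) whose base is either a circle of diameter ``d`` or a
rectangle of width ``e`` and length ``f``, measured at the base of the
chamber.  ``h`` and ``g`` are the smallest and largest observed distances
between neighbouring chambers.  The card's gross weight includes the packed
dosage forms, so the packaging (tare) weight is always derived, never
measured.

Internal units are mm, mm² and g throughout; quantities conventionally
reported in cm² (card areas) are converted at the function boundary.
Rounded card corners are deliberately ignored: punched blister remnants end
up in the waste stream either way, so the bounding rectangle 2b × i is the
relevant material area.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: mm² per cm², used at every reporting boundary.
MM2_PER_CM2 = 100.0

#: Granularity of length and mass measurements (digital caliper / mg scale).
LENGTH_PRECISION_MM = 0.1
MASS_PRECISION_G = 0.001


class Shape(str, Enum):
    """Dosage-form shape class."""

    round = "round"
    elongated = "elongated"
    capsule = "capsule"


class AlveolusShape(str, Enum):
    """Base geometry of a blister chamber (capsules use the elongated base)."""

    round = "round"
    elongated = "elongated"


class Material(str, Enum):
    """Laminate class of the blister card."""

    al_al = "al_al"
    al_plastic = "al_plastic"
    plastic = "plastic"


class SodfSpec(BaseModel):
    """One solid oral dosage form (tablet or capsule).

    Round forms carry ``diameter_mm``; elongated forms and capsules carry
    ``length_mm`` and ``width_mm``.  ``height_mm`` is optional because it is
    not always retrievable from drug information systems; volume estimates
    are then unavailable rather than erroneous.
    """

    model_config = ConfigDict(frozen=True)

    shape: Shape
    strength_mg: float = Field(gt=0)
    diameter_mm: Optional[float] = Field(default=None, gt=0)
    length_mm: Optional[float] = Field(default=None, gt=0)
    width_mm: Optional[float] = Field(default=None, gt=0)
    height_mm: Optional[float] = Field(default=None, gt=0)
    mass_g: float = Field(gt=0)
    volume_mm3: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _shape_dimensions(self) -> "SodfSpec":
        if self.shape is Shape.round:
            if self.diameter_mm is None:
                raise ValueError("round SODF requires diameter_mm")
            if self.length_mm is not None or self.width_mm is not None:
                raise ValueError("round SODF must not carry length_mm/width_mm")
        else:
            if self.length_mm is None or self.width_mm is None:
                raise ValueError(
                    f"{self.shape.value} SODF requires length_mm and width_mm"
                )
            if self.diameter_mm is not None:
                raise ValueError(
                    f"{self.shape.value} SODF must not carry diameter_mm"
                )
        return self


class AlveolusSpec(BaseModel):
    """Blister-chamber base geometry, measured at the base of the alveolus."""

    model_config = ConfigDict(frozen=True)

    shape: AlveolusShape
    d_mm: Optional[float] = Field(default=None, gt=0)
    e_mm: Optional[float] = Field(default=None, gt=0)
    f_mm: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _shape_dimensions(self) -> "AlveolusSpec":
        if self.shape is AlveolusShape.round:
            if self.d_mm is None:
                raise ValueError("round alveolus requires d_mm")
            if self.e_mm is not None or self.f_mm is not None:
                raise ValueError("round alveolus must not carry e_mm/f_mm")
        else:
            if self.e_mm is None or self.f_mm is None:
                raise ValueError("elongated alveolus requires e_mm and f_mm")
            if self.d_mm is not None:
                raise ValueError("elongated alveolus must not carry d_mm")
        return self


class BlisterCardRecord(BaseModel):
    """One marketed blister card — a row of the measurement table.

    ``half_width_b_mm`` is the measured half-width b; the full card width is
    2b.  ``gross_weight_g`` includes the packed dosage forms.
    """

    model_config = ConfigDict(frozen=True)

    brand_id: str
    material: Material
    n_sodf: int = Field(ge=1)
    n_rows: int = Field(ge=1)
    card_length_i_mm: float = Field(gt=0)
    half_width_b_mm: float = Field(gt=0)
    gross_weight_g: float = Field(gt=0)
    gap_min_h_mm: float = Field(ge=0)
    gap_max_g_mm: float = Field(ge=0)
    compartment_len_max_a_mm: Optional[float] = Field(default=None, gt=0)
    compartment_len_min_c_mm: Optional[float] = Field(default=None, gt=0)
    n_empty_fields: int = Field(default=0, ge=0)
    empty_field_width_cprime_mm: Optional[float] = Field(default=None, gt=0)
    alveolus: AlveolusSpec
    sodf: SodfSpec
    package_size: int = Field(ge=1)
    cards_per_pack: int = Field(ge=1)

    @model_validator(mode="after")
    def _record_invariants(self) -> "BlisterCardRecord":
        if self.gap_min_h_mm > self.gap_max_g_mm + 1e-9:
            raise ValueError(
                f"gap_min_h_mm ({self.gap_min_h_mm}) exceeds gap_max_g_mm "
                f"({self.gap_max_g_mm})"
            )
        content_g = self.n_sodf * self.sodf.mass_g
        if self.gross_weight_g < content_g - 1e-9:
            raise ValueError(
                f"gross weight {self.gross_weight_g} g lighter than contained "
                f"SODF ({content_g} g)"
            )
        if self.package_size > self.cards_per_pack * self.n_sodf:
            raise ValueError(
                "package_size exceeds cards_per_pack × n_sodf "
                f"({self.package_size} > {self.cards_per_pack * self.n_sodf})"
            )
        face_mm2 = 2.0 * self.half_width_b_mm * self.card_length_i_mm
        alv_mm2 = self.n_sodf * alveolus_base_area(self.alveolus)
        if face_mm2 < alv_mm2 * (1.0 - 1e-9):
            raise ValueError(
                f"card face area {face_mm2:.1f} mm² smaller than total "
                f"alveolus base area {alv_mm2:.1f} mm²"
            )
        return self


# ---------------------------------------------------------------------------
# per-card derived quantities


def alveolus_base_area(alv: AlveolusSpec) -> float:
    """Base area of one blister chamber in mm².

    Round chambers: π (d/2)²; elongated chambers: e × f.
    """
    if alv.shape is AlveolusShape.round:
        return math.pi * (alv.d_mm / 2.0) ** 2
    return alv.e_mm * alv.f_mm


def card_face_area(card: BlisterCardRecord) -> float:
    """Total card face area 2b × i, in cm² (rounded corners ignored)."""
    return 2.0 * card.half_width_b_mm * card.card_length_i_mm / MM2_PER_CM2


def area_per_sodf(card: BlisterCardRecord) -> float:
    """Card face area apportioned to one dosage form, in cm²."""
    return card_face_area(card) / card.n_sodf


def alveolus_area_fraction(card: BlisterCardRecord) -> float:
    """Percentage of the card face occupied by alveolus bases, in (0, 100]."""
    face_mm2 = card_face_area(card) * MM2_PER_CM2
    return 100.0 * card.n_sodf * alveolus_base_area(card.alveolus) / face_mm2


def tare_weight_percent(card: BlisterCardRecord) -> float:
    """Packaging (tare) weight as a percentage of the gross weight."""
    content_g = card.n_sodf * card.sodf.mass_g
    return 100.0 * (card.gross_weight_g - content_g) / card.gross_weight_g


def sodf_footprint_area(sodf: SodfSpec) -> float:
    """Projected (plan-view) area of the dosage form in mm²."""
    if sodf.shape is Shape.round:
        return math.pi * (sodf.diameter_mm / 2.0) ** 2
    return sodf.length_mm * sodf.width_mm


def alveolus_to_sodf_area_ratio(card: BlisterCardRecord) -> float:
    """How many times larger the chamber base is than the packed form."""
    footprint = sodf_footprint_area(card.sodf)
    if footprint <= 0:
        raise ValueError("SODF footprint area must be positive")
    return alveolus_base_area(card.alveolus) / footprint


def sodf_volume_estimate(sodf: SodfSpec) -> Optional[float]:
    """Dosage-form volume in mm³, or ``None`` when the height is unknown.

    Round forms are treated as cylinders, elongated forms and capsules as
    elliptic cylinders (π/4 · length · width · height).
    """
    if sodf.height_mm is None:
        return None
    if sodf.shape is Shape.round:
        return math.pi * (sodf.diameter_mm / 2.0) ** 2 * sodf.height_mm
    return math.pi / 4.0 * sodf.length_mm * sodf.width_mm * sodf.height_mm


def check_measurement_precision(card: BlisterCardRecord) -> list[str]:
    """Warnings for values finer than the measurement instruments resolve.

    Lengths are expected at 0.1 mm granularity, masses at 1 mg.  Returns a
    list of human-readable messages; an empty list means the record respects
    the recording convention.  This is advisory — derived full-precision
    values (e.g. round-tripped files) are deliberately not rejected.
    """
    issues: list[str] = []

    def _len(name: str, value: Optional[float]) -> None:
        if value is None:
            return
        if abs(value / LENGTH_PRECISION_MM - round(value / LENGTH_PRECISION_MM)) > 1e-6:
            issues.append(f"{name} = {value} mm finer than 0.1 mm granularity")

    def _mass(name: str, value: Optional[float]) -> None:
        if value is None:
            return
        if abs(value / MASS_PRECISION_G - round(value / MASS_PRECISION_G)) > 1e-6:
            issues.append(f"{name} = {value} g finer than 1 mg granularity")

    _len("card_length_i_mm", card.card_length_i_mm)
    _len("half_width_b_mm", card.half_width_b_mm)
    _len("gap_min_h_mm", card.gap_min_h_mm)
    _len("gap_max_g_mm", card.gap_max_g_mm)
    _len("alveolus.d_mm", card.alveolus.d_mm)
    _len("alveolus.e_mm", card.alveolus.e_mm)
    _len("alveolus.f_mm", card.alveolus.f_mm)
    _len("sodf.diameter_mm", card.sodf.diameter_mm)
    _len("sodf.length_mm", card.sodf.length_mm)
    _len("sodf.width_mm", card.sodf.width_mm)
    _len("sodf.height_mm", card.sodf.height_mm)
    _mass("gross_weight_g", card.gross_weight_g)
    _mass("sodf.mass_g", card.sodf.mass_g)
    return issues
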