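"""Annual national blister-packaging waste from dispensed-DDD ledgers.

The chain: dispensed DDD × (WHO DDD in mg) / (strength in mg) gives the
number of dosage forms consumed per year; dividing by the package size gives
fractional package equivalents, dividing by the per-card count gives blister
cards; cards × card weight gives waste mass.  Mass converts onward into
compacted volume (density 1.4 t/m³, polyvinyl chloride), freight-train
length (70 t, 15.4 m per wagon), card footprint area and per-capita area.

Two scalar multiplications extrapolate beyond the measured top-seller set: a
rule of three over DDD totals carries the measured products to the whole
statutory market, and the factor 1.105 adds the 10.5% privately insured
population.  Package and card counts stay fractional throughout
("equivalents"), and train lengths use fractional wagons — the published
figures reproduce only without intermediate rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .geometry import BlisterCardRecord

MM2_PER_KM2 = 1e12


class DddLedgerEntry(BaseModel):
    """Annual dispensed DDD count for one brand."""

    model_config = ConfigDict(frozen=True)

    brand_id: str
    ddd_dispensed: float = Field(gt=0)
    who_ddd_mg: float = Field(gt=0)
    include_in_market: bool = True


class MarketConstants(BaseModel):
    """Physical and market constants used in the extrapolation."""

    model_config = ConfigDict(frozen=True)

    blister_density_t_per_m3: float = Field(default=1.4, gt=0)
    wagon_capacity_t: float = Field(default=70.0, gt=0)
    wagon_length_m: float = Field(default=15.4, gt=0)
    private_uplift: float = Field(default=1.105, gt=0)
    population: float = Field(default=83.2e6, gt=0)


class WasteEstimate(BaseModel):
    """Annual totals for one product or a cohort."""

    model_config = ConfigDict(frozen=True)

    n_sodf: float = Field(ge=0)
    package_equivalents: float = Field(ge=0)
    n_cards: float = Field(ge=0)
    mass_t: float = Field(ge=0)
    area_km2: float = Field(ge=0)
    volume_m3: float = Field(ge=0)
    train_m: float = Field(ge=0)
    per_capita_m2: float = Field(ge=0)


# ---------------------------------------------------------------------------
# elementary conversions


def annual_sodf_count(entry: DddLedgerEntry, strength_mg: float) -> float:
    """Dosage forms consumed per year.

    DDD counts are converted to milligrams via the WHO reference daily dose
    and divided by the strength of the analysed presentation; when the WHO
    DDD equals the strength this reduces to the DDD count itself.
    """
    if strength_mg <= 0:
        raise ValueError("strength must be positive")
    return entry.ddd_dispensed * entry.who_ddd_mg / strength_mg


def package_equivalents(n_sodf: float, package_size: int) -> float:
    """Fractional package equivalents (never rounded up)."""
    if package_size < 1:
        raise ValueError("package size must be >= 1")
    return n_sodf / package_size


def annual_card_count(n_sodf: float, sodf_per_card: int) -> float:
    """Fractional blister-card count per year."""
    if sodf_per_card < 1:
        raise ValueError("per-card SODF count must be >= 1")
    return n_sodf / sodf_per_card


def annual_waste_mass_t(n_cards: float, card_weight_g: float) -> float:
    """Waste mass in tonnes from a card count and per-card weight in grams."""
    if n_cards < 0 or card_weight_g < 0:
        raise ValueError("inputs must be non-negative")
    return n_cards * card_weight_g * 1e-6


def annual_waste_area_km2(n_cards: float, card: BlisterCardRecord) -> float:
    """Footprint area of the discarded cards in km².

    The per-card footprint is card length i × (number of blister rows × b);
    for the usual two-row card this equals the face area 2b × i.
    """
    per_card_mm2 = card.card_length_i_mm * card.n_rows * card.half_width_b_mm
    return n_cards * per_card_mm2 / MM2_PER_KM2


def market_rule_of_three(
    top45_mass_t: float, top45_ddd: float, market_ddd: float
) -> float:
    """Linear extrapolation of waste mass from the measured products' DDD
    share to the whole market's DDD total."""
    if top45_ddd <= 0:
        raise ValueError("measured-cohort DDD total must be positive")
    return top45_mass_t * market_ddd / top45_ddd


def private_insurance_uplift(
    value: float, constants: Optional[MarketConstants] = None
) -> float:
    """Add the privately insured population (×1.105 by default)."""
    if value < 0:
        raise ValueError("value must be non-negative")
    return value * (constants or MarketConstants()).private_uplift


def waste_volume_m3(
    mass_t: float, constants: Optional[MarketConstants] = None
) -> float:
    """Maximally compacted waste volume at the blister laminate density."""
    if mass_t < 0:
        raise ValueError("mass must be non-negative")
    return mass_t / (constants or MarketConstants()).blister_density_t_per_m3


def cube_edge_m(volume_m3: float) -> float:
    """Edge length of a cube holding the given volume."""
    if volume_m3 < 0:
        raise ValueError("volume must be non-negative")
    return volume_m3 ** (1.0 / 3.0)


def train_length_m(mass_t: float, constants: Optional[MarketConstants] = None) -> float:
    """Goods-train length carrying the waste mass, fractional wagons."""
    if mass_t < 0:
        raise ValueError("mass must be non-negative")
    c = constants or MarketConstants()
    return mass_t / c.wagon_capacity_t * c.wagon_length_m


def per_capita_area_m2(
    area_km2: float, constants: Optional[MarketConstants] = None
) -> float:
    """Waste footprint per inhabitant in m²."""
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    return area_km2 * 1e6 / (constants or MarketConstants()).population


# ---------------------------------------------------------------------------
# product- and cohort-level chains


def estimate_product_waste(
    card: BlisterCardRecord,
    entry: DddLedgerEntry,
    constants: Optional[MarketConstants] = None,
) -> WasteEstimate:
    """Full per-product chain from a DDD ledger entry to annual totals."""
    constants = constants or MarketConstants()
    n_sodf = annual_sodf_count(entry, card.sodf.strength_mg)
    packages = package_equivalents(n_sodf, card.package_size)
    n_cards = annual_card_count(n_sodf, card.n_sodf)
    mass_t = annual_waste_mass_t(n_cards, card.gross_weight_g)
    area_km2 = annual_waste_area_km2(n_cards, card)
    return WasteEstimate(
        n_sodf=n_sodf,
        package_equivalents=packages,
        n_cards=n_cards,
        mass_t=mass_t,
        area_km2=area_km2,
        volume_m3=waste_volume_m3(mass_t, constants),
        train_m=train_length_m(mass_t, constants),
        per_capita_m2=per_capita_area_m2(area_km2, constants),
    )


@dataclass(frozen=True)
class WasteTotals:
    """Cohort-level annual totals, scalable by market and insurance factors."""

    n_sodf: float
    package_equivalents: float
    n_cards: float
    mass_t: float
    area_km2: float

    def scaled(self, factor: float) -> "WasteTotals":
        return WasteTotals(
            n_sodf=self.n_sodf * factor,
            package_equivalents=self.package_equivalents * factor,
            n_cards=self.n_cards * factor,
            mass_t=self.mass_t * factor,
            area_km2=self.area_km2 * factor,
        )

    def as_estimate(self, constants: Optional[MarketConstants] = None) -> WasteEstimate:
        constants = constants or MarketConstants()
        return WasteEstimate(
            n_sodf=self.n_sodf,
            package_equivalents=self.package_equivalents,
            n_cards=self.n_cards,
            mass_t=self.mass_t,
            area_km2=self.area_km2,
            volume_m3=waste_volume_m3(self.mass_t, constants),
            train_m=train_length_m(self.mass_t, constants),
            per_capita_m2=per_capita_area_m2(self.area_km2, constants),
        )


@dataclass(frozen=True)
class CohortWasteSummary:
    """Measured-cohort and whole-market totals, statutory and uplifted."""

    per_product: pd.DataFrame
    top_statutory: WasteEstimate
    top_entire: WasteEstimate
    market_statutory: Optional[WasteEstimate]
    market_entire: Optional[WasteEstimate]
    constants: MarketConstants


def estimate_cohort_waste(
    cards: Sequence[BlisterCardRecord],
    ledger: Sequence[DddLedgerEntry],
    constants: Optional[MarketConstants] = None,
    market_ddd: Optional[float] = None,
) -> CohortWasteSummary:
    """Chain every ledger entry through its card and aggregate.

    ``market_ddd`` is the whole-market DDD total; when given, the measured
    cohort's included entries (``include_in_market``) anchor a rule of three
    to whole-market totals.  The private-insurance uplift is applied to both
    the measured cohort and the market extrapolation.
    """
    constants = constants or MarketConstants()
    by_brand = {c.brand_id: c for c in cards}
    rows = []
    included_ddd = 0.0
    for entry in ledger:
        card = by_brand.get(entry.brand_id)
        if card is None:
            raise KeyError(f"ledger brand {entry.brand_id!r} not in measurement table")
        est = estimate_product_waste(card, entry, constants)
        rows.append(
            {
                "brand_id": entry.brand_id,
                "ddd_dispensed": entry.ddd_dispensed,
                "include_in_market": entry.include_in_market,
                "n_sodf": est.n_sodf,
                "package_equivalents": est.package_equivalents,
                "n_cards": est.n_cards,
                "mass_t": est.mass_t,
                "area_km2": est.area_km2,
            }
        )
        if entry.include_in_market:
            included_ddd += entry.ddd_dispensed
    per_product = pd.DataFrame(rows)
    top = WasteTotals(
        n_sodf=per_product["n_sodf"].sum(),
        package_equivalents=per_product["package_equivalents"].sum(),
        n_cards=per_product["n_cards"].sum(),
        mass_t=per_product["mass_t"].sum(),
        area_km2=per_product["area_km2"].sum(),
    )
    uplift = constants.private_uplift
    market_statutory = market_entire = None
    if market_ddd is not None:
        inc = per_product[per_product["include_in_market"]]
        included = WasteTotals(
            n_sodf=inc["n_sodf"].sum(),
            package_equivalents=inc["package_equivalents"].sum(),
            n_cards=inc["n_cards"].sum(),
            mass_t=inc["mass_t"].sum(),
            area_km2=inc["area_km2"].sum(),
        )
        factor = market_rule_of_three(1.0, included_ddd, market_ddd)
        market = included.scaled(factor)
        market_statutory = market.as_estimate(constants)
        market_entire = market.scaled(uplift).as_estimate(constants)
    return CohortWasteSummary(
        per_product=per_product,
        top_statutory=top.as_estimate(constants),
        top_entire=top.scaled(uplift).as_estimate(constants),
        market_statutory=market_statutory,
        market_entire=market_entire,
        constants=constants,
    )
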