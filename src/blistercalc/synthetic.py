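"""Synthetic measurement cohorts and DDD ledgers.

The generator emulates the published 45-product measurement cohort: 27
round tablets, 16 elongated tablets and 2 capsules; 13 aluminum-aluminum
cards, one pure-plastic card and the rest aluminum-plastic.  Each directly
sampled metric follows a truncated normal whose parameters default to the
published per-class mean ± SD and range; the truncnorm location is
calibrated so the *truncated* mean equals the configured mean, which makes
parameter-recovery checks exact despite asymmetric truncation.

Dependent quantities are derived, not sampled, so every record is
internally consistent by construction: the chamber base area comes from the
sampled card area and area fraction, the dosage-form footprint from the
chamber area divided by a material-specific chamber-to-form ratio, the card
side lengths from a feasible row layout with gaps inside the observed
ranges, and the gross weight from an areal laminate density plus the packed
forms.  The two capsules are emitted deterministically from their
individually published values.

A single integer seed governs everything; each metric draws from its own
named substream, so adding a metric leaves the others' draws unchanged.
"""

from __future__ import annotations

import math
import zlib
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

from .geometry import (
    AlveolusShape,
    AlveolusSpec,
    BlisterCardRecord,
    Material,
    Shape,
    SodfSpec,
)
from .waste import DddLedgerEntry


class MetricSpec(BaseModel):
    """Truncated-normal parameters (mean, sd, min, max) for one metric."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(ge=0)
    min: float
    max: float

    @model_validator(mode="after")
    def _feasible(self) -> "MetricSpec":
        if not self.min < self.max:
            raise ValueError(f"min ({self.min}) must be < max ({self.max})")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"mean ({self.mean}) outside range [{self.min}, {self.max}]"
            )
        return self


def _default_class_metrics() -> dict[str, dict[str, MetricSpec]]:
    ms = MetricSpec
    return {
        "round": {
            "strength_mg": ms(mean=50.0, sd=109.0, min=0.05, max=500.0),
            "package_size": ms(mean=97.9, sd=25.9, min=50, max=200),
            "sodf_per_card": ms(mean=17.4, sd=7.31, min=5, max=25),
            "package_blister_area_cm2": ms(mean=326.0, sd=120.0, min=191.0, max=563.0),
            "alveolus_fraction_pct": ms(mean=29.4, sd=7.65, min=15.1, max=41.5),
            "sodf_mass_g": ms(mean=0.18, sd=0.12, min=0.04, max=0.59),
            "sodf_height_mm": ms(mean=4.0, sd=1.0, min=2.0, max=7.0),
        },
        "elongated": {
            "strength_mg": ms(mean=203.0, sd=293.0, min=5.0, max=850.0),
            "package_size": ms(mean=96.9, sd=31.8, min=20, max=180),
            "sodf_per_card": ms(mean=14.4, sd=6.02, min=10, max=25),
            "package_blister_area_cm2": ms(mean=440.0, sd=228.0, min=95.4, max=811.0),
            "alveolus_fraction_pct": ms(mean=35.1, sd=6.99, min=18.6, max=49.1),
            "sodf_mass_g": ms(mean=0.36, sd=0.33, min=0.08, max=0.94),
            "sodf_height_mm": ms(mean=5.5, sd=1.0, min=3.0, max=8.0),
            "alveolus_aspect": ms(mean=2.0, sd=0.3, min=1.3, max=3.0),
        },
    }


def _default_shared_metrics() -> dict[str, MetricSpec]:
    ms = MetricSpec
    return {
        # smallest chamber-to-chamber distance h, observed 2–8 mm, mean 4.64
        "gap_h_mm": ms(mean=4.64, sd=1.5, min=2.0, max=8.0),
        # laminate areal density: anchors gross card weights near 13–16 g
        "areal_density_g_cm2": ms(mean=0.18, sd=0.05, min=0.06, max=0.35),
        # chamber base area / dosage-form footprint, by laminate class
        "ratio_al_al": ms(mean=4.3, sd=1.5, min=1.5, max=8.0),
        "ratio_mixed": ms(mean=1.7, sd=0.6, min=1.05, max=4.0),
    }


#: The two capsules, reported individually in the source cohort.
CAPSULE_PRODUCTS = (
    {
        "strength_mg": 0.4,
        "package_size": 100,
        "cards_per_pack": 10,
        "n_sodf": 10,
        "package_blister_area_cm2": 400.0,
        "alveolus_fraction_pct": 20.9,
        "sodf_mass_g": 0.14,
        "sodf_height_mm": 6.0,
        "alveolus_aspect": 2.4,
    },
    {
        "strength_mg": 50.0,
        "package_size": 100,
        "cards_per_pack": 10,
        "n_sodf": 10,
        "package_blister_area_cm2": 552.0,
        "alveolus_fraction_pct": 28.9,
        "sodf_mass_g": 0.23,
        "sodf_height_mm": 6.5,
        "alveolus_aspect": 2.4,
    },
)


class CohortConfig(BaseModel):
    """Cohort composition and per-metric distributions."""

    n_products: int = Field(default=45, ge=1)
    n_round: int = Field(default=27, ge=0)
    n_elongated: int = Field(default=16, ge=0)
    n_capsule: int = Field(default=2, ge=0)
    n_al_al: int = Field(default=13, ge=0)
    n_plastic: int = Field(default=1, ge=0)
    class_metrics: dict[str, dict[str, MetricSpec]] = Field(
        default_factory=_default_class_metrics
    )
    shared_metrics: dict[str, MetricSpec] = Field(
        default_factory=_default_shared_metrics
    )
    mean_ddd_per_product: float = Field(default=2e8, gt=0)
    ddd_sigma_log: float = Field(default=1.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _composition(self) -> "CohortConfig":
        if self.n_round + self.n_elongated + self.n_capsule != self.n_products:
            raise ValueError("shape mix must sum to n_products")
        non_capsule = self.n_round + self.n_elongated
        if self.n_al_al + self.n_plastic > non_capsule:
            raise ValueError(
                "material mix exceeds the number of non-capsule products"
            )
        return self

    @classmethod
    def with_size(cls, n_products: int, seed: int = 0, **overrides) -> "CohortConfig":
        """Scale the default 27/16/2 and 13/31/1 mixes to another size."""
        base = cls()
        n_round = round(n_products * base.n_round / base.n_products)
        n_capsule = round(n_products * base.n_capsule / base.n_products)
        n_elongated = n_products - n_round - n_capsule
        n_al_al = round(n_products * base.n_al_al / base.n_products)
        n_plastic = max(1, round(n_products * base.n_plastic / base.n_products))
        return cls(
            n_products=n_products,
            n_round=n_round,
            n_elongated=n_elongated,
            n_capsule=n_capsule,
            n_al_al=min(n_al_al, n_round + n_elongated - n_plastic),
            n_plastic=n_plastic,
            seed=seed,
            **overrides,
        )


# ---------------------------------------------------------------------------
# calibrated truncated-normal sampling


@lru_cache(maxsize=512)
def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Parent location mu such that the [lo, hi]-truncated normal with scale
    sd has mean exactly ``mean``.  Monotone in mu, solved by brentq."""

    def truncated_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    span = hi - lo + 6.0 * sd
    lo_mu, hi_mu = lo - span, hi + span
    # truncated mean -> lo as mu -> -inf, -> hi as mu -> +inf
    return float(optimize.brentq(lambda m: truncated_mean(m) - mean, lo_mu, hi_mu))


class _PointMass:
    """Degenerate distribution: every draw equals the configured mean."""

    def __init__(self, value: float):
        self.value = value

    def mean(self) -> float:
        return self.value

    def std(self) -> float:
        return 0.0

    def rvs(self, size: int = 1, random_state=None) -> np.ndarray:
        return np.full(size, self.value)


def metric_distribution(spec: MetricSpec):
    """Frozen distribution implementing a metric's sampling law.

    Degenerate (sd = 0) metrics are a point mass at the configured mean;
    otherwise a scipy truncated normal with calibrated location.
    """
    if spec.sd == 0:
        return _PointMass(spec.mean)
    mu = _calibrated_loc(spec.mean, spec.sd, spec.min, spec.max)
    a, b = (spec.min - mu) / spec.sd, (spec.max - mu) / spec.sd
    return stats.truncnorm(a, b, loc=mu, scale=spec.sd)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent random substream derived from one seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _sample(spec: MetricSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    if spec.sd == 0:
        return np.full(size, spec.mean)
    dist = metric_distribution(spec)
    return np.asarray(dist.rvs(size=size, random_state=rng), dtype=float)


# ---------------------------------------------------------------------------
# record assembly


def _round_len(x: float) -> float:
    return round(float(x), 1)


def _alveolus_dims(shape: Shape, area_mm2: float, aspect: float) -> AlveolusSpec:
    if shape is Shape.round:
        return AlveolusSpec(
            shape=AlveolusShape.round,
            d_mm=_round_len(2.0 * math.sqrt(area_mm2 / math.pi)),
        )
    f = math.sqrt(aspect * area_mm2)
    return AlveolusSpec(
        shape=AlveolusShape.elongated,
        e_mm=_round_len(area_mm2 / f),
        f_mm=_round_len(f),
    )


def _row_count(n: int) -> int:
    """Row count of the marketed layout: prefer 2 rows, then 3, else 1."""
    if n % 2 == 0:
        return 2
    if n % 3 == 0:
        return 3
    return 1


def _layout_card(
    card_mm2: float,
    alv: AlveolusSpec,
    n: int,
    h_gap: float,
) -> tuple[float, float, float, float]:
    """Card sides (i, 2b) and gaps (h, g) realizing ``card_mm2``.

    The card length i packs the columns with the within-row gap h; the width
    follows from the target area, and the implied row gap g must be at least
    h.  Infeasibly tight targets first shrink h towards its 2 mm floor and,
    as a last resort, inflate the card area by 5% over the minimal layout.
    """
    if alv.shape is AlveolusShape.round:
        a_len = a_wid = alv.d_mm
    else:
        a_len, a_wid = alv.e_mm, alv.f_mm
    r = _row_count(n)
    cols = n // r

    def length(h: float) -> float:
        return cols * a_len + (cols + 1) * h

    def needed_width(h: float) -> float:
        return r * a_wid + (r + 1) * h

    h = h_gap
    if card_mm2 / length(h) < needed_width(h):
        # shrink the within-row gap towards its observed floor
        h = 2.0
        if card_mm2 / length(h) < needed_width(h):
            card_mm2 = length(h) * needed_width(h) * 1.05
    i = length(h)
    width = card_mm2 / i
    g = (width - r * a_wid) / (r + 1)
    if g < h:
        g = h
        width = needed_width(g)
    return i, width, h, g


def _assemble_record(
    brand_id: str,
    shape: Shape,
    material: Material,
    strength_mg: float,
    package_size: int,
    n_sodf: int,
    package_area_cm2: float,
    fraction_pct: float,
    sodf_mass_g: float,
    sodf_height_mm: float,
    aspect: float,
    ratio: float,
    h_gap: float,
    density_g_cm2: float,
) -> BlisterCardRecord:
    cards_per_pack = max(1, math.ceil(package_size / n_sodf))
    card_mm2 = package_area_cm2 * 100.0 / cards_per_pack
    alv_area = fraction_pct / 100.0 * card_mm2 / n_sodf
    alv = _alveolus_dims(
        Shape.round if shape is Shape.round else Shape.elongated, alv_area, aspect
    )
    # dosage form sits inside the chamber: footprint = chamber area / ratio
    scale = 1.0 / math.sqrt(ratio)
    if shape is Shape.round:
        sodf = SodfSpec(
            shape=shape,
            strength_mg=strength_mg,
            diameter_mm=max(0.5, _round_len(alv.d_mm * scale)),
            height_mm=_round_len(sodf_height_mm),
            mass_g=round(sodf_mass_g, 3),
        )
    else:
        sodf = SodfSpec(
            shape=shape,
            strength_mg=strength_mg,
            length_mm=max(0.5, _round_len(alv.f_mm * scale)),
            width_mm=max(0.5, _round_len(alv.e_mm * scale)),
            height_mm=_round_len(sodf_height_mm),
            mass_g=round(sodf_mass_g, 3),
        )
    i, width, h, g = _layout_card(card_mm2, alv, n_sodf, h_gap)
    i = _round_len(i)
    b = _round_len(width / 2.0)
    h = _round_len(h)
    g = max(_round_len(g), h)
    face_cm2 = 2.0 * b * i / 100.0
    gross = round(density_g_cm2 * face_cm2 + n_sodf * sodf.mass_g, 3)
    return BlisterCardRecord(
        brand_id=brand_id,
        material=material,
        n_sodf=n_sodf,
        n_rows=_row_count(n_sodf),
        card_length_i_mm=i,
        half_width_b_mm=b,
        gross_weight_g=gross,
        gap_min_h_mm=h,
        gap_max_g_mm=g,
        alveolus=alv,
        sodf=sodf,
        package_size=package_size,
        cards_per_pack=math.ceil(package_size / n_sodf),
    )


def _integerize(values: np.ndarray, spec: MetricSpec) -> np.ndarray:
    return np.clip(np.rint(values), math.ceil(spec.min), math.floor(spec.max)).astype(
        int
    )


def generate_cohort(config: Optional[CohortConfig] = None) -> list[BlisterCardRecord]:
    """Generate a deterministic measurement cohort from a config and seed."""
    config = config or CohortConfig()
    seed = config.seed

    # material assignment over non-capsule products (capsules: al_plastic)
    non_capsule = config.n_round + config.n_elongated
    materials = (
        [Material.al_al] * config.n_al_al
        + [Material.plastic] * config.n_plastic
        + [Material.al_plastic] * (non_capsule - config.n_al_al - config.n_plastic)
    )
    _substream(seed, "material").shuffle(materials)  # type: ignore[arg-type]

    class_values: dict[str, dict[str, np.ndarray]] = {}
    for cls, count in (("round", config.n_round), ("elongated", config.n_elongated)):
        metrics = config.class_metrics[cls]
        class_values[cls] = {
            name: _sample(spec, _substream(seed, f"{cls}/{name}"), count)
            for name, spec in metrics.items()
        }

    shared = config.shared_metrics
    h_gaps = _sample(shared["gap_h_mm"], _substream(seed, "gap_h_mm"), non_capsule)
    densities = _sample(
        shared["areal_density_g_cm2"],
        _substream(seed, "areal_density_g_cm2"),
        non_capsule,
    )
    ratio_streams = {
        Material.al_al: iter(
            _sample(
                shared["ratio_al_al"], _substream(seed, "ratio_al_al"), non_capsule
            )
        ),
        "mixed": iter(
            _sample(shared["ratio_mixed"], _substream(seed, "ratio_mixed"), non_capsule)
        ),
    }

    records: list[BlisterCardRecord] = []
    idx = 0
    for cls, shape, count in (
        ("round", Shape.round, config.n_round),
        ("elongated", Shape.elongated, config.n_elongated),
    ):
        vals = class_values[cls]
        metrics = config.class_metrics[cls]
        n_sodf_v = _integerize(vals["sodf_per_card"], metrics["sodf_per_card"])
        package_v = _integerize(vals["package_size"], metrics["package_size"])
        for j in range(count):
            material = materials[idx]
            ratio_key = Material.al_al if material is Material.al_al else "mixed"
            aspect = (
                float(vals["alveolus_aspect"][j]) if "alveolus_aspect" in vals else 1.0
            )
            records.append(
                _assemble_record(
                    brand_id=f"SYN-{idx:04d}-{cls}",
                    shape=shape,
                    material=material,
                    strength_mg=float(vals["strength_mg"][j]),
                    package_size=int(package_v[j]),
                    n_sodf=int(n_sodf_v[j]),
                    package_area_cm2=float(vals["package_blister_area_cm2"][j]),
                    fraction_pct=float(vals["alveolus_fraction_pct"][j]),
                    sodf_mass_g=float(vals["sodf_mass_g"][j]),
                    sodf_height_mm=float(vals["sodf_height_mm"][j]),
                    aspect=aspect,
                    ratio=float(next(ratio_streams[ratio_key])),
                    h_gap=float(h_gaps[idx]),
                    density_g_cm2=float(densities[idx]),
                )
            )
            idx += 1

    for j in range(config.n_capsule):
        spec = CAPSULE_PRODUCTS[j % len(CAPSULE_PRODUCTS)]
        records.append(
            _assemble_record(
                brand_id=f"SYN-{idx + j:04d}-capsule",
                shape=Shape.capsule,
                material=Material.al_plastic,
                strength_mg=spec["strength_mg"],
                package_size=spec["package_size"],
                n_sodf=spec["n_sodf"],
                package_area_cm2=spec["package_blister_area_cm2"],
                fraction_pct=spec["alveolus_fraction_pct"],
                sodf_mass_g=spec["sodf_mass_g"],
                sodf_height_mm=spec["sodf_height_mm"],
                aspect=spec["alveolus_aspect"],
                ratio=1.7,
                h_gap=4.0,
                density_g_cm2=0.18,
            )
        )
    return records


def generate_ddd_ledger(
    cohort: Sequence[BlisterCardRecord],
    mean_ddd_per_product: float = 2e8,
    seed: int = 0,
    sigma_log: float = 1.0,
    equal: bool = False,
) -> list[DddLedgerEntry]:
    """Log-normal dispensed-DDD counts for a cohort, WHO DDD = strength.

    ``equal=True`` gives every product exactly the mean (the ledger total is
    then n × mean, convenient for linearity checks).
    """
    if mean_ddd_per_product <= 0:
        raise ValueError("mean DDD per product must be positive")
    n = len(cohort)
    if equal or sigma_log == 0:
        ddd = np.full(n, mean_ddd_per_product)
    else:
        rng = _substream(seed, "ddd")
        mu = math.log(mean_ddd_per_product) - sigma_log**2 / 2.0
        ddd = rng.lognormal(mean=mu, sigma=sigma_log, size=n)
    return [
        DddLedgerEntry(
            brand_id=card.brand_id,
            ddd_dispensed=float(d),
            who_ddd_mg=card.sodf.strength_mg,
            include_in_market=True,
        )
        for card, d in zip(cohort, ddd)
    ]


def worked_example_fixture() -> tuple[list[BlisterCardRecord], list[DddLedgerEntry]]:
    """Three hand-built products with hand-checkable totals.

    The round product carries 24 chambers of 11 mm diameter on a 60 cm²
    card; a two-row re-arrangement at the 2 mm aluminum-plastic margin gives
    44.24 cm², a 26.3% saving.
    """
    cards = [
        BlisterCardRecord(
            brand_id="WX-ROUND-24",
            material=Material.al_plastic,
            n_sodf=24,
            n_rows=2,
            card_length_i_mm=150.0,
            half_width_b_mm=20.0,
            gross_weight_g=12.0,
            gap_min_h_mm=2.0,
            gap_max_g_mm=6.0,
            alveolus=AlveolusSpec(shape=AlveolusShape.round, d_mm=11.0),
            sodf=SodfSpec(
                shape=Shape.round,
                strength_mg=100.0,
                diameter_mm=8.0,
                height_mm=4.0,
                mass_g=0.25,
            ),
            package_size=96,
            cards_per_pack=4,
        ),
        BlisterCardRecord(
            brand_id="WX-ELONG-10",
            material=Material.al_al,
            n_sodf=10,
            n_rows=2,
            card_length_i_mm=80.0,
            half_width_b_mm=15.0,
            gross_weight_g=10.0,
            gap_min_h_mm=2.0,
            gap_max_g_mm=4.0,
            alveolus=AlveolusSpec(shape=AlveolusShape.elongated, e_mm=5.0, f_mm=20.0),
            sodf=SodfSpec(
                shape=Shape.elongated,
                strength_mg=200.0,
                length_mm=18.0,
                width_mm=4.0,
                height_mm=3.5,
                mass_g=0.4,
            ),
            package_size=100,
            cards_per_pack=10,
        ),
        BlisterCardRecord(
            brand_id="WX-CAPSULE-10",
            material=Material.al_plastic,
            n_sodf=10,
            n_rows=2,
            card_length_i_mm=100.0,
            half_width_b_mm=20.0,
            gross_weight_g=8.0,
            gap_min_h_mm=4.0,
            gap_max_g_mm=10.0,
            alveolus=AlveolusSpec(shape=AlveolusShape.elongated, e_mm=8.0, f_mm=18.0),
            sodf=SodfSpec(
                shape=Shape.capsule,
                strength_mg=50.0,
                length_mm=16.0,
                width_mm=6.0,
                height_mm=6.0,
                mass_g=0.15,
            ),
            package_size=100,
            cards_per_pack=10,
        ),
    ]
    ledger = [
        DddLedgerEntry(
            brand_id="WX-ROUND-24", ddd_dispensed=1e6, who_ddd_mg=100.0
        ),
        DddLedgerEntry(
            brand_id="WX-ELONG-10", ddd_dispensed=2e6, who_ddd_mg=200.0
        ),
        DddLedgerEntry(
            brand_id="WX-CAPSULE-10", ddd_dispensed=5e5, who_ddd_mg=50.0
        ),
    ]
    return cards, ledger
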