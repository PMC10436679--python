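"""Medicine and consumable costing per course, and ASHA incentive rules.

Oral amoxicillin is dispensed in 60 ml bottles lasting six days at
twice-daily dosing, so a 7-day course needs two bottles and any 1-6 day
course one — generalised as ceiling(days / 6). Injectable gentamicin is
priced per administration, and each injection consumes a linked set of
syringe, needle, methylated spirit and cotton swab; pneumonia courses
(oral only) therefore carry no consumable cost.

ASHAs earn ₹250 for completing six or seven postnatal home visits, ₹125
for two to five, and a ₹100 transport incentive per infant they mobilise
to a facility. Shared program costs are assigned to PSBI management via
item-keyed attribution fractions (e.g. 20% of postnatal incentives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .classification import classify_treatment, is_treated
from .errors import CostkitError
from .model import (
    AttributionFractions,
    IMNCIClass,
    IncentiveSchedule,
    PriceList,
    TreatmentCourse,
)
from .money import Money, inr

BOTTLE_DAYS = 6  # days of twice-daily dosing one 60 ml bottle covers


@dataclass(frozen=True)
class CommodityCost:
    """Medicines and consumables for one treatment course, in INR."""

    medicines: Money
    consumables: Money

    @property
    def total(self) -> Money:
        return self.medicines + self.consumables


def amoxicillin_bottles(days_of_treatment: int) -> int:
    """Bottles of amoxicillin needed for ``days_of_treatment`` days."""
    if days_of_treatment < 0:
        raise ValueError(f"days_of_treatment must be >= 0, got {days_of_treatment}")
    return math.ceil(days_of_treatment / BOTTLE_DAYS)


def injection_consumable_set(prices: PriceList) -> float:
    """INR cost of the per-injection consumable set (syringe, needle, spirit, swab)."""
    return sum(prices.require(i) for i in ("syringe", "needle", "spirit", "cotton_swab"))


def _amox_days(course: TreatmentCourse) -> int:
    # Pneumonia courses are recorded in doses; convert at two doses per day
    # for bottle counting when days were not recorded directly.
    if course.amoxicillin_days:
        return course.amoxicillin_days
    return math.ceil(course.amoxicillin_doses / 2)


def course_commodity_cost(
    course: TreatmentCourse,
    prices: PriceList,
    *,
    allow_uncategorised: bool = False,
) -> CommodityCost:
    """Medicines + consumables for one course.

    By default only recommended/acceptable courses are costed, matching the
    headline analysis; pass ``allow_uncategorised=True`` to price partial or
    non-compliant courses for sensitivity analyses.
    """
    if not allow_uncategorised and not is_treated(classify_treatment(course)):
        raise CostkitError(
            "course is not recommended/acceptable; pass allow_uncategorised=True "
            "to cost it anyway"
        )
    bottles = amoxicillin_bottles(_amox_days(course))
    medicines = bottles * prices.require("amoxicillin_bottle_60ml")
    medicines += course.gentamicin_days * prices.require("gentamicin_per_administration")
    consumables = 0.0
    if course.gentamicin_days:
        consumables = course.gentamicin_days * injection_consumable_set(prices)
    return CommodityCost(medicines=inr(medicines), consumables=inr(consumables))


def pre_referral_dose_cost(prices: PriceList) -> Money:
    """Referral slip plus one pre-referral dose of gentamicin and amoxicillin.

    The gentamicin dose consumes one administration plus its consumable
    set; the amoxicillin dose is priced as one bottle (the 1-6 day rule —
    whether a part bottle could be shared is not recorded, so a full
    bottle is assumed).
    """
    return inr(
        prices.require("referral_slip")
        + prices.require("gentamicin_per_administration")
        + injection_consumable_set(prices)
        + prices.require("amoxicillin_bottle_60ml")
    )


def postnatal_incentive(visit_count: int, schedule: IncentiveSchedule) -> Money:
    """ASHA incentive earned for a given completed postnatal visit count."""
    if not 0 <= visit_count <= 7:
        raise ValueError(f"visit_count must be in [0, 7], got {visit_count}")
    if visit_count >= schedule.full_threshold_visits:
        return inr(schedule.postnatal_full_inr)
    lo, hi = schedule.half_range
    if lo <= visit_count <= hi:
        return inr(schedule.postnatal_half_inr)
    return inr(0.0)


def referral_incentive(mobilised_by_asha: bool, schedule: IncentiveSchedule) -> Money:
    """Transport incentive paid to the ASHA when she mobilised the infant.

    Families presenting the infant themselves earn the ASHA nothing.
    """
    return inr(schedule.referral_transport_inr if mobilised_by_asha else 0.0)


def attribute_to_psbi(
    cost: Money, item_key: str, fractions: AttributionFractions
) -> Money:
    """Share of a pooled cost attributed to PSBI management.

    Unknown item keys are an error — a missing fraction must never default
    silently to 100%.
    """
    return cost * fractions.get(item_key)


def straight_line_annualised(purchase_price: float, useful_life_years: float) -> float:
    """Annualised cost of an equipment item (straight line, no discounting)."""
    if useful_life_years <= 0:
        raise ValueError("useful_life_years must be positive")
    return purchase_price / useful_life_years


def expected_commodity_cost(
    target_class: IMNCIClass, category_mix: dict, prices: PriceList
) -> CommodityCost:
    """Expected per-course commodity cost under an adherence-category mix.

    ``category_mix`` maps TreatmentCategory -> probability over the
    recommended/acceptable categories only (the costed ones); acceptable
    PSBI courses draw gentamicin days uniformly on 2-6, acceptable
    pneumonia courses doses uniformly on 10-13. Used by the closed-form
    expectation oracle for the synthetic generator.
    """
    from .model import TreatmentCategory

    rec = category_mix.get(TreatmentCategory.RECOMMENDED, 0.0)
    acc = category_mix.get(TreatmentCategory.ACCEPTABLE, 0.0)
    mass = rec + acc
    if mass <= 0:
        return CommodityCost(inr(0.0), inr(0.0))
    rec, acc = rec / mass, acc / mass
    bottle = prices.require("amoxicillin_bottle_60ml")
    if target_class is IMNCIClass.PNEUMONIA:
        # 14 doses -> 7 d -> 2 bottles; 10-13 doses -> 5-7 d -> always 1-2
        # bottles: ceil(ceil(d/2)/6) = 1 for 10-11 doses (5-6 d), 2 for 12-13.
        e_bottles = rec * 2 + acc * (0.5 * 1 + 0.5 * 2)
        return CommodityCost(inr(e_bottles * bottle), inr(0.0))
    genta = prices.require("gentamicin_per_administration")
    conset = injection_consumable_set(prices)
    e_genta_days = rec * 7 + acc * 4.0  # uniform 2-6 -> mean 4
    medicines = 2 * bottle + e_genta_days * genta  # 7 d amoxicillin -> 2 bottles
    return CommodityCost(inr(medicines), inr(e_genta_days * conset))
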