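"""Medicine/consumable costing, the amoxicillin bottle rule, and incentives."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costkit.commodities import (
    amoxicillin_bottles,
    attribute_to_psbi,
    course_commodity_cost,
    postnatal_incentive,
    pre_referral_dose_cost,
    referral_incentive,
    straight_line_annualised,
)
from costkit.errors import CostkitError, MissingPriceError, UnknownAttributionKeyError
from costkit.model import (
    AttributionFractions,
    IMNCIClass,
    IncentiveSchedule,
    PriceList,
    TreatmentCourse,
)
from costkit.money import inr

CSI = IMNCIClass.CLINICAL_SEVERE_INFECTION

PRICES = PriceList(
    amoxicillin_bottle_60ml=30.0,
    gentamicin_per_administration=10.0,
    syringe=3.0,
    needle=2.0,
    spirit=1.5,
    cotton_swab=1.5,
    mother_card=3.0,
    referral_slip=2.0,
)


def _bottles_by_consumption(days: int) -> int:
    """Day-by-day oracle: 10 ml twice daily from 60 ml bottles."""
    bottles, remaining = 0, 0.0
    for _ in range(days):
        if remaining < 10.0:
            bottles += 1
            remaining = 60.0
        remaining -= 10.0
    return bottles


@pytest.mark.parametrize("days, expected", [(7, 2), (4, 1), (0, 0), (6, 1), (13, 3)])
def test_bottle_rule_examples(days, expected):
    assert amoxicillin_bottles(days) == expected


def test_bottle_rule_matches_consumption_oracle():
    for days in range(0, 31):
        assert amoxicillin_bottles(days) == _bottles_by_consumption(days), days


def test_pneumonia_course_has_no_consumables():
    course = TreatmentCourse(target_class=IMNCIClass.PNEUMONIA,
                             amoxicillin_doses=14, amoxicillin_days=7)
    cc = course_commodity_cost(course, PRICES)
    assert cc.medicines.amount == pytest.approx(60.0)  # 2 bottles x ₹30
    assert cc.consumables.amount == 0.0


def test_csi_recommended_course_cost():
    """7 gentamicin administrations at ₹10 + 2 bottles at ₹30 = ₹130
    medicines; 7 injections x ₹8 consumable set = ₹56."""
    course = TreatmentCourse(target_class=CSI, gentamicin_days=7, amoxicillin_days=7)
    cc = course_commodity_cost(course, PRICES)
    assert cc.medicines.amount == pytest.approx(130.0)
    assert cc.consumables.amount == pytest.approx(56.0)


def test_partial_course_requires_opt_in():
    course = TreatmentCourse(target_class=CSI, gentamicin_days=1, amoxicillin_days=7)
    with pytest.raises(CostkitError):
        course_commodity_cost(course, PRICES)
    cc = course_commodity_cost(course, PRICES, allow_uncategorised=True)
    assert cc.medicines.amount == pytest.approx(2 * 30.0 + 10.0)


def test_missing_price_names_item():
    course = TreatmentCourse(target_class=CSI, gentamicin_days=7, amoxicillin_days=7)
    with pytest.raises(MissingPriceError, match="gentamicin_per_administration"):
        course_commodity_cost(course, PriceList(amoxicillin_bottle_60ml=30.0))


def test_commodity_cost_monotone_in_gentamicin_days():
    last = 0.0
    for g in range(2, 8):
        course = TreatmentCourse(target_class=CSI, gentamicin_days=g, amoxicillin_days=7)
        total = course_commodity_cost(course, PRICES).total.amount
        assert total >= last
        last = total


def test_pre_referral_dose_cost_components():
    """slip ₹2 + gentamicin ₹10 + consumable set ₹8 + bottle ₹30 = ₹50."""
    assert pre_referral_dose_cost(PRICES).amount == pytest.approx(50.0)
    zero = PriceList(**{f: 0.0 for f in (
        "amoxicillin_bottle_60ml", "gentamicin_per_administration",
        "syringe", "needle", "spirit", "cotton_swab", "referral_slip")})
    assert pre_referral_dose_cost(zero).amount == 0.0


@pytest.mark.parametrize(
    "visits, expected",
    [(7, 250.0), (6, 250.0), (5, 125.0), (3, 125.0), (2, 125.0), (1, 0.0), (0, 0.0)],
)
def test_postnatal_incentive_schedule(visits, expected):
    assert postnatal_incentive(visits, IncentiveSchedule()).amount == expected


def test_postnatal_incentive_half_range_configurable():
    """The one-to-five reading of the half incentive is reproducible."""
    wide = IncentiveSchedule(half_range=(1, 5))
    assert postnatal_incentive(1, wide).amount == 125.0


def test_referral_incentive():
    s = IncentiveSchedule()
    assert referral_incentive(True, s).amount == 100.0
    assert referral_incentive(False, s).amount == 0.0
    assert sum(referral_incentive(True, s).amount for _ in range(685)) == 68_500.0


def test_attribution_examples():
    fr = AttributionFractions()
    assert attribute_to_psbi(inr(1000), "postnatal_incentive", fr).amount == 200.0
    assert attribute_to_psbi(inr(500), "mother_card", fr).amount == 500.0
    zero = AttributionFractions(fractions={"x": 0.0})
    assert attribute_to_psbi(inr(900), "x", zero).amount == 0.0


def test_unknown_attribution_key_rejected():
    with pytest.raises(UnknownAttributionKeyError):
        attribute_to_psbi(inr(100), "mystery_item", AttributionFractions())


@settings(derandomize=True, max_examples=100)
@given(
    cost=st.floats(min_value=0, max_value=1e6),
    frac=st.floats(min_value=0, max_value=1),
    k=st.floats(min_value=0, max_value=10),
)
def test_attribution_never_increases_and_is_linear(cost, frac, k):
    fr = AttributionFractions(fractions={"item": frac})
    out = attribute_to_psbi(inr(cost), "item", fr)
    assert out.amount <= cost + 1e-9
    scaled = attribute_to_psbi(inr(cost) * k, "item", fr)
    assert scaled.amount == pytest.approx(out.amount * k, rel=1e-9, abs=1e-9)


def test_straight_line_annualisation():
    assert straight_line_annualised(2000.0, 4) == 500.0
    with pytest.raises(ValueError):
        straight_line_annualised(2000.0, 0)
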