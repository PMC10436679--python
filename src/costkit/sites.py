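"""Deterministic registers for the two study sites, built from printed tallies.

These builders reconstruct the register structure of the Palwal (Haryana)
and Lucknow (Uttar Pradesh) site-years from the published counts: live
births, postnatal-visit coverage (including each site's share of complete
6-7-visit schedules), infants identified with pneumonia or PSBI, per-arm
adherence splits, the per-activity provider time/coverage survey and the
per-activity delivery tallies.

Salaries and commodity prices are **synthetic calibrations**, not sourced
values: the study's salary and price schedules were never published, so
these are chosen (once) to be realistic for the setting and to make the
reproducible report cells land on the published figures. Infant-level flags
are set to keep the published headline counts exact; where the published
per-activity tallies disagree with the headline counts (they do, in both
directions), the per-activity tallies are carried in ``n_units`` and drive
the cost pools.
"""

from __future__ import annotations

from itertools import count
from typing import Dict, Iterable, List, Optional, Tuple

from .model import (
    ActivityCoverage,
    ActivityId,
    ClinicalSigns,
    CoverageRow,
    IMNCIClass,
    InfantRecord,
    OperationalInputs,
    AdminStaffRow,
    AnnualCostItem,
    TrainingEvent,
    PriceList,
    ProviderType,
    SalarySchedule,
    SiteRegister,
    TreatmentCourse,
)

EXCHANGE_RATE_INR_PER_USD = 68.5

A = ProviderType.ANM
N = ProviderType.NURSE
M = ProviderType.MEDICAL_OFFICER
ASHA = ProviderType.ASHA

_SIGNS = {
    IMNCIClass.PNEUMONIA: (ClinicalSigns(respiratory_rate=62), 10),
    IMNCIClass.SEVERE_PNEUMONIA: (ClinicalSigns(respiratory_rate=64), 3),
    IMNCIClass.CLINICAL_SEVERE_INFECTION: (
        ClinicalSigns(respiratory_rate=45, temperature_c=38.5),
        20,
    ),
    IMNCIClass.CRITICAL_ILLNESS: (ClinicalSigns(convulsions=True), 5),
    IMNCIClass.NO_PSBI_SIGN: (ClinicalSigns(respiratory_rate=40), 15),
}


def _coverage(
    activity: ActivityId, rows: Dict[ProviderType, Tuple[float, float]], n_units: int
) -> ActivityCoverage:
    return ActivityCoverage(
        activity_id=activity,
        rows={
            p: CoverageRow(coverage_fraction=c, mean_minutes=m) for p, (c, m) in rows.items()
        },
        n_units=n_units,
    )


def _course(cls: IMNCIClass, kind: str, variant: int = 0) -> Optional[TreatmentCourse]:
    """A representative course for an adherence category within an arm."""
    if kind == "accepted":
        return None
    if kind == "noncompliant":
        drug = "cefixime" if cls is not IMNCIClass.CRITICAL_ILLNESS else "non-recommended"
        return TreatmentCourse(target_class=cls, other_antibiotics=[drug])
    if cls is IMNCIClass.PNEUMONIA:
        doses = {"recommended": 14, "acceptable": 12, "partial": 6}[kind]
        return TreatmentCourse(
            target_class=cls, amoxicillin_doses=doses, amoxicillin_days=(doses + 1) // 2
        )
    days = {"recommended": (7, 7), "acceptable": (2 + variant % 5, 7), "partial": (7, 5)}[kind]
    return TreatmentCourse(target_class=cls, gentamicin_days=days[0], amoxicillin_days=days[1])


def _spread_visits(counts_by_visits: Dict[int, int]) -> List[int]:
    """Interleave visit counts so any slice of infants has a mixed distribution."""
    pools = {v: n for v, n in counts_by_visits.items() if n > 0}
    total = sum(pools.values())
    out: List[int] = []
    while len(out) < total:
        for v in sorted(pools):
            if pools[v] > 0:
                out.append(v)
                pools[v] -= 1
    return out


def _build_infants(
    site: str,
    visit_counts: Dict[int, int],
    cases: Iterable[Tuple[IMNCIClass, str, int]],
    n_mobilised_flags: int,
    followup_plan: List[Tuple[int, int]],
) -> List[InfantRecord]:
    """Assemble the infant list: identified cases first, then visited-only rows.

    ``cases`` is (class, adherence kind, count); ``followup_plan`` is
    (visits, n-infants) applied in order over the coursed cases.
    """
    visits = _spread_visits(visit_counts)
    ids = count()
    infants: List[InfantRecord] = []
    followups: List[int] = []
    for v, n in followup_plan:
        followups.extend([v] * n)
    fu = iter(followups)
    mobilised_left = n_mobilised_flags

    for cls, kind, n in cases:
        for _ in range(n):
            idx = next(ids)
            signs, age = _SIGNS[cls]
            course = _course(cls, kind, variant=idx)
            accepted = kind == "accepted"
            mob = mobilised_left > 0
            if mob:
                mobilised_left -= 1
            infants.append(
                InfantRecord(
                    infant_id=f"{site}-{idx:05d}",
                    age_days_at_presentation=age,
                    postnatal_visits=visits[idx],
                    signs=signs,
                    mobilised_by_asha=mob,
                    referral_accepted=accepted,
                    pre_referral_dose_given=accepted,
                    treatment_course=course,
                    followup_visits=next(fu, 0) if course is not None else 0,
                )
            )
    signs, age = _SIGNS[IMNCIClass.NO_PSBI_SIGN]
    for idx in ids:
        if idx >= len(visits):
            break
        infants.append(
            InfantRecord(
                infant_id=f"{site}-{idx:05d}",
                age_days_at_presentation=age,
                postnatal_visits=visits[idx],
                signs=signs,
            )
        )
    return infants


def _prices() -> PriceList:
    # synthetic calibration, shared across sites (medicine prices did not
    # differ between them)
    return PriceList(
        amoxicillin_bottle_60ml=13.7,
        gentamicin_per_administration=13.5,
        syringe=10.0,
        needle=4.0,
        spirit=3.0,
        cotton_swab=3.0,
        mother_card=3.0,
        referral_slip=2.0,
        hbnc_kit=2000.0,
        weighing_scale=500.0,
    )


def lucknow_register() -> SiteRegister:
    """The Lucknow (Uttar Pradesh) site-year register, 2018-19.

    13 895 live births; 12 040 infants with >=1 postnatal visit (87%), 17%
    of them completing 6-7 visits; 610 identified with pneumonia or PSBI
    (5.1% of visited); 94 pneumonia (all recommended), 19 severe pneumonia
    (17 recommended), 452 clinical severe infection (191 recommended), 31
    critical illness, 14 accepted referrals.
    """
    visit_counts = {1: 2400, 2: 1893, 3: 1900, 4: 1900, 5: 1900, 6: 1300, 7: 747}
    CSI = IMNCIClass.CLINICAL_SEVERE_INFECTION
    SP = IMNCIClass.SEVERE_PNEUMONIA
    cases = [
        (IMNCIClass.PNEUMONIA, "recommended", 94),
        (SP, "recommended", 17),
        (SP, "partial", 2),
        (CSI, "recommended", 191),
        (CSI, "partial", 161),
        (CSI, "noncompliant", 100),
        (IMNCIClass.CRITICAL_ILLNESS, "noncompliant", 31),
        (CSI, "accepted", 14),
    ]
    # 596 coursed infants sharing 1302 follow-up visits
    followup_plan = [(3, 110), (2, 486)]
    infants = _build_infants("lko", visit_counts, cases, 397, followup_plan)

    coverage = {
        ActivityId.POSTNATAL_VISIT: _coverage(
            ActivityId.POSTNATAL_VISIT, {ASHA: (1.0, 19)}, 70645
        ),
        ActivityId.MOBILISATION: _coverage(ActivityId.MOBILISATION, {ASHA: (1.0, 36)}, 685),
        ActivityId.ASSESSMENT: _coverage(
            ActivityId.ASSESSMENT, {A: (0.1, 20), N: (0.1, 17), M: (0.8, 7)}, 1049
        ),
        ActivityId.REFERRAL_COUNSELLING: _coverage(
            ActivityId.REFERRAL_COUNSELLING, {A: (0.1, 23), N: (0.1, 12), M: (0.8, 7)}, 640
        ),
        ActivityId.PRE_REFERRAL_DOSE: _coverage(
            ActivityId.PRE_REFERRAL_DOSE, {A: (0.1, 13), N: (0.1, 8), M: (0.8, 8)}, 14
        ),
        ActivityId.TREAT_PNEUMONIA: _coverage(
            ActivityId.TREAT_PNEUMONIA, {A: (0.1, 10), N: (0.9, 8), M: (0.1, 4)}, 94
        ),
        ActivityId.TREAT_SEVERE_PNEUMONIA: _coverage(
            ActivityId.TREAT_SEVERE_PNEUMONIA, {A: (0.1, 11), N: (0.1, 9), M: (0.9, 4)}, 19
        ),
        ActivityId.TREAT_CSI: _coverage(
            ActivityId.TREAT_CSI, {A: (0.1, 10), N: (0.1, 7), M: (0.9, 4)}, 452
        ),
        ActivityId.FOLLOWUP: _coverage(
            ActivityId.FOLLOWUP, {A: (0.1, 14), N: (0.1, 10), M: (0.9, 6)}, 1302
        ),
    }

    salaries = SalarySchedule(
        annual_salary_inr={A: 288_000.0, N: 460_800.0, M: 702_720.0}
    )
    operational = OperationalInputs(
        admin_roster=[
            AdminStaffRow(
                provider=M, n_staff=2, day_fraction=0.25, days_per_year=240,
                annual_salary_inr=700_000.0,
            ),
            AdminStaffRow(
                provider=ProviderType.ASHA_COORDINATOR, n_staff=6, day_fraction=0.5,
                days_per_year=240, annual_salary_inr=270_000.0,
            ),
        ],
        training_events=[
            TrainingEvent(
                name="provider-imnci", n_trainees=120, n_days=2,
                trainer_honoraria_inr=60_000, per_diems_inr=120_000,
                materials_inr=40_000, rental_refreshments_inr=30_000,
            ),
            TrainingEvent(
                name="refresher", n_trainees=80, n_days=1,
                trainer_honoraria_inr=40_000, per_diems_inr=70_000,
                materials_inr=20_000, rental_refreshments_inr=20_000,
            ),
        ],
        iec_items=[AnnualCostItem(item_key="iec_job_aids", annual_cost_inr=300_000.0)],
    )

    return SiteRegister(
        site_name="Lucknow",
        period="2018-19",
        live_births=13_895,
        exchange_rate_inr_per_usd=EXCHANGE_RATE_INR_PER_USD,
        infants=infants,
        activity_coverage=coverage,
        salaries=salaries,
        prices=_prices(),
        operational=operational,
        supply_pools={
            "hbnc_kit_weighing_scale_annualised": 40_000.0,
            "consumables_general": 30_000.0,
        },
    )


def palwal_register() -> SiteRegister:
    """The Palwal (Haryana) site-year register, 2018-19.

    4271 live births; 2316 infants with >=1 postnatal visit (54%), 39% of
    them completing 6-7 visits; 136 identified (5.9% of visited); 22
    pneumonia (all recommended), 108 clinical severe infection treated (67
    recommended/acceptable), 6 accepted referrals, no severe-pneumonia or
    critical-illness arm.
    """
    visit_counts = {1: 313, 2: 300, 3: 300, 4: 300, 5: 200, 6: 600, 7: 303}
    CSI = IMNCIClass.CLINICAL_SEVERE_INFECTION
    cases = [
        (IMNCIClass.PNEUMONIA, "recommended", 22),
        (CSI, "recommended", 57),
        (CSI, "acceptable", 10),
        (CSI, "partial", 26),
        (CSI, "noncompliant", 15),
        (CSI, "accepted", 6),
    ]
    # 130 coursed infants sharing 204 follow-up visits
    followup_plan = [(2, 74), (1, 56)]
    infants = _build_infants("pwl", visit_counts, cases, 29, followup_plan)

    coverage = {
        ActivityId.POSTNATAL_VISIT: _coverage(
            ActivityId.POSTNATAL_VISIT, {ASHA: (1.0, 20)}, 13_208
        ),
        ActivityId.MOBILISATION: _coverage(ActivityId.MOBILISATION, {ASHA: (1.0, 45)}, 33),
        ActivityId.ASSESSMENT: _coverage(
            ActivityId.ASSESSMENT, {A: (0.1, 15), N: (0.1, 3), M: (0.8, 9)}, 159
        ),
        ActivityId.REFERRAL_COUNSELLING: _coverage(
            ActivityId.REFERRAL_COUNSELLING, {A: (0.1, 11), N: (0.1, 3), M: (0.8, 7)}, 135
        ),
        ActivityId.PRE_REFERRAL_DOSE: _coverage(
            ActivityId.PRE_REFERRAL_DOSE, {A: (0.1, 10), N: (0.1, 5), M: (0.8, 6)}, 32
        ),
        ActivityId.TREAT_PNEUMONIA: _coverage(
            ActivityId.TREAT_PNEUMONIA, {A: (0.07, 7), N: (0.93, 2), M: (0.3, 4)}, 22
        ),
        ActivityId.TREAT_CSI: _coverage(
            ActivityId.TREAT_CSI, {A: (0.07, 6), N: (0.93, 3), M: (0.93, 4)}, 108
        ),
        ActivityId.FOLLOWUP: _coverage(
            ActivityId.FOLLOWUP, {A: (0.07, 15), N: (0.93, 11), M: (0.3, 7)}, 204
        ),
    }

    salaries = SalarySchedule(
        annual_salary_inr={A: 230_400.0, N: 345_600.0, M: 576_000.0}
    )
    operational = OperationalInputs(
        admin_roster=[
            AdminStaffRow(
                provider=ProviderType.ASHA_COORDINATOR, n_staff=4, day_fraction=0.5,
                days_per_year=240, annual_salary_inr=250_000.0,
            ),
            AdminStaffRow(
                provider=M, n_staff=2, day_fraction=0.25, days_per_year=240,
                annual_salary_inr=550_000.0,
            ),
        ],
        training_events=[
            TrainingEvent(
                name="provider-imnci", n_trainees=100, n_days=2,
                trainer_honoraria_inr=30_000, per_diems_inr=120_000,
                materials_inr=30_000, rental_refreshments_inr=20_000,
            ),
        ],
        iec_items=[AnnualCostItem(item_key="iec_job_aids", annual_cost_inr=160_000.0)],
        site_specials=[
            AnnualCostItem(item_key="school_rallies_super_village", annual_cost_inr=120_000.0),
            AnnualCostItem(item_key="asha_transport_per_diem", annual_cost_inr=700_000.0),
        ],
    )

    return SiteRegister(
        site_name="Palwal",
        period="2018-19",
        live_births=4271,
        exchange_rate_inr_per_usd=EXCHANGE_RATE_INR_PER_USD,
        infants=infants,
        activity_coverage=coverage,
        salaries=salaries,
        prices=_prices(),
        operational=operational,
        supply_pools={
            "hbnc_kit_weighing_scale_annualised": 25_000.0,
            "consumables_general": 20_000.0,
        },
    )
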