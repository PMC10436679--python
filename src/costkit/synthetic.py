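"""Synthetic site-register generator and its closed-form cost expectation.

``generate_site`` draws a full :class:`~costkit.model.SiteRegister` with the
statistical structure of a study site: live births, a postnatal-visit count
distribution, an identification rate among visited infants, a sign mix over
IMNCI classes, referral-acceptance and ASHA-mobilisation probabilities, and
per-arm adherence-category mixes. ``expected_costs`` computes the
expectation of every report line analytically (plug-in expectations for
ratio lines), which serves as the parameter-recovery oracle: the pipeline
run on a generated register must converge to it as live births grow.

Activity tallies (``n_units``) in the generated register are the realised
counts, exactly as a site's own register would record them.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .commodities import expected_commodity_cost, postnatal_incentive, pre_referral_dose_cost
from .model import (
    COSTED_PSBI_CLASSES,
    ActivityCoverage,
    ActivityId,
    AttributionFractions,
    ClinicalSigns,
    CoverageRow,
    IMNCIClass,
    IncentiveSchedule,
    InfantRecord,
    OperationalInputs,
    PriceList,
    ProviderType,
    SalarySchedule,
    SiteRegister,
    TreatmentCategory,
    TreatmentCourse,
)
from .operations_admin import operational_cost_per_live_birth
from .staff_time import staff_cost_per_infant

_GENERATED_CLASSES = (
    IMNCIClass.PNEUMONIA,
    IMNCIClass.SEVERE_PNEUMONIA,
    IMNCIClass.CLINICAL_SEVERE_INFECTION,
    IMNCIClass.CRITICAL_ILLNESS,
)

_CATEGORIES = (
    TreatmentCategory.RECOMMENDED,
    TreatmentCategory.ACCEPTABLE,
    TreatmentCategory.PARTIAL,
    TreatmentCategory.NON_COMPLIANT,
)


def _check_vector(name: str, probs: Dict, keys) -> None:
    total = sum(probs.get(k, 0.0) for k in keys)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {total}")
    if any(probs.get(k, 0.0) < 0 for k in keys):
        raise ValueError(f"{name} has negative entries")


class SiteParams(BaseModel):
    """Generator parameters for one synthetic site-year."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    site_name: str = "synthetic"
    period: str = "2018-19"
    live_births: int = Field(gt=0)
    p_visited: float = Field(ge=0.0, le=1.0)
    #: distribution of postnatal visit counts 1..7, conditional on >=1 visit
    visit_count_distribution: List[float]
    p_identified_given_visited: float = Field(ge=0.0, le=1.0)
    sign_mix: Dict[IMNCIClass, float]
    p_mobilised_by_asha: float = Field(ge=0.0, le=1.0)
    p_referral_accepted: float = Field(ge=0.0, le=1.0)
    compliance_mix_psbi: Dict[TreatmentCategory, float]
    compliance_mix_pneumonia: Dict[TreatmentCategory, float]
    #: distribution of follow-up visit counts 0..len-1 per coursed infant
    followup_visits_distribution: List[float]
    #: provider mix per activity: {activity: {provider: (coverage, minutes)}}
    activity_minutes: Dict[ActivityId, Dict[ProviderType, Tuple[float, float]]]
    salaries: SalarySchedule
    prices: PriceList
    incentives: IncentiveSchedule = Field(default_factory=IncentiveSchedule)
    attribution: AttributionFractions = Field(default_factory=AttributionFractions)
    operational: OperationalInputs = Field(default_factory=OperationalInputs)
    supply_pools: Dict[str, float] = Field(default_factory=dict)
    exchange_rate_inr_per_usd: float = Field(default=68.5, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _vectors(self):
        if len(self.visit_count_distribution) != 7:
            raise ValueError("visit_count_distribution must cover counts 1..7")
        if abs(sum(self.visit_count_distribution) - 1.0) > 1e-9:
            raise ValueError("visit_count_distribution must sum to 1")
        _check_vector("sign_mix", self.sign_mix, _GENERATED_CLASSES)
        _check_vector("compliance_mix_psbi", self.compliance_mix_psbi, _CATEGORIES)
        _check_vector("compliance_mix_pneumonia", self.compliance_mix_pneumonia, _CATEGORIES)
        if abs(sum(self.followup_visits_distribution) - 1.0) > 1e-9:
            raise ValueError("followup_visits_distribution must sum to 1")
        return self


def _signs_for(cls: IMNCIClass, rng: np.random.Generator) -> Tuple[ClinicalSigns, int]:
    """Draw (signs, age) consistent with one IMNCI class."""
    if cls is IMNCIClass.PNEUMONIA:
        age = int(rng.integers(7, 60))
        return ClinicalSigns(respiratory_rate=int(rng.integers(60, 81))), age
    if cls is IMNCIClass.SEVERE_PNEUMONIA:
        age = int(rng.integers(0, 7))
        return ClinicalSigns(respiratory_rate=int(rng.integers(60, 81))), age
    if cls is IMNCIClass.CLINICAL_SEVERE_INFECTION:
        age = int(rng.integers(0, 60))
        return ClinicalSigns(respiratory_rate=45, temperature_c=38.5), age
    if cls is IMNCIClass.CRITICAL_ILLNESS:
        age = int(rng.integers(0, 60))
        return ClinicalSigns(convulsions=True), age
    return ClinicalSigns(respiratory_rate=40), int(rng.integers(0, 60))


def _draw_course(
    cls: IMNCIClass, category: TreatmentCategory, rng: np.random.Generator
) -> TreatmentCourse:
    if category is TreatmentCategory.NON_COMPLIANT:
        return TreatmentCourse(target_class=cls, other_antibiotics=["cefixime"])
    if cls is IMNCIClass.PNEUMONIA:
        if category is TreatmentCategory.RECOMMENDED:
            doses = 14
        elif category is TreatmentCategory.ACCEPTABLE:
            doses = int(rng.integers(10, 14))
        else:
            doses = int(rng.integers(0, 10))
        return TreatmentCourse(
            target_class=cls, amoxicillin_doses=doses, amoxicillin_days=math.ceil(doses / 2)
        )
    if cls is IMNCIClass.CRITICAL_ILLNESS:
        # no categorisable regimen available at primary level
        return TreatmentCourse(target_class=cls, other_antibiotics=["non-recommended"])
    if category is TreatmentCategory.RECOMMENDED:
        g, a = 7, 7
    elif category is TreatmentCategory.ACCEPTABLE:
        g, a = int(rng.integers(2, 7)), 7
    else:  # PARTIAL: either too little gentamicin or a short amoxicillin course
        if rng.random() < 0.5:
            g, a = int(rng.integers(0, 2)), 7
        else:
            g, a = int(rng.integers(0, 8)), int(rng.integers(0, 7))
    return TreatmentCourse(target_class=cls, gentamicin_days=g, amoxicillin_days=a)


def generate_site(params: SiteParams, seed: Optional[int] = None) -> SiteRegister:
    """Draw one synthetic site register; reproducible given the seed."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_visited = int(rng.binomial(params.live_births, params.p_visited))
    visit_counts = rng.choice(
        np.arange(1, 8), size=n_visited, p=np.asarray(params.visit_count_distribution)
    )
    identified = rng.random(n_visited) < params.p_identified_given_visited

    class_values = list(_GENERATED_CLASSES)
    class_probs = np.array([params.sign_mix.get(c, 0.0) for c in class_values])

    infants: List[InfantRecord] = []
    n_units = {a: 0 for a in ActivityId}
    n_units[ActivityId.POSTNATAL_VISIT] = int(visit_counts.sum())

    followup_k = np.arange(len(params.followup_visits_distribution))
    followup_p = np.asarray(params.followup_visits_distribution)

    for idx in range(n_visited):
        visits = int(visit_counts[idx])
        if not identified[idx]:
            signs, age = _signs_for(IMNCIClass.NO_PSBI_SIGN, rng)
            infants.append(
                InfantRecord(
                    infant_id=f"{params.site_name}-{idx:06d}",
                    age_days_at_presentation=age,
                    postnatal_visits=visits,
                    signs=signs,
                )
            )
            continue

        cls = class_values[int(rng.choice(len(class_values), p=class_probs))]
        signs, age = _signs_for(cls, rng)
        mobilised = bool(rng.random() < params.p_mobilised_by_asha)
        n_units[ActivityId.ASSESSMENT] += 1
        is_psbi = cls is not IMNCIClass.PNEUMONIA
        accepted = False
        course = None
        followups = 0
        if is_psbi:
            n_units[ActivityId.REFERRAL_COUNSELLING] += 1
            accepted = bool(rng.random() < params.p_referral_accepted)
        if accepted:
            n_units[ActivityId.PRE_REFERRAL_DOSE] += 1
        else:
            mix = (
                params.compliance_mix_pneumonia
                if cls is IMNCIClass.PNEUMONIA
                else params.compliance_mix_psbi
            )
            cat = _CATEGORIES[
                int(rng.choice(4, p=np.array([mix.get(c, 0.0) for c in _CATEGORIES])))
            ]
            course = _draw_course(cls, cat, rng)
            followups = int(rng.choice(followup_k, p=followup_p))
            n_units[ActivityId.FOLLOWUP] += followups
            treat_act = {
                IMNCIClass.PNEUMONIA: ActivityId.TREAT_PNEUMONIA,
                IMNCIClass.SEVERE_PNEUMONIA: ActivityId.TREAT_SEVERE_PNEUMONIA,
                IMNCIClass.CLINICAL_SEVERE_INFECTION: ActivityId.TREAT_CSI,
            }.get(cls)
            if treat_act is not None:
                n_units[treat_act] += 1
        if mobilised:
            n_units[ActivityId.MOBILISATION] += 1

        infants.append(
            InfantRecord(
                infant_id=f"{params.site_name}-{idx:06d}",
                age_days_at_presentation=age,
                postnatal_visits=visits,
                signs=signs,
                mobilised_by_asha=mobilised,
                referral_accepted=accepted,
                pre_referral_dose_given=accepted,
                treatment_course=course,
                followup_visits=followups,
            )
        )

    coverage = {}
    for activity, rows in params.activity_minutes.items():
        coverage[activity] = ActivityCoverage(
            activity_id=activity,
            rows={
                p: CoverageRow(coverage_fraction=cov, mean_minutes=minutes)
                for p, (cov, minutes) in rows.items()
            },
            n_units=n_units[activity],
        )

    return SiteRegister(
        site_name=params.site_name,
        period=params.period,
        live_births=params.live_births,
        exchange_rate_inr_per_usd=params.exchange_rate_inr_per_usd,
        infants=infants,
        activity_coverage=coverage,
        salaries=params.salaries,
        prices=params.prices,
        incentives=params.incentives,
        attribution=params.attribution,
        operational=params.operational,
        supply_pools=dict(params.supply_pools),
    )


def expected_costs(params: SiteParams) -> Dict[str, float]:
    """Closed-form expectations of the main report lines, in INR.

    Per-treated and per-live-birth lines are plug-in expectations
    (expected numerator over expected denominator); for the deterministic
    limit (all probabilities 0/1) they coincide exactly with the pipeline.
    """
    e_visited = params.live_births * params.p_visited
    e_visits_per = float(
        np.dot(np.arange(1, 8), np.asarray(params.visit_count_distribution))
    )
    e_incentive_per_visited = sum(
        p * postnatal_incentive(k, params.incentives).amount
        for k, p in zip(range(1, 8), params.visit_count_distribution)
    )
    e_identified = e_visited * params.p_identified_given_visited
    e_class = {c: e_identified * params.sign_mix.get(c, 0.0) for c in _GENERATED_CLASSES}
    e_psbi_classified = sum(e_class[c] for c in _GENERATED_CLASSES if c is not IMNCIClass.PNEUMONIA)
    e_accepted = e_psbi_classified * params.p_referral_accepted
    e_mobilised = e_identified * params.p_mobilised_by_asha

    keep = 1.0 - params.p_referral_accepted
    mix_psbi = params.compliance_mix_psbi
    mix_pneu = params.compliance_mix_pneumonia
    recacc_psbi = mix_psbi.get(TreatmentCategory.RECOMMENDED, 0.0) + mix_psbi.get(
        TreatmentCategory.ACCEPTABLE, 0.0
    )
    recacc_pneu = mix_pneu.get(TreatmentCategory.RECOMMENDED, 0.0) + mix_pneu.get(
        TreatmentCategory.ACCEPTABLE, 0.0
    )
    e_treated = {
        IMNCIClass.PNEUMONIA: e_class[IMNCIClass.PNEUMONIA] * recacc_pneu,
        IMNCIClass.SEVERE_PNEUMONIA: e_class[IMNCIClass.SEVERE_PNEUMONIA] * keep * recacc_psbi,
        IMNCIClass.CLINICAL_SEVERE_INFECTION: e_class[IMNCIClass.CLINICAL_SEVERE_INFECTION]
        * keep
        * recacc_psbi,
    }
    e_treated_psbi = sum(e_treated[c] for c in COSTED_PSBI_CLASSES)
    e_treated_total = e_treated_psbi + e_treated[IMNCIClass.PNEUMONIA]
    if e_treated_total <= 0:
        raise ValueError("parameters give zero expected treated infants")

    def unit_staff(activity: ActivityId) -> float:
        rows = params.activity_minutes.get(activity)
        if rows is None:
            return 0.0
        ac = ActivityCoverage(
            activity_id=activity,
            rows={
                p: CoverageRow(coverage_fraction=c, mean_minutes=m)
                for p, (c, m) in rows.items()
            },
        )
        return staff_cost_per_infant(ac, params.salaries).amount

    frac = params.attribution
    incentives_pool = (
        e_visited * e_incentive_per_visited * frac.get("postnatal_incentive")
        + e_mobilised * params.incentives.referral_transport_inr
    )
    staff_pool = (
        e_identified * unit_staff(ActivityId.ASSESSMENT)
        + e_psbi_classified * unit_staff(ActivityId.REFERRAL_COUNSELLING)
        + e_accepted * unit_staff(ActivityId.PRE_REFERRAL_DOSE)
    )
    supplies_pool = 0.0
    if e_accepted:
        supplies_pool += e_accepted * pre_referral_dose_cost(params.prices).amount
    if params.prices.mother_card is not None:
        supplies_pool += params.prices.mother_card * e_visited * frac.get("mother_card")
    for key, annual in params.supply_pools.items():
        supplies_pool += annual * frac.get(key)

    pre_total = (incentives_pool + staff_pool + supplies_pool) / e_treated_total
    pre_staff = staff_pool / e_treated_total

    recacc = {
        TreatmentCategory.RECOMMENDED: mix_psbi.get(TreatmentCategory.RECOMMENDED, 0.0),
        TreatmentCategory.ACCEPTABLE: mix_psbi.get(TreatmentCategory.ACCEPTABLE, 0.0),
    }
    recacc_p = {
        TreatmentCategory.RECOMMENDED: mix_pneu.get(TreatmentCategory.RECOMMENDED, 0.0),
        TreatmentCategory.ACCEPTABLE: mix_pneu.get(TreatmentCategory.ACCEPTABLE, 0.0),
    }
    visits = {
        IMNCIClass.PNEUMONIA: 1,
        IMNCIClass.SEVERE_PNEUMONIA: 7,
        IMNCIClass.CLINICAL_SEVERE_INFECTION: 7,
    }
    treat_act = {
        IMNCIClass.PNEUMONIA: ActivityId.TREAT_PNEUMONIA,
        IMNCIClass.SEVERE_PNEUMONIA: ActivityId.TREAT_SEVERE_PNEUMONIA,
        IMNCIClass.CLINICAL_SEVERE_INFECTION: ActivityId.TREAT_CSI,
    }
    arm_total = {}
    arm_staff = {}
    for cls in visits:
        if e_treated[cls] <= 0:
            # an arm nobody is treated in contributes no outpatient line,
            # matching the pipeline on a register without such courses
            arm_staff[cls] = arm_total[cls] = 0.0
            continue
        mix = recacc_p if cls is IMNCIClass.PNEUMONIA else recacc
        cc = expected_commodity_cost(cls, mix, params.prices)
        staff = unit_staff(treat_act[cls]) * visits[cls]
        arm_staff[cls] = staff
        arm_total[cls] = staff + cc.medicines.amount + cc.consumables.amount

    if e_treated_psbi > 0:
        outp_psbi = (
            sum(arm_total[c] * e_treated[c] for c in COSTED_PSBI_CLASSES) / e_treated_psbi
        )
        outp_psbi_staff = (
            sum(arm_staff[c] * e_treated[c] for c in COSTED_PSBI_CLASSES) / e_treated_psbi
        )
    else:
        outp_psbi = outp_psbi_staff = 0.0

    e_coursed = e_class[IMNCIClass.PNEUMONIA] + (e_psbi_classified * keep)
    e_followup_mean = float(
        np.dot(
            np.arange(len(params.followup_visits_distribution)),
            np.asarray(params.followup_visits_distribution),
        )
    )
    followup = (
        e_coursed * e_followup_mean * unit_staff(ActivityId.FOLLOWUP) / e_treated_total
    )

    operational, administrative = operational_cost_per_live_birth(
        params.operational, frac, params.live_births, params.salaries.working_days_per_year
    )
    op_admin = operational.amount + administrative.amount

    direct_psbi = pre_total + outp_psbi + followup
    direct_pneu = pre_total + arm_total[IMNCIClass.PNEUMONIA] + followup
    total_psbi = direct_psbi + op_admin
    total_pneu = direct_pneu + op_admin
    staff_psbi = pre_staff + outp_psbi_staff + followup + administrative.amount
    staff_pneu = pre_staff + arm_staff[IMNCIClass.PNEUMONIA] + followup + administrative.amount

    return {
        "treated_psbi": e_treated_psbi,
        "treated_pneumonia": e_treated[IMNCIClass.PNEUMONIA],
        "pre_outpatient_per_treated": pre_total,
        "pre_outpatient_staff_per_treated": pre_staff,
        "outpatient_pneumonia_per_treated": arm_total[IMNCIClass.PNEUMONIA],
        "outpatient_psbi_per_treated": outp_psbi,
        "followup_per_treated": followup,
        "operational_per_live_birth": operational.amount,
        "administrative_per_live_birth": administrative.amount,
        "direct_psbi_per_treated": direct_psbi,
        "direct_pneumonia_per_treated": direct_pneu,
        "total_psbi_per_treated": total_psbi,
        "total_pneumonia_per_treated": total_pneu,
        "incremental_psbi_per_treated": total_psbi - staff_psbi,
        "incremental_pneumonia_per_treated": total_pneu - staff_pneu,
    }


def report_lines_inr(report) -> Dict[str, float]:
    """Pipeline report lines in INR keyed like :func:`expected_costs`."""
    from .model import IMNCIClass as C

    return {
        "treated_psbi": float(report.treated.psbi),
        "treated_pneumonia": float(report.treated.pneumonia),
        "pre_outpatient_per_treated": report.pre_outpatient_per_treated.amount,
        "pre_outpatient_staff_per_treated": report.pre_outpatient_staff_per_treated.amount,
        "outpatient_pneumonia_per_treated": report.outpatient[C.PNEUMONIA].total.amount,
        "outpatient_psbi_per_treated": report.outpatient_psbi.total.amount,
        "followup_per_treated": report.followup_per_treated.amount,
        "operational_per_live_birth": report.operational_per_live_birth.amount,
        "administrative_per_live_birth": report.administrative_per_live_birth.amount,
        "direct_psbi_per_treated": report.direct_psbi.amount,
        "direct_pneumonia_per_treated": report.direct_pneumonia.amount,
        "total_psbi_per_treated": report.total_psbi.amount,
        "total_pneumonia_per_treated": report.total_pneumonia.amount,
        "incremental_psbi_per_treated": report.incremental_psbi.amount,
        "incremental_pneumonia_per_treated": report.incremental_pneumonia.amount,
    }
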