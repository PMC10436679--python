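"""Site-level cost aggregation and report assembly.

The pipeline mirrors how a bottom-up activity-based costing is assembled:

1. *Pre-outpatient* — everything spent getting a sick infant identified and
   to a facility: attributed postnatal-visit incentives, ASHA mobilisation
   incentives, staff time for assessment / referral counselling /
   pre-referral dosing, pre-referral supplies, mother cards and attributed
   shared supply pools. Expressed per infant receiving recommended or
   acceptable treatment (both arms combined).
2. *Outpatient treatment* — staff time, medicines and consumables per
   treated infant, separately for pneumonia and for each PSBI subclass,
   with PSBI summarised as a treated-count-weighted average.
3. *Follow-up* — facility reassessment visits, costed per visit and spread
   over all treated infants.
4. *Operational and administrative* — indirect costs per live birth.

Totals per treated infant add the direct per-infant costs to the per-live-
birth indirect block; incremental costs strip every salary-derived
component, leaving the cash outlay for supplies, medicines and operations.
All arithmetic is in INR; conversion to USD happens once, at reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .classification import classify_clinical, classify_treatment, is_treated
from .commodities import (
    CommodityCost,
    course_commodity_cost,
    postnatal_incentive,
    pre_referral_dose_cost,
    referral_incentive,
)
from .errors import CostkitError, CurrencyError
from .model import (
    COSTED_PSBI_CLASSES,
    ActivityCoverage,
    ActivityId,
    IMNCIClass,
    SiteRegister,
    TreatmentCategory,
)
from .money import Currency, Money, inr, printed, to_usd
from .operations_admin import operational_cost_per_live_birth
from .staff_time import staff_cost_per_infant


@dataclass(frozen=True)
class CostBreakdown:
    """Additive cost components in one currency."""

    staff: Money
    medicines: Money
    consumables: Money
    incentives: Money
    operational: Money
    administrative: Money

    @property
    def total(self) -> Money:
        return (
            self.staff
            + self.medicines
            + self.consumables
            + self.incentives
            + self.operational
            + self.administrative
        )


@dataclass(frozen=True)
class TreatedCounts:
    psbi: int
    pneumonia: int
    by_class: Dict[IMNCIClass, int]

    @property
    def total(self) -> int:
        return self.psbi + self.pneumonia


@dataclass
class CostingOptions:
    """Tunable conventions of the costing model.

    visits_per_course
        Facility visits one treated infant generates per arm: 7 for the
        PSBI subclasses (daily gentamicin injection over the recommended
        course) and 1 for pneumonia (a dispensing visit; mothers administer
        the oral course at home).
    denominator
        ``"all_treated"`` spreads pre-outpatient and follow-up costs over
        recommended/acceptable treated infants of both arms combined (the
        headline convention); ``"psbi_only"`` restricts to the PSBI arm for
        sensitivity analyses.
    """

    visits_per_course: Dict[IMNCIClass, int] = field(
        default_factory=lambda: {
            IMNCIClass.PNEUMONIA: 1,
            IMNCIClass.SEVERE_PNEUMONIA: 7,
            IMNCIClass.CLINICAL_SEVERE_INFECTION: 7,
        }
    )
    denominator: str = "all_treated"


_TREAT_ACTIVITY = {
    IMNCIClass.PNEUMONIA: ActivityId.TREAT_PNEUMONIA,
    IMNCIClass.SEVERE_PNEUMONIA: ActivityId.TREAT_SEVERE_PNEUMONIA,
    IMNCIClass.CLINICAL_SEVERE_INFECTION: ActivityId.TREAT_CSI,
}


def infant_imnci_class(infant) -> IMNCIClass:
    return classify_clinical(infant.signs, infant.age_days_at_presentation)


def count_treated(register: SiteRegister) -> TreatedCounts:
    """Infants receiving recommended or acceptable treatment, by arm."""
    by_class = {
        IMNCIClass.PNEUMONIA: 0,
        IMNCIClass.SEVERE_PNEUMONIA: 0,
        IMNCIClass.CLINICAL_SEVERE_INFECTION: 0,
    }
    for infant in register.infants:
        course = infant.treatment_course
        if course is None:
            continue
        if course.target_class not in by_class:
            continue  # critical illness / no-sign courses are not categorisable
        if is_treated(classify_treatment(course)):
            by_class[course.target_class] += 1
    psbi = sum(by_class[c] for c in COSTED_PSBI_CLASSES)
    return TreatedCounts(psbi=psbi, pneumonia=by_class[IMNCIClass.PNEUMONIA], by_class=by_class)


# ---------------------------------------------------------------------------
# free-standing report arithmetic (also used on printed table inputs)
# ---------------------------------------------------------------------------


def outpatient_psbi_weighted(
    subclass_costs: Mapping[IMNCIClass, Money], subclass_n: Mapping[IMNCIClass, int]
) -> Money:
    """Treated-count-weighted average cost over the PSBI subclasses."""
    num: Optional[Money] = None
    den = 0
    for cls in COSTED_PSBI_CLASSES:
        n = subclass_n.get(cls, 0)
        if n == 0:
            continue
        term = subclass_costs[cls] * n
        num = term if num is None else num + term
        den += n
    if den == 0 or num is None:
        raise CostkitError("no treated infants in any PSBI subclass")
    return num / den


def followup_cost_per_treated(
    followup_visits: int, per_visit_staff_cost: Money, treated_total: int
) -> Money:
    """Follow-up reassessment cost spread over all treated infants."""
    if treated_total <= 0:
        raise CostkitError("treated_total must be positive")
    return per_visit_staff_cost * followup_visits / treated_total


def total_cost_per_treated(direct: Money, op_admin_per_live_birth: Money) -> Money:
    """Direct per-treated cost plus the per-live-birth indirect block."""
    if direct.currency != op_admin_per_live_birth.currency:
        raise CurrencyError("direct and indirect components must share a currency")
    return direct + op_admin_per_live_birth


def incremental_cost(total: Money, staff_components: Money) -> Money:
    """Total minus every salary-derived component: the cash outlay for
    supplies, medicines and operations."""
    try:
        return total - staff_components
    except ValueError as exc:
        raise CostkitError(
            f"staff components ({staff_components.amount:.2f}) exceed total "
            f"({total.amount:.2f}); component specification is inconsistent"
        ) from exc


def staff_share(total: Money, incremental: Money) -> float:
    """Share of total cost that is salary-derived, as a fraction."""
    if total.amount <= 0:
        raise CostkitError("total must be positive")
    return (total.amount - incremental.amount) / total.amount


def cross_site_weighted_average(
    values: Sequence, weights: Sequence[float]
):
    """Average of per-site values weighted by treated counts.

    Accepts Money (single currency) or plain numbers; returns the same kind.
    """
    if len(values) != len(weights):
        raise CostkitError(
            f"values ({len(values)}) and weights ({len(weights)}) differ in length"
        )
    w_total = float(sum(weights))
    if w_total <= 0:
        raise CostkitError("total weight must be positive")
    if values and isinstance(values[0], Money):
        acc = values[0] * weights[0]
        for v, w in zip(values[1:], weights[1:]):
            acc = acc + v * w
        return acc / w_total
    return sum(float(v) * float(w) for v, w in zip(values, weights)) / w_total


def coverage_statistics(register: SiteRegister) -> Dict[str, float]:
    """Named coverage percentages at the precision a report table prints.

    * ``visited_pct`` — live births receiving >=1 postnatal home visit;
    * ``complete_visit_pct`` — share of visited infants with 6-7 visits;
    * ``identified_pct`` — visited infants identified with pneumonia/PSBI;
    * ``psbi_rec_acc_pct`` — PSBI-arm infants on recommended/acceptable
      treatment, of all treated for PSBI;
    * ``pneumonia_rec_acc_pct`` — same for the pneumonia arm.

    A zero denominator omits the statistic with a warning rather than
    raising.
    """
    stats: Dict[str, float] = {}
    visited = register.n_visited()
    complete = sum(1 for i in register.infants if i.postnatal_visits >= 6)
    classes = [infant_imnci_class(i) for i in register.infants]
    identified = sum(1 for c in classes if c is not IMNCIClass.NO_PSBI_SIGN)
    psbi_all = sum(
        1
        for c in classes
        if c
        in (
            IMNCIClass.SEVERE_PNEUMONIA,
            IMNCIClass.CLINICAL_SEVERE_INFECTION,
            IMNCIClass.CRITICAL_ILLNESS,
        )
    )
    pneumonia_all = sum(1 for c in classes if c is IMNCIClass.PNEUMONIA)
    treated = count_treated(register)

    def pct(name, num, den, dp):
        if den <= 0:
            warnings.warn(f"zero denominator for {name}; statistic omitted", stacklevel=2)
            return
        stats[name] = printed(100.0 * num / den, dp)

    pct("visited_pct", visited, register.live_births, 0)
    pct("complete_visit_pct", complete, visited, 0)
    pct("identified_pct", identified, visited, 1)
    pct("psbi_rec_acc_pct", treated.psbi, psbi_all, 0)
    pct("pneumonia_rec_acc_pct", treated.pneumonia, pneumonia_all, 0)
    return stats


# ---------------------------------------------------------------------------
# the site pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmCost:
    """Per-treated-infant outpatient cost for one arm/subclass (INR)."""

    staff: Money
    medicines: Money
    consumables: Money
    n_treated: int

    @property
    def total(self) -> Money:
        return self.staff + self.medicines + self.consumables


@dataclass
class SiteCostReport:
    """All report lines for one site, in INR; render USD via :meth:`usd_table`."""

    site_name: str
    period: str
    live_births: int
    exchange_rate: float
    treated: TreatedCounts
    coverage: Dict[str, float]

    pre_outpatient_per_treated: Money
    pre_outpatient_staff_per_treated: Money
    pre_outpatient_incentives_per_treated: Money

    outpatient: Dict[IMNCIClass, ArmCost]
    outpatient_psbi: ArmCost  # weighted across subclasses

    followup_per_treated: Money  # entirely staff time

    operational_per_live_birth: Money
    administrative_per_live_birth: Money

    @property
    def op_admin_per_live_birth(self) -> Money:
        return self.operational_per_live_birth + self.administrative_per_live_birth

    @property
    def direct_pneumonia(self) -> Money:
        return (
            self.pre_outpatient_per_treated
            + self.outpatient[IMNCIClass.PNEUMONIA].total
            + self.followup_per_treated
        )

    @property
    def direct_psbi(self) -> Money:
        return (
            self.pre_outpatient_per_treated
            + self.outpatient_psbi.total
            + self.followup_per_treated
        )

    @property
    def total_psbi(self) -> Money:
        return total_cost_per_treated(self.direct_psbi, self.op_admin_per_live_birth)

    @property
    def total_pneumonia(self) -> Money:
        return total_cost_per_treated(self.direct_pneumonia, self.op_admin_per_live_birth)

    def staff_components(self, arm: str) -> Money:
        """All salary-derived cost per treated infant for ``arm`` ('psbi'/'pneumonia')."""
        outp = self.outpatient_psbi if arm == "psbi" else self.outpatient[IMNCIClass.PNEUMONIA]
        return (
            self.pre_outpatient_staff_per_treated
            + outp.staff
            + self.followup_per_treated
            + self.administrative_per_live_birth
        )

    @property
    def incremental_psbi(self) -> Money:
        return incremental_cost(self.total_psbi, self.staff_components("psbi"))

    @property
    def incremental_pneumonia(self) -> Money:
        return incremental_cost(self.total_pneumonia, self.staff_components("pneumonia"))

    @property
    def per_live_birth_total(self) -> Money:
        """Total program cost spread over every live birth in the catchment."""
        direct_pool = (
            self.direct_psbi * self.treated.psbi
            + self.direct_pneumonia * self.treated.pneumonia
        )
        return direct_pool / self.live_births + self.op_admin_per_live_birth

    def direct_breakdown(self, arm: str) -> CostBreakdown:
        outp = self.outpatient_psbi if arm == "psbi" else self.outpatient[IMNCIClass.PNEUMONIA]
        non_incentive_pre = self.pre_outpatient_per_treated - self.pre_outpatient_incentives_per_treated
        supplies_pre = non_incentive_pre - self.pre_outpatient_staff_per_treated
        return CostBreakdown(
            staff=self.pre_outpatient_staff_per_treated + outp.staff + self.followup_per_treated,
            medicines=outp.medicines,
            consumables=outp.consumables + supplies_pre,
            incentives=self.pre_outpatient_incentives_per_treated,
            operational=self.operational_per_live_birth,
            administrative=self.administrative_per_live_birth,
        )

    def usd(self, m: Money, dp: int = 1) -> float:
        return to_usd(m, self.exchange_rate, dp).amount

    def usd_table(self) -> Dict[str, float]:
        """The per-site cost summary in USD at printed (1 dp) precision."""
        u = self.usd
        total_psbi = self.total_psbi
        table = {
            "pre_outpatient_per_treated": u(self.pre_outpatient_per_treated),
            "outpatient_pneumonia_per_treated": u(self.outpatient[IMNCIClass.PNEUMONIA].total),
            "outpatient_psbi_per_treated": u(self.outpatient_psbi.total),
            "followup_per_treated": u(self.followup_per_treated),
            "direct_pneumonia_per_treated": u(self.direct_pneumonia),
            "direct_psbi_per_treated": u(self.direct_psbi),
            "operational_per_live_birth": u(self.operational_per_live_birth),
            "administrative_per_live_birth": u(self.administrative_per_live_birth),
            "op_admin_per_live_birth": u(self.op_admin_per_live_birth),
            "total_psbi_per_treated": u(total_psbi),
            "total_pneumonia_per_treated": u(self.total_pneumonia),
            "incremental_psbi_per_treated": u(self.incremental_psbi),
            "incremental_pneumonia_per_treated": u(self.incremental_pneumonia),
            "total_per_live_birth": u(self.per_live_birth_total),
            "pre_outpatient_share_pct": printed(
                100.0 * self.pre_outpatient_per_treated.amount / total_psbi.amount, 1
            ),
            "op_admin_share_pct": printed(
                100.0 * self.op_admin_per_live_birth.amount / total_psbi.amount, 1
            ),
            "staff_share_psbi_pct": printed(
                100.0 * staff_share(total_psbi, self.incremental_psbi), 0
            ),
        }
        return table


def _activity_units(
    register: SiteRegister, activity: ActivityId, fallback: int
) -> int:
    ac = register.activity_coverage.get(activity)
    if ac is not None and ac.n_units > 0:
        return ac.n_units
    return fallback


def _unit_staff_cost(register: SiteRegister, activity: ActivityId) -> Money:
    ac = register.activity_coverage.get(activity)
    if ac is None:
        raise CostkitError(f"no activity_coverage entry for {activity.value}")
    return staff_cost_per_infant(ac, register.salaries)


def pre_outpatient_cost_per_treated(
    register: SiteRegister, options: Optional[CostingOptions] = None
) -> Tuple[Money, Money, Money]:
    """(total, staff part, incentive part) per treated infant, in INR.

    The pool covers identification and facility management before outpatient
    treatment: attributed postnatal incentives, mobilisation incentives,
    assessment / counselling / pre-referral staff time, pre-referral
    supplies, mother cards and attributed shared supply pools.
    """
    options = options or CostingOptions()
    treated = count_treated(register)
    den = treated.psbi if options.denominator == "psbi_only" else treated.total
    if den <= 0:
        raise CostkitError("no treated infants; pre-outpatient cost undefined")

    incentives_pool = 0.0
    for infant in register.infants:
        incentives_pool_full = postnatal_incentive(infant.postnatal_visits, register.incentives)
        incentives_pool += incentives_pool_full.amount
    incentives_pool *= register.attribution.get("postnatal_incentive")

    n_mobilised = _activity_units(
        register,
        ActivityId.MOBILISATION,
        sum(1 for i in register.infants if i.mobilised_by_asha),
    )
    incentives_pool += (
        referral_incentive(True, register.incentives).amount * n_mobilised
    )

    staff_pool = 0.0
    classes = [infant_imnci_class(i) for i in register.infants]
    n_identified = sum(1 for c in classes if c is not IMNCIClass.NO_PSBI_SIGN)
    n_psbi = sum(
        1
        for c in classes
        if c
        in (
            IMNCIClass.SEVERE_PNEUMONIA,
            IMNCIClass.CLINICAL_SEVERE_INFECTION,
            IMNCIClass.CRITICAL_ILLNESS,
        )
    )
    n_accepted = sum(1 for i in register.infants if i.referral_accepted)
    for activity, fallback in (
        (ActivityId.ASSESSMENT, n_identified),
        (ActivityId.REFERRAL_COUNSELLING, n_psbi),
        (ActivityId.PRE_REFERRAL_DOSE, n_accepted),
    ):
        if activity not in register.activity_coverage:
            continue
        n = _activity_units(register, activity, fallback)
        staff_pool += _unit_staff_cost(register, activity).amount * n

    supplies_pool = 0.0
    n_preref = _activity_units(register, ActivityId.PRE_REFERRAL_DOSE, n_accepted)
    if n_preref:
        supplies_pool += pre_referral_dose_cost(register.prices).amount * n_preref
    if register.prices.mother_card is not None:
        supplies_pool += (
            register.prices.mother_card
            * register.n_visited()
            * register.attribution.get("mother_card")
        )
    for key, annual in register.supply_pools.items():
        supplies_pool += annual * register.attribution.get(key)

    total = inr((incentives_pool + staff_pool + supplies_pool) / den)
    return total, inr(staff_pool / den), inr(incentives_pool / den)


def _outpatient_arm(
    register: SiteRegister, cls: IMNCIClass, options: CostingOptions
) -> Optional[ArmCost]:
    """Per-treated outpatient cost for one arm; None when nobody was treated."""
    courses = [
        i.treatment_course
        for i in register.infants
        if i.treatment_course is not None
        and i.treatment_course.target_class is cls
        and is_treated(classify_treatment(i.treatment_course))
    ]
    if not courses:
        return None
    activity = register.activity_coverage.get(_TREAT_ACTIVITY[cls])
    if activity is None:
        raise CostkitError(
            f"treated infants present but no activity_coverage for {_TREAT_ACTIVITY[cls].value}"
        )
    per_visit = staff_cost_per_infant(activity, register.salaries)
    staff = per_visit * options.visits_per_course[cls]
    med = 0.0
    cons = 0.0
    for course in courses:
        cc = course_commodity_cost(course, register.prices)
        med += cc.medicines.amount
        cons += cc.consumables.amount
    n = len(courses)
    return ArmCost(
        staff=staff, medicines=inr(med / n), consumables=inr(cons / n), n_treated=n
    )


def cost_site(
    register: SiteRegister, options: Optional[CostingOptions] = None
) -> SiteCostReport:
    """Run the full costing pipeline for one site register."""
    options = options or CostingOptions()
    treated = count_treated(register)
    if treated.total == 0:
        raise CostkitError("register has no treated infants; nothing to cost")

    pre_total, pre_staff, pre_incentives = pre_outpatient_cost_per_treated(register, options)

    outpatient: Dict[IMNCIClass, ArmCost] = {}
    for cls in (IMNCIClass.PNEUMONIA, *COSTED_PSBI_CLASSES):
        arm = _outpatient_arm(register, cls, options)
        if arm is not None:
            outpatient[cls] = arm
    if IMNCIClass.PNEUMONIA not in outpatient:
        outpatient[IMNCIClass.PNEUMONIA] = ArmCost(inr(0), inr(0), inr(0), 0)

    psbi_arms = {c: a for c, a in outpatient.items() if c in COSTED_PSBI_CLASSES}
    if not psbi_arms:
        raise CostkitError("no treated PSBI infants in register")
    weighted_total = outpatient_psbi_weighted(
        {c: a.total for c, a in psbi_arms.items()},
        {c: a.n_treated for c, a in psbi_arms.items()},
    )
    weighted_staff = outpatient_psbi_weighted(
        {c: a.staff for c, a in psbi_arms.items()},
        {c: a.n_treated for c, a in psbi_arms.items()},
    )
    weighted_med = outpatient_psbi_weighted(
        {c: a.medicines for c, a in psbi_arms.items()},
        {c: a.n_treated for c, a in psbi_arms.items()},
    )
    outpatient_psbi = ArmCost(
        staff=weighted_staff,
        medicines=weighted_med,
        consumables=weighted_total - weighted_staff - weighted_med,
        n_treated=treated.psbi,
    )

    followup_n = _activity_units(
        register,
        ActivityId.FOLLOWUP,
        sum(i.followup_visits for i in register.infants if i.treatment_course is not None),
    )
    if ActivityId.FOLLOWUP in register.activity_coverage and followup_n:
        per_visit = _unit_staff_cost(register, ActivityId.FOLLOWUP)
        den = treated.psbi if options.denominator == "psbi_only" else treated.total
        followup = followup_cost_per_treated(followup_n, per_visit, den)
    else:
        followup = inr(0.0)

    operational, administrative = operational_cost_per_live_birth(
        register.operational,
        register.attribution,
        register.live_births,
        register.salaries.working_days_per_year,
    )

    return SiteCostReport(
        site_name=register.site_name,
        period=register.period,
        live_births=register.live_births,
        exchange_rate=register.exchange_rate_inr_per_usd,
        treated=treated,
        coverage=coverage_statistics(register),
        pre_outpatient_per_treated=pre_total,
        pre_outpatient_staff_per_treated=pre_staff,
        pre_outpatient_incentives_per_treated=pre_incentives,
        outpatient=outpatient,
        outpatient_psbi=outpatient_psbi,
        followup_per_treated=followup,
        operational_per_live_birth=operational,
        administrative_per_live_birth=administrative,
    )


def cross_site_summary(reports: List[SiteCostReport]) -> Dict[str, float]:
    """Treated-count-weighted USD averages across sites."""
    if not reports:
        raise CostkitError("no site reports to summarise")
    psbi_values = [r.usd(r.total_psbi) for r in reports]
    psbi_weights = [r.treated.psbi for r in reports]
    pneu_values = [r.usd(r.total_pneumonia) for r in reports]
    pneu_weights = [r.treated.pneumonia for r in reports]
    return {
        "weighted_total_psbi_per_treated": printed(
            cross_site_weighted_average(psbi_values, psbi_weights), 1
        ),
        "weighted_total_pneumonia_per_treated": printed(
            cross_site_weighted_average(pneu_values, pneu_weights), 1
        ),
        "treated_psbi": float(sum(psbi_weights)),
        "treated_pneumonia": float(sum(pneu_weights)),
    }
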