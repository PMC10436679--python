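"""Domain types for site registers, provider-time surveys and cost schedules.

The in-memory model mirrors what an implementation-research site keeps on
paper: a register of young infants (0-59 days) seen through postnatal home
visits and facility presentation, the provider-time survey for each program
activity, and the salary / price / incentive schedules needed to turn
activity counts into rupee costs.

Validation is pydantic-based so that a malformed register reports *every*
violation at once rather than failing on the first field.
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import MissingSalaryError, UnknownAttributionKeyError


class ProviderType(str, Enum):
    """Closed set of provider cadres appearing in the activity survey."""

    ASHA = "ASHA"
    ANM = "ANM"
    NURSE = "NURSE"
    MEDICAL_OFFICER = "MEDICAL_OFFICER"
    LHV = "LHV"
    ASHA_COORDINATOR = "ASHA_COORDINATOR"
    OTHER = "OTHER"


class ActivityId(str, Enum):
    """Program activities costed by the pipeline (Domains 1-3)."""

    POSTNATAL_VISIT = "POSTNATAL_VISIT"
    MOBILISATION = "MOBILISATION"
    ASSESSMENT = "ASSESSMENT"
    REFERRAL_COUNSELLING = "REFERRAL_COUNSELLING"
    PRE_REFERRAL_DOSE = "PRE_REFERRAL_DOSE"
    TREAT_PNEUMONIA = "TREAT_PNEUMONIA"
    TREAT_SEVERE_PNEUMONIA = "TREAT_SEVERE_PNEUMONIA"
    TREAT_CSI = "TREAT_CSI"
    FOLLOWUP = "FOLLOWUP"


class IMNCIClass(str, Enum):
    """Sign-based classification of a sick young infant.

    Precedence when signs from several classes co-occur:
    CRITICAL_ILLNESS > CLINICAL_SEVERE_INFECTION > SEVERE_PNEUMONIA /
    PNEUMONIA > NO_PSBI_SIGN.
    """

    PNEUMONIA = "PNEUMONIA"
    SEVERE_PNEUMONIA = "SEVERE_PNEUMONIA"
    CLINICAL_SEVERE_INFECTION = "CLINICAL_SEVERE_INFECTION"
    CRITICAL_ILLNESS = "CRITICAL_ILLNESS"
    NO_PSBI_SIGN = "NO_PSBI_SIGN"


#: PSBI subclasses that are costed as outpatient treatment arms. Critical
#: illness is excluded: injectable ampicillin was unavailable at primary
#: facilities, so those infants never received a categorisable regimen.
COSTED_PSBI_CLASSES = (IMNCIClass.SEVERE_PNEUMONIA, IMNCIClass.CLINICAL_SEVERE_INFECTION)


class TreatmentCategory(str, Enum):
    RECOMMENDED = "RECOMMENDED"
    ACCEPTABLE = "ACCEPTABLE"
    PARTIAL = "PARTIAL"
    NON_COMPLIANT = "NON_COMPLIANT"


class ClinicalSigns(BaseModel):
    """Signs assessed at presentation under the IMNCI algorithm."""

    model_config = ConfigDict(extra="forbid")

    respiratory_rate: int = Field(default=0, ge=0, le=250)
    temperature_c: float = Field(default=36.8, ge=25.0, le=45.0)
    stopped_feeding_well: bool = False
    severe_chest_indrawing: bool = False
    movement_only_when_stimulated: bool = False
    convulsions: bool = False
    no_movement_at_all: bool = False
    not_able_to_feed_at_all: bool = False


class TreatmentCourse(BaseModel):
    """Drugs, days and doses actually given to one infant as an outpatient.

    PSBI adherence is judged on *days* of gentamicin and amoxicillin;
    fast-breathing pneumonia adherence on amoxicillin *doses* (twice daily,
    14 doses for the full 7-day course).
    """

    model_config = ConfigDict(extra="forbid")

    target_class: IMNCIClass
    gentamicin_days: int = Field(default=0, ge=0)
    amoxicillin_days: int = Field(default=0, ge=0)
    amoxicillin_doses: int = Field(default=0, ge=0)
    other_antibiotics: List[str] = Field(default_factory=list)
    non_antibiotics_only: bool = False

    @model_validator(mode="after")
    def _consistent(self):
        if self.amoxicillin_doses > 2 * self.amoxicillin_days + 1:
            raise ValueError(
                f"amoxicillin_doses={self.amoxicillin_doses} exceeds twice-daily dosing "
                f"over amoxicillin_days={self.amoxicillin_days}"
            )
        if self.non_antibiotics_only and (
            self.gentamicin_days or self.amoxicillin_days
            or self.amoxicillin_doses or self.other_antibiotics
        ):
            raise ValueError("non_antibiotics_only course must have empty antibiotic fields")
        return self


class InfantRecord(BaseModel):
    """One register row: a young infant seen by the program in the site-year."""

    model_config = ConfigDict(extra="forbid")

    infant_id: str
    age_days_at_presentation: int = Field(ge=0, le=59)
    postnatal_visits: int = Field(default=0, ge=0, le=7)
    signs: ClinicalSigns = Field(default_factory=ClinicalSigns)
    mobilised_by_asha: bool = False
    referral_accepted: bool = False
    pre_referral_dose_given: bool = False
    treatment_course: Optional[TreatmentCourse] = None
    followup_visits: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _referral_logic(self):
        # Accepted referrals leave for hospital after the pre-referral dose;
        # an outpatient course can only belong to infants kept on site.
        if self.referral_accepted and self.treatment_course is not None:
            raise ValueError(
                f"infant {self.infant_id}: accepted referral cannot also carry an "
                "outpatient treatment_course"
            )
        return self


class CoverageRow(BaseModel):
    model_config = ConfigDict(extra="forbid")

    coverage_fraction: float = Field(ge=0.0, le=1.0)
    mean_minutes: float = Field(ge=0.0)

    @field_validator("mean_minutes")
    @classmethod
    def _finite(cls, v):
        if not math.isfinite(v):
            raise ValueError("mean_minutes must be finite")
        return v


class ActivityCoverage(BaseModel):
    """Provider mix for one activity: who attends, how often, for how long.

    Coverage fractions are *independent attendance probabilities* per
    provider and need not sum to one: a visit in which a medical officer
    sees 80% of infants and a nurse 90% counts both contributions, so the
    coverage-weighted time is 0.8x(MO minutes) + 0.9x(nurse minutes).
    ``n_units`` is the number of visits (or infants) the activity was
    delivered to in the site-year, taken from the site's own tally.
    """

    model_config = ConfigDict(extra="forbid")

    activity_id: ActivityId
    rows: Dict[ProviderType, CoverageRow]
    n_units: int = Field(default=0, ge=0)


class SalarySchedule(BaseModel):
    """Annual salaries per cadre plus the working-time convention.

    The per-minute rate is annual salary / (working days x working minutes);
    defaults of 240 days x 480 minutes follow the usual public-sector
    assumption. ASHAs are incentive-paid, not salaried: an ASHA salary entry
    is accepted with a warning but never used for staff costing.
    """

    model_config = ConfigDict(extra="forbid")

    annual_salary_inr: Dict[ProviderType, float] = Field(default_factory=dict)
    working_days_per_year: int = Field(default=240, gt=0)
    working_minutes_per_day: int = Field(default=480, gt=0)

    @model_validator(mode="after")
    def _check(self):
        for p, s in self.annual_salary_inr.items():
            if s <= 0:
                raise ValueError(f"annual salary for {p.value} must be positive, got {s}")
        if ProviderType.ASHA in self.annual_salary_inr:
            warnings.warn(
                "salary entry for ASHA is ignored: ASHA time is costed through "
                "incentives, not salary",
                stacklevel=2,
            )
        return self

    @property
    def working_minutes_per_year(self) -> int:
        return self.working_days_per_year * self.working_minutes_per_day

    def rate_per_minute(self, provider: ProviderType) -> float:
        if provider is ProviderType.ASHA:
            return 0.0
        try:
            annual = self.annual_salary_inr[provider]
        except KeyError:
            raise MissingSalaryError(provider.value) from None
        return annual / self.working_minutes_per_year


#: Default shares of shared program costs attributed to PSBI management.
DEFAULT_ATTRIBUTION = {
    "postnatal_incentive": 0.20,
    "consumables_general": 0.20,
    "mother_card": 1.00,
    "hbnc_kit_weighing_scale_annualised": 0.50,
    "iec_job_aids": 0.50,
    "school_rallies_super_village": 1.00,
    "asha_transport_per_diem": 0.10,
}


class AttributionFractions(BaseModel):
    """Item-keyed shares in [0, 1] of shared costs assigned to PSBI."""

    model_config = ConfigDict(extra="forbid")

    fractions: Dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ATTRIBUTION))

    @model_validator(mode="after")
    def _in_unit_interval(self):
        for k, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"attribution fraction for {k!r} must be in [0,1], got {f}")
        return self

    def get(self, item_key: str) -> float:
        try:
            return self.fractions[item_key]
        except KeyError:
            raise UnknownAttributionKeyError(item_key) from None


#: Commodity items a price list must be able to quote.
PRICE_ITEMS = (
    "amoxicillin_bottle_60ml",
    "gentamicin_per_administration",
    "syringe",
    "needle",
    "spirit",
    "cotton_swab",
    "mother_card",
    "referral_slip",
    "hbnc_kit",
    "weighing_scale",
)


class PriceList(BaseModel):
    """Unit prices (INR) for medicines and consumables.

    A ``None`` price means the item was not surveyed; any operation that
    needs it raises :class:`~costkit.errors.MissingPriceError` naming the
    item. ``hbnc_kit`` and ``weighing_scale`` are annualised per-item costs.
    """

    model_config = ConfigDict(extra="forbid")

    amoxicillin_bottle_60ml: Optional[float] = Field(default=None, ge=0)
    gentamicin_per_administration: Optional[float] = Field(default=None, ge=0)
    syringe: Optional[float] = Field(default=None, ge=0)
    needle: Optional[float] = Field(default=None, ge=0)
    spirit: Optional[float] = Field(default=None, ge=0)
    cotton_swab: Optional[float] = Field(default=None, ge=0)
    mother_card: Optional[float] = Field(default=None, ge=0)
    referral_slip: Optional[float] = Field(default=None, ge=0)
    hbnc_kit: Optional[float] = Field(default=None, ge=0)
    weighing_scale: Optional[float] = Field(default=None, ge=0)

    def require(self, item: str) -> float:
        v = getattr(self, item, None)
        if v is None:
            from .errors import MissingPriceError

            raise MissingPriceError(item)
        return v


class IncentiveSchedule(BaseModel):
    """ASHA incentive rules for postnatal visit completion and referral transport."""

    model_config = ConfigDict(extra="forbid")

    postnatal_full_inr: float = Field(default=250.0, ge=0)
    postnatal_half_inr: float = Field(default=125.0, ge=0)
    full_threshold_visits: int = Field(default=6, ge=0, le=7)
    half_range: Tuple[int, int] = (2, 5)
    referral_transport_inr: float = Field(default=100.0, ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.postnatal_half_inr > self.postnatal_full_inr:
            raise ValueError("half incentive cannot exceed full incentive")
        lo, hi = self.half_range
        if not (0 <= lo <= hi <= 7):
            raise ValueError(f"half_range must be within 0-7 and ordered, got {self.half_range}")
        return self


class AdminStaffRow(BaseModel):
    """One cadre's contribution to program management, supervision, coordination."""

    model_config = ConfigDict(extra="forbid")

    provider: ProviderType
    n_staff: int = Field(ge=0)
    day_fraction: float = Field(ge=0.0, le=1.0)
    days_per_year: int = Field(ge=0)
    annual_salary_inr: float = Field(gt=0)


class TrainingEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "training"
    n_trainees: int = Field(ge=0)
    n_days: int = Field(ge=0)
    trainer_honoraria_inr: float = Field(default=0.0, ge=0)
    per_diems_inr: float = Field(default=0.0, ge=0)
    materials_inr: float = Field(default=0.0, ge=0)
    rental_refreshments_inr: float = Field(default=0.0, ge=0)


class AnnualCostItem(BaseModel):
    model_config = ConfigDict(extra="forbid")

    item_key: str
    annual_cost_inr: float = Field(ge=0)


class OperationalInputs(BaseModel):
    """Indirect cost block: admin roster, trainings, IEC/demand generation."""

    model_config = ConfigDict(extra="forbid")

    admin_roster: List[AdminStaffRow] = Field(default_factory=list)
    training_events: List[TrainingEvent] = Field(default_factory=list)
    iec_items: List[AnnualCostItem] = Field(default_factory=list)
    site_specials: List[AnnualCostItem] = Field(default_factory=list)
    include_training_of_trainers: bool = False
    training_of_trainers_inr: float = Field(default=0.0, ge=0)


class SiteRegister(BaseModel):
    """Everything needed to cost one site-year of PSBI management."""

    model_config = ConfigDict(extra="forbid")

    site_name: str
    period: str
    live_births: int = Field(gt=0)
    exchange_rate_inr_per_usd: float = Field(default=68.5, gt=0)
    infants: List[InfantRecord] = Field(default_factory=list)
    activity_coverage: Dict[ActivityId, ActivityCoverage] = Field(default_factory=dict)
    salaries: SalarySchedule = Field(default_factory=SalarySchedule)
    prices: PriceList = Field(default_factory=PriceList)
    incentives: IncentiveSchedule = Field(default_factory=IncentiveSchedule)
    attribution: AttributionFractions = Field(default_factory=AttributionFractions)
    operational: OperationalInputs = Field(default_factory=OperationalInputs)
    #: shared supply pools (annual INR) entering pre-outpatient costs after
    #: attribution, keyed like the attribution table
    supply_pools: Dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _consistent(self):
        ids = [i.infant_id for i in self.infants]
        if len(set(ids)) != len(ids):
            raise ValueError("infant_id values must be unique within a register")
        for key, ac in self.activity_coverage.items():
            if ac.activity_id != key:
                raise ValueError(
                    f"activity_coverage key {key.value} does not match entry "
                    f"{ac.activity_id.value}"
                )
        for key, pool in self.supply_pools.items():
            if pool < 0:
                raise ValueError(f"supply pool {key!r} must be non-negative")
        return self

    def n_visited(self) -> int:
        """Infants that received at least one postnatal home visit."""
        return sum(1 for i in self.infants if i.postnatal_visits >= 1)
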