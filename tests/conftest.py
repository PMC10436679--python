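import pytest

from costkit.model import (
    ActivityCoverage,
    ActivityId,
    CoverageRow,
    IMNCIClass,
    PriceList,
    ProviderType,
    SalarySchedule,
    TreatmentCategory,
)
from costkit.report import cost_site
from costkit.sites import lucknow_register, palwal_register
from costkit.synthetic import SiteParams

A = ProviderType.ANM
N = ProviderType.NURSE
M = ProviderType.MEDICAL_OFFICER
ASHA = ProviderType.ASHA


def coverage(activity, rows, n_units=0):
    return ActivityCoverage(
        activity_id=activity,
        rows={
            p: CoverageRow(coverage_fraction=c, mean_minutes=m) for p, (c, m) in rows.items()
        },
        n_units=n_units,
    )


@pytest.fixture(scope="session")
def lucknow():
    return lucknow_register()


@pytest.fixture(scope="session")
def palwal():
    return palwal_register()


@pytest.fixture(scope="session")
def lucknow_report(lucknow):
    return cost_site(lucknow)


@pytest.fixture(scope="session")
def palwal_report(palwal):
    return cost_site(palwal)


def make_params(seed=0, live_births=12000, **overrides):
    """A mid-sized synthetic site with every activity present."""
    activity_minutes = {
        ActivityId.POSTNATAL_VISIT: {ASHA: (1.0, 20.0)},
        ActivityId.MOBILISATION: {ASHA: (1.0, 40.0)},
        ActivityId.ASSESSMENT: {A: (0.1, 15.0), N: (0.1, 5.0), M: (0.8, 9.0)},
        ActivityId.REFERRAL_COUNSELLING: {A: (0.1, 11.0), N: (0.1, 3.0), M: (0.8, 7.0)},
        ActivityId.PRE_REFERRAL_DOSE: {A: (0.1, 10.0), N: (0.1, 5.0), M: (0.8, 6.0)},
        ActivityId.TREAT_PNEUMONIA: {A: (0.1, 7.0), N: (0.9, 2.0), M: (0.3, 4.0)},
        ActivityId.TREAT_SEVERE_PNEUMONIA: {A: (0.1, 11.0), N: (0.1, 9.0), M: (0.9, 4.0)},
        ActivityId.TREAT_CSI: {A: (0.1, 6.0), N: (0.9, 3.0), M: (0.9, 4.0)},
        ActivityId.FOLLOWUP: {A: (0.1, 15.0), N: (0.9, 11.0), M: (0.3, 7.0)},
    }
    base = dict(
        site_name="synthetic",
        live_births=live_births,
        p_visited=0.8,
        visit_count_distribution=[0.1, 0.15, 0.15, 0.15, 0.15, 0.15, 0.15],
        p_identified_given_visited=0.06,
        sign_mix={
            IMNCIClass.PNEUMONIA: 0.2,
            IMNCIClass.SEVERE_PNEUMONIA: 0.05,
            IMNCIClass.CLINICAL_SEVERE_INFECTION: 0.7,
            IMNCIClass.CRITICAL_ILLNESS: 0.05,
        },
        p_mobilised_by_asha=0.5,
        p_referral_accepted=0.1,
        compliance_mix_psbi={
            TreatmentCategory.RECOMMENDED: 0.4,
            TreatmentCategory.ACCEPTABLE: 0.2,
            TreatmentCategory.PARTIAL: 0.3,
            TreatmentCategory.NON_COMPLIANT: 0.1,
        },
        compliance_mix_pneumonia={
            TreatmentCategory.RECOMMENDED: 0.8,
            TreatmentCategory.ACCEPTABLE: 0.2,
            TreatmentCategory.PARTIAL: 0.0,
            TreatmentCategory.NON_COMPLIANT: 0.0,
        },
        followup_visits_distribution=[0.1, 0.4, 0.5],
        activity_minutes=activity_minutes,
        salaries=SalarySchedule(
            annual_salary_inr={A: 240_000.0, N: 380_000.0, M: 640_000.0}
        ),
        prices=PriceList(
            amoxicillin_bottle_60ml=13.7,
            gentamicin_per_administration=13.5,
            syringe=10.0,
            needle=4.0,
            spirit=3.0,
            cotton_swab=3.0,
            mother_card=3.0,
            referral_slip=2.0,
        ),
        supply_pools={"hbnc_kit_weighing_scale_annualised": 30_000.0},
        seed=seed,
    )
    base.update(overrides)
    return SiteParams.model_validate(base)
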