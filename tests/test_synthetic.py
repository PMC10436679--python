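"""Synthetic register generator: determinism, schema validity, degenerate
limits and parameter recovery against the closed-form expectation."""

import math

import numpy as np
import pytest

from costkit.model import IMNCIClass, TreatmentCategory
from costkit.report import cost_site, count_treated
from costkit.synthetic import expected_costs, generate_site, report_lines_inr
from tests.conftest import make_params

CSI = IMNCIClass.CLINICAL_SEVERE_INFECTION


def test_generator_is_seed_deterministic():
    params = make_params(seed=11, live_births=1500)
    a = generate_site(params)
    b = generate_site(params)
    assert a.model_dump() == b.model_dump()
    c = generate_site(params, seed=12)
    assert c.model_dump() != a.model_dump()


def test_generated_register_is_schema_valid_and_consistent():
    reg = generate_site(make_params(seed=5, live_births=2000))
    assert reg.n_visited() <= reg.live_births
    assert all(0 <= i.postnatal_visits <= 7 for i in reg.infants)
    for i in reg.infants:
        if i.referral_accepted:
            assert i.treatment_course is None


def test_degenerate_compliance_all_recommended():
    """With a point mass at RECOMMENDED and no referrals accepted, every
    coursed infant counts as treated."""
    params = make_params(
        seed=2,
        live_births=1200,
        p_referral_accepted=0.0,
        sign_mix={
            IMNCIClass.PNEUMONIA: 0.3,
            IMNCIClass.SEVERE_PNEUMONIA: 0.1,
            CSI: 0.6,
            IMNCIClass.CRITICAL_ILLNESS: 0.0,
        },
        compliance_mix_psbi={TreatmentCategory.RECOMMENDED: 1.0,
                             TreatmentCategory.ACCEPTABLE: 0.0,
                             TreatmentCategory.PARTIAL: 0.0,
                             TreatmentCategory.NON_COMPLIANT: 0.0},
        compliance_mix_pneumonia={TreatmentCategory.RECOMMENDED: 1.0,
                                  TreatmentCategory.ACCEPTABLE: 0.0,
                                  TreatmentCategory.PARTIAL: 0.0,
                                  TreatmentCategory.NON_COMPLIANT: 0.0},
    )
    reg = generate_site(params)
    coursed = sum(1 for i in reg.infants if i.treatment_course is not None)
    assert count_treated(reg).total == coursed


def test_deterministic_limit_matches_closed_form_exactly():
    """With all probabilities 0/1 and a point-mass visit distribution the
    pipeline equals the expectation to rounding error."""
    params = make_params(
        seed=9,
        live_births=500,
        p_visited=1.0,
        visit_count_distribution=[0, 0, 0, 0, 0, 0, 1.0],
        p_identified_given_visited=1.0,
        sign_mix={IMNCIClass.PNEUMONIA: 0.0, IMNCIClass.SEVERE_PNEUMONIA: 0.0,
                  CSI: 1.0, IMNCIClass.CRITICAL_ILLNESS: 0.0},
        p_mobilised_by_asha=1.0,
        p_referral_accepted=0.0,
        compliance_mix_psbi={TreatmentCategory.RECOMMENDED: 1.0,
                             TreatmentCategory.ACCEPTABLE: 0.0,
                             TreatmentCategory.PARTIAL: 0.0,
                             TreatmentCategory.NON_COMPLIANT: 0.0},
        compliance_mix_pneumonia={TreatmentCategory.RECOMMENDED: 1.0,
                                  TreatmentCategory.ACCEPTABLE: 0.0,
                                  TreatmentCategory.PARTIAL: 0.0,
                                  TreatmentCategory.NON_COMPLIANT: 0.0},
        followup_visits_distribution=[0.0, 0.0, 1.0],
    )
    got = report_lines_inr(cost_site(generate_site(params)))
    exp = expected_costs(params)
    for key, e in exp.items():
        assert got[key] == pytest.approx(e, rel=1e-9, abs=1e-9), key


def test_zero_prices_and_salaries_leave_only_incentives():
    """With all prices zero and only unsalaried (incentive-paid) providers,
    every cost line except the incentive block vanishes."""
    from costkit.model import ActivityId, PriceList, ProviderType, SalarySchedule

    asha_only = {
        act: {ProviderType.ASHA: (1.0, 10.0)}
        for act in ActivityId
    }
    params = make_params(
        seed=4,
        live_births=3000,
        activity_minutes=asha_only,
        salaries=SalarySchedule(annual_salary_inr={}),
        prices=PriceList(**{k: 0.0 for k in (
            "amoxicillin_bottle_60ml", "gentamicin_per_administration", "syringe",
            "needle", "spirit", "cotton_swab", "mother_card", "referral_slip")}),
        supply_pools={},
    )
    reg = generate_site(params)
    report = cost_site(reg)
    assert report.pre_outpatient_staff_per_treated.amount == 0.0
    assert report.outpatient_psbi.medicines.amount == 0.0
    assert report.pre_outpatient_incentives_per_treated.amount > 0.0


def test_parameter_recovery_twenty_seeds():
    """Every deterministic report line from the pipeline on a generated
    register lies within three standard errors of the closed form, for 20
    random parameter draws from a fixed master seed.

    The standard error of each per-treated line is approximated by its
    value times the coefficient of variation of a mean over the treated
    infants, cv <= 1.5/sqrt(n_treated)."""
    master = np.random.default_rng(20190228)
    for draw in range(20):
        params = make_params(
            seed=int(master.integers(2**31)),
            live_births=6000,
            p_visited=float(master.uniform(0.5, 0.95)),
            p_identified_given_visited=float(master.uniform(0.04, 0.10)),
            p_mobilised_by_asha=float(master.uniform(0.2, 0.8)),
            p_referral_accepted=float(master.uniform(0.0, 0.2)),
        )
        exp = expected_costs(params)
        got = report_lines_inr(cost_site(generate_site(params)))
        n_min = min(exp["treated_psbi"], exp["treated_pneumonia"])
        tol = 3 * 1.5 / math.sqrt(n_min)
        for key, e in exp.items():
            if e == 0:
                assert got[key] == pytest.approx(0.0, abs=1e-9)
                continue
            rel = abs(got[key] - e) / abs(e)
            assert rel <= tol, (draw, key, rel, tol)
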