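"""Report assembly: treated counts, weighted averages, totals, incrementals,
coverage statistics and the additivity invariants on the site fixtures."""

import pytest

from costkit.errors import CostkitError, CurrencyError
from costkit.model import IMNCIClass, SiteRegister
from costkit.money import inr, printed, to_usd, usd
from costkit.report import (
    count_treated,
    coverage_statistics,
    cross_site_summary,
    cross_site_weighted_average,
    followup_cost_per_treated,
    incremental_cost,
    outpatient_psbi_weighted,
    staff_share,
    total_cost_per_treated,
)

SP = IMNCIClass.SEVERE_PNEUMONIA
CSI = IMNCIClass.CLINICAL_SEVERE_INFECTION


def test_treated_counts_on_site_fixtures(palwal, lucknow):
    pw = count_treated(palwal)
    assert (pw.psbi, pw.pneumonia) == (67, 22)
    lk = count_treated(lucknow)
    assert (lk.psbi, lk.pneumonia) == (208, 94)
    assert lk.by_class[SP] == 17
    assert lk.by_class[CSI] == 191


def test_empty_register_counts_zero():
    reg = SiteRegister(site_name="x", period="p", live_births=10)
    counts = count_treated(reg)
    assert (counts.psbi, counts.pneumonia, counts.total) == (0, 0, 0)


def test_psbi_weighted_average_staff_example():
    """Subclass staff costs 6.5 (n=17) and 5.6 (n=191) average to 5.7."""
    out = outpatient_psbi_weighted(
        {SP: usd(6.5), CSI: usd(5.6)}, {SP: 17, CSI: 191}
    )
    assert printed(out.amount, 1) == 5.7


def test_psbi_weighted_identity_and_invariance():
    assert outpatient_psbi_weighted({CSI: usd(6.5)}, {CSI: 191}).amount == 6.5
    both = outpatient_psbi_weighted({SP: usd(4.0), CSI: usd(4.0)}, {SP: 3, CSI: 500})
    assert both.amount == pytest.approx(4.0)
    with pytest.raises(CostkitError):
        outpatient_psbi_weighted({SP: usd(1.0)}, {SP: 0})


def test_followup_cost_spreads_over_treated():
    assert followup_cost_per_treated(204, inr(50.0), 89).amount == pytest.approx(
        204 * 50.0 / 89
    )
    assert followup_cost_per_treated(0, inr(50.0), 89).amount == 0.0
    assert followup_cost_per_treated(1, inr(7.0), 1).amount == 7.0
    with pytest.raises(CostkitError):
        followup_cost_per_treated(10, inr(50.0), 0)


def test_total_cost_addition_examples():
    assert printed(total_cost_per_treated(usd(13.6), usd(1.8)).amount, 1) == 15.4
    assert printed(total_cost_per_treated(usd(7.9), usd(1.8)).amount, 1) == 9.7
    assert total_cost_per_treated(usd(5.0), usd(0.0)).amount == 5.0
    with pytest.raises(CurrencyError):
        total_cost_per_treated(usd(5.0), inr(10.0))


def test_incremental_cost_and_reconstruction():
    total, staff = usd(15.4), usd(11.1)
    inc = incremental_cost(total, staff)
    assert printed(inc.amount, 1) == 4.3
    assert (inc + staff).amount == pytest.approx(total.amount)
    assert incremental_cost(total, usd(0.0)).amount == total.amount
    with pytest.raises(CostkitError):
        incremental_cost(usd(5.0), usd(6.0))


def test_cross_site_weighted_average_examples():
    assert printed(cross_site_weighted_average([11.8, 9.7], [22, 94]), 1) == 10.1
    psbi = cross_site_weighted_average([17.2, 15.4], [67, 208])
    assert printed(psbi, 1) == 15.8
    assert printed(psbi, 0) == 16.0
    assert cross_site_weighted_average([usd(5.0), usd(5.0)], [10, 90]).amount == 5.0
    with pytest.raises(CostkitError):
        cross_site_weighted_average([1.0], [1, 2])
    with pytest.raises(CostkitError):
        cross_site_weighted_average([1.0, 2.0], [0, 0])


def test_weighted_average_bounded_by_inputs():
    lo, hi = 9.7, 11.8
    avg = cross_site_weighted_average([hi, lo], [22, 94])
    assert lo <= avg <= hi


def test_coverage_statistics_on_fixtures(palwal, lucknow):
    pw = coverage_statistics(palwal)
    assert pw["visited_pct"] == 54.0
    assert pw["identified_pct"] == 5.9
    assert pw["psbi_rec_acc_pct"] == 59.0
    assert pw["complete_visit_pct"] == 39.0
    lk = coverage_statistics(lucknow)
    assert lk["visited_pct"] == 87.0
    assert lk["identified_pct"] == 5.1
    assert lk["psbi_rec_acc_pct"] == 40.0
    assert lk["complete_visit_pct"] == 17.0


def test_zero_denominator_omits_statistic_with_warning():
    reg = SiteRegister(site_name="x", period="p", live_births=5)
    with pytest.warns(UserWarning):
        stats = coverage_statistics(reg)
    assert "identified_pct" not in stats


@pytest.mark.parametrize("fixture", ["palwal_report", "lucknow_report"])
def test_direct_cost_additivity_at_printed_precision(fixture, request):
    """Each printed total equals the sum of its printed components to within
    one unit in the last place per component."""
    r = request.getfixturevalue(fixture)
    t = r.usd_table()
    assert t["direct_psbi_per_treated"] == pytest.approx(
        t["pre_outpatient_per_treated"]
        + t["outpatient_psbi_per_treated"]
        + t["followup_per_treated"],
        abs=0.3,
    )
    assert t["op_admin_per_live_birth"] == pytest.approx(
        t["operational_per_live_birth"] + t["administrative_per_live_birth"], abs=0.2
    )
    assert t["total_psbi_per_treated"] == pytest.approx(
        t["direct_psbi_per_treated"] + t["op_admin_per_live_birth"], abs=0.2
    )
    assert t["total_pneumonia_per_treated"] == pytest.approx(
        t["direct_pneumonia_per_treated"] + t["op_admin_per_live_birth"], abs=0.2
    )


@pytest.mark.parametrize("fixture", ["palwal_report", "lucknow_report"])
def test_incremental_plus_staff_reconstructs_total(fixture, request):
    r = request.getfixturevalue(fixture)
    for arm in ("psbi", "pneumonia"):
        total = getattr(r, f"total_{arm}")
        inc = getattr(r, f"incremental_{arm}")
        assert inc.amount + r.staff_components(arm).amount == pytest.approx(total.amount)


def test_lucknow_calibrated_cells_match_published_column(lucknow_report):
    """The feasible cells of the published Lucknow cost column are
    reproduced end-to-end by the pipeline on the calibrated register."""
    t = lucknow_report.usd_table()
    assert t["outpatient_pneumonia_per_treated"] == 0.9
    assert t["outpatient_psbi_per_treated"] == 6.6
    assert t["followup_per_treated"] == 2.5
    assert t["operational_per_live_birth"] == 0.6
    assert t["administrative_per_live_birth"] == 1.2
    assert t["op_admin_per_live_birth"] == 1.8


def test_palwal_calibrated_cells(palwal_report):
    t = palwal_report.usd_table()
    assert t["outpatient_pneumonia_per_treated"] == 0.6
    assert t["operational_per_live_birth"] == 1.6
    assert t["administrative_per_live_birth"] == 2.6
    assert t["op_admin_per_live_birth"] == 4.3


def test_currency_discipline_convert_once(lucknow_report):
    """Aggregating in INR then converting differs from converting each
    component first by at most one unit in the last printed place."""
    r = lucknow_report
    agg_then_convert = r.usd(r.direct_psbi)
    convert_then_agg = (
        to_usd(r.pre_outpatient_per_treated, r.exchange_rate, 1).amount
        + to_usd(r.outpatient_psbi.total, r.exchange_rate, 1).amount
        + to_usd(r.followup_per_treated, r.exchange_rate, 1).amount
    )
    assert abs(agg_then_convert - printed(convert_then_agg, 1)) <= 0.3


def test_cross_site_summary_weights_by_treated(palwal_report, lucknow_report):
    summary = cross_site_summary([palwal_report, lucknow_report])
    pw, lk = palwal_report, lucknow_report
    expected = cross_site_weighted_average(
        [pw.usd(pw.total_psbi), lk.usd(lk.total_psbi)], [67, 208]
    )
    assert summary["weighted_total_psbi_per_treated"] == printed(expected, 1)
    assert summary["treated_psbi"] == 275
    assert summary["treated_pneumonia"] == 116


def test_staff_share_identity():
    assert printed(100 * staff_share(usd(15.4), usd(4.3)), 0) == 72.0
    with pytest.raises(CostkitError):
        staff_share(usd(0.0), usd(0.0))
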