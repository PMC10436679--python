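"""Coverage-weighted provider time, and what it costs in salaries.

When several cadres each see a share of infants, the expected time per
infant is the sum of (coverage x minutes) over cadres.
"""

from costkit import SalarySchedule, average_time_per_infant, staff_cost_per_infant
from costkit.model import ActivityCoverage, ActivityId, CoverageRow, ProviderType

M, N = ProviderType.MEDICAL_OFFICER, ProviderType.NURSE

assessment = ActivityCoverage(
    activity_id=ActivityId.ASSESSMENT,
    rows={
        M: CoverageRow(coverage_fraction=0.80, mean_minutes=10),
        N: CoverageRow(coverage_fraction=0.20, mean_minutes=15),
    },
)
total, per = average_time_per_infant(assessment)
print(f"assessment: {total:.0f} minutes per infant "
      f"(MO {per[M]:.0f}, nurse {per[N]:.0f})")

treatment = ActivityCoverage(
    activity_id=ActivityId.TREAT_CSI,
    rows={
        M: CoverageRow(coverage_fraction=0.80, mean_minutes=5),
        N: CoverageRow(coverage_fraction=0.90, mean_minutes=10),
    },
)
total, per = average_time_per_infant(treatment)
print(f"treatment:  {total:.0f} minutes per infant "
      f"(MO {per[M]:.0f}, nurse {per[N]:.0f})")

# price that time: salaries chosen so MO costs ₹3/min and nurse ₹1/min
salaries = SalarySchedule(annual_salary_inr={M: 3 * 240 * 480, N: 1 * 240 * 480})
cost = staff_cost_per_infant(assessment, salaries)
print(f"assessment staff cost at those salaries: {cost}")
# Expected output: 11 and 13 minutes — each cadre's share of visits times
# its minutes — and ₹27 = 8 MO-min x ₹3 + 3 nurse-min x ₹1.
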