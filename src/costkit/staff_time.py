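"""Coverage-weighted provider time and staff cost per infant per activity.

Each activity's provider mix states, per cadre, the share of visits that
cadre attends and its mean minutes per visit. Because providers attend
independently (a visit may involve both a nurse and a medical officer, each
up to 100% of visits), the expected time an infant receives is the sum of
coverage x minutes over providers — e.g. a medical officer assessing 80% of
infants for 10 minutes and a nurse 20% for 15 minutes yields 8 + 3 = 11
minutes per infant assessed.

Staff cost prices that time at each cadre's per-minute salary. ASHA time is
deliberately costed at zero here: ASHAs are paid through incentives
(handled in :mod:`costkit.commodities`), not salaries.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .errors import CostkitError
from .model import ActivityCoverage, ProviderType, SalarySchedule
from .money import Money, inr


def average_time_per_infant(
    activity: ActivityCoverage,
) -> Tuple[float, Dict[ProviderType, float]]:
    """Expected provider minutes per infant receiving ``activity``.

    Returns the total and the per-provider contributions
    (coverage_fraction x mean_minutes for each cadre).
    """
    if not activity.rows:
        raise CostkitError(
            f"activity {activity.activity_id.value} has no provider rows"
        )
    per_provider = {
        p: row.coverage_fraction * row.mean_minutes for p, row in activity.rows.items()
    }
    return sum(per_provider.values()), per_provider


def staff_cost_per_infant(
    activity: ActivityCoverage, salaries: SalarySchedule
) -> Money:
    """Expected salary cost (INR) per infant receiving ``activity``.

    Sum over providers of coverage x minutes x per-minute rate. ASHA rows
    contribute time but zero salary cost. A salaried provider without a
    salary entry raises :class:`~costkit.errors.MissingSalaryError`.
    """
    _, per_provider = average_time_per_infant(activity)
    total = 0.0
    for provider, minutes in per_provider.items():
        if minutes == 0.0 and provider not in salaries.annual_salary_inr:
            continue  # zero-coverage rows need no salary entry
        total += minutes * salaries.rate_per_minute(provider)
    return inr(total)


def total_activity_staff_cost(
    activity: ActivityCoverage, salaries: SalarySchedule
) -> Money:
    """Site-year staff cost of an activity: per-infant cost x units delivered."""
    return staff_cost_per_infant(activity, salaries) * activity.n_units
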