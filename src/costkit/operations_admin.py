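"""Indirect cost block: administrative staff FTE, training, IEC / demand generation.

These costs benefit every newborn in the catchment rather than a specific
treated infant, so they are expressed per live birth. Administrative staff
time is costed as full-time equivalents: staff count x share of the working
day x share of working days in the year x annual salary. Training is costed
from its components (trainer honoraria, trainee per diems, materials,
venue/refreshments) and summarised per trainee-day. Training of trainers is
a startup cost, excluded by default.
"""

from __future__ import annotations

from typing import Iterable, Tuple

from .errors import CostkitError, MissingSalaryError  # noqa: F401  (re-export context)
from .model import AdminStaffRow, AttributionFractions, OperationalInputs, TrainingEvent
from .money import Money, inr


def admin_staff_cost(
    roster: Iterable[AdminStaffRow], working_days_per_year: int = 240
) -> Money:
    """Annual INR cost of administrative / supervisory staff time.

    Each row contributes n_staff x day_fraction x (days_per_year /
    working_days_per_year) x annual salary.
    """
    total = 0.0
    for row in roster:
        fte = row.n_staff * row.day_fraction * (row.days_per_year / working_days_per_year)
        total += fte * row.annual_salary_inr
    return inr(total)


def training_cost(event: TrainingEvent) -> Tuple[Money, Money]:
    """(total, per-trainee-day) cost of one training event."""
    total = (
        event.trainer_honoraria_inr
        + event.per_diems_inr
        + event.materials_inr
        + event.rental_refreshments_inr
    )
    trainee_days = event.n_trainees * event.n_days
    if trainee_days == 0:
        if total > 0:
            raise CostkitError(
                f"training event {event.name!r} has costs but zero trainee-days"
            )
        return inr(0.0), inr(0.0)
    return inr(total), inr(total / trainee_days)


def operational_cost_per_live_birth(
    inputs: OperationalInputs,
    fractions: AttributionFractions,
    live_births: int,
    working_days_per_year: int = 240,
) -> Tuple[Money, Money]:
    """(operational, administrative) INR cost per live birth.

    Operational = trainings + attributed IEC/job-aid items + attributed
    site-special items (school rallies, supervision per diems, ...), spread
    over live births. Administrative = the FTE-costed admin roster per live
    birth. The two are reported separately and summed downstream.
    """
    if live_births <= 0:
        raise CostkitError(f"live_births must be positive, got {live_births}")
    operational = 0.0
    for ev in inputs.training_events:
        total, _ = training_cost(ev)
        operational += total.amount
    if inputs.include_training_of_trainers:
        operational += inputs.training_of_trainers_inr
    for item in inputs.iec_items:
        operational += item.annual_cost_inr * fractions.get(item.item_key)
    for item in inputs.site_specials:
        operational += item.annual_cost_inr * fractions.get(item.item_key)
    administrative = admin_staff_cost(inputs.admin_roster, working_days_per_year)
    return inr(operational / live_births), administrative / live_births
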