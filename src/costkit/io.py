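"""Reading and writing site registers as a directory of CSV + YAML files.

Canonical layout (schema version 1)::

    <register>/
      site.yaml               site name, period, live births, exchange rate,
                              incentive schedule, attribution fractions,
                              salary schedule, operational inputs, supply pools
      infants.csv             one row per infant record
      activity_coverage.csv   activity_id, provider, coverage_fraction,
                              mean_minutes, n_units
      prices.csv              item, unit_price_inr, unit_basis

Booleans are written as 0/1; the ``other_antibiotics`` list is
semicolon-joined. Loading validates everything and reports *all*
violations; a register is never partially loaded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .errors import RegisterParseError, RegisterValidationError
from .model import (
    ActivityCoverage,
    ActivityId,
    AdminStaffRow,
    AnnualCostItem,
    AttributionFractions,
    ClinicalSigns,
    CoverageRow,
    IMNCIClass,
    IncentiveSchedule,
    InfantRecord,
    OperationalInputs,
    PRICE_ITEMS,
    PriceList,
    ProviderType,
    SalarySchedule,
    SiteRegister,
    TrainingEvent,
    TreatmentCourse,
)

SCHEMA_VERSION = "1"

_SIGN_FIELDS = list(ClinicalSigns.model_fields)
_COURSE_FIELDS = [
    "target_class",
    "gentamicin_days",
    "amoxicillin_days",
    "amoxicillin_doses",
    "other_antibiotics",
    "non_antibiotics_only",
]
_BOOL_FIELDS = [
    "stopped_feeding_well",
    "severe_chest_indrawing",
    "movement_only_when_stimulated",
    "convulsions",
    "no_movement_at_all",
    "not_able_to_feed_at_all",
    "mobilised_by_asha",
    "referral_accepted",
    "pre_referral_dose_given",
    "non_antibiotics_only",
]

_UNIT_BASIS = {
    "amoxicillin_bottle_60ml": "per_bottle",
    "gentamicin_per_administration": "per_administration",
    "hbnc_kit": "per_annualised_item",
    "weighing_scale": "per_annualised_item",
}


def _fmt_pydantic(prefix: str, exc: ValidationError) -> List[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{prefix}: {loc}: {err['msg']}")
    return out


def _infant_from_row(idx: int, row: pd.Series, violations: List[str]):
    data: Dict = {}
    try:
        signs = {
            f: (bool(int(row[f])) if f in _BOOL_FIELDS else row[f])
            for f in _SIGN_FIELDS
        }
        course = None
        if int(row.get("has_course", 0)):
            raw_abx = row.get("other_antibiotics", "")
            abx = "" if pd.isna(raw_abx) else str(raw_abx)
            course = {
                "target_class": IMNCIClass(row["target_class"]),
                "gentamicin_days": int(row["gentamicin_days"]),
                "amoxicillin_days": int(row["amoxicillin_days"]),
                "amoxicillin_doses": int(row["amoxicillin_doses"]),
                "other_antibiotics": [a for a in abx.split(";") if a],
                "non_antibiotics_only": bool(int(row["non_antibiotics_only"])),
            }
        data = {
            "infant_id": str(row["infant_id"]),
            "age_days_at_presentation": int(row["age_days_at_presentation"]),
            "postnatal_visits": int(row["postnatal_visits"]),
            "signs": signs,
            "mobilised_by_asha": bool(int(row["mobilised_by_asha"])),
            "referral_accepted": bool(int(row["referral_accepted"])),
            "pre_referral_dose_given": bool(int(row["pre_referral_dose_given"])),
            "treatment_course": course,
            "followup_visits": int(row["followup_visits"]),
        }
    except (KeyError, ValueError, TypeError) as exc:
        violations.append(f"infants.csv row {idx}: {exc}")
        return None
    try:
        return InfantRecord.model_validate(data)
    except ValidationError as exc:
        violations.extend(_fmt_pydantic(f"infants.csv row {idx}", exc))
        return None


def load_site_register(path: Union[str, Path], schema_version: str = SCHEMA_VERSION) -> SiteRegister:
    """Load and fully validate a register directory.

    Raises :class:`RegisterParseError` for malformed files (naming the file
    and field) and :class:`RegisterValidationError` carrying every
    invariant violation found.
    """
    if schema_version != SCHEMA_VERSION:
        raise RegisterParseError(f"unsupported schema version {schema_version!r}")
    root = Path(path)
    if not root.is_dir():
        raise RegisterParseError(f"register directory {root} does not exist")

    def read_csv(name: str, required: List[str]) -> pd.DataFrame:
        f = root / name
        if not f.exists():
            raise RegisterParseError(f"{name}: file missing from register directory")
        try:
            df = pd.read_csv(f)
        except Exception as exc:  # malformed CSV
            raise RegisterParseError(f"{name}: {exc}") from exc
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise RegisterParseError(f"{name}: missing column(s) {', '.join(missing)}")
        return df

    cfg_file = root / "site.yaml"
    if not cfg_file.exists():
        raise RegisterParseError("site.yaml: file missing from register directory")
    try:
        cfg = yaml.safe_load(cfg_file.read_text()) or {}
    except yaml.YAMLError as exc:
        raise RegisterParseError(f"site.yaml: {exc}") from exc

    violations: List[str] = []

    infants_df = read_csv(
        "infants.csv",
        ["infant_id", "age_days_at_presentation", "postnatal_visits", "followup_visits"],
    )
    infants = []
    for idx, row in infants_df.iterrows():
        rec = _infant_from_row(int(idx) + 2, row, violations)  # +2: header + 1-basing
        if rec is not None:
            infants.append(rec)

    cov_df = read_csv(
        "activity_coverage.csv",
        ["activity_id", "provider", "coverage_fraction", "mean_minutes", "n_units"],
    )
    coverage: Dict[ActivityId, ActivityCoverage] = {}
    for act_name, group in cov_df.groupby("activity_id", sort=False):
        try:
            act = ActivityId(act_name)
            rows = {
                ProviderType(r["provider"]): CoverageRow(
                    coverage_fraction=float(r["coverage_fraction"]),
                    mean_minutes=float(r["mean_minutes"]),
                )
                for _, r in group.iterrows()
            }
            coverage[act] = ActivityCoverage(
                activity_id=act, rows=rows, n_units=int(group["n_units"].iloc[0])
            )
        except (ValueError, ValidationError) as exc:
            if isinstance(exc, ValidationError):
                violations.extend(_fmt_pydantic(f"activity_coverage.csv [{act_name}]", exc))
            else:
                violations.append(f"activity_coverage.csv [{act_name}]: {exc}")

    prices_df = read_csv("prices.csv", ["item", "unit_price_inr"])
    price_kwargs = {}
    for _, r in prices_df.iterrows():
        item = str(r["item"])
        if item not in PRICE_ITEMS:
            violations.append(f"prices.csv: unknown item {item!r}")
            continue
        price_kwargs[item] = float(r["unit_price_inr"])

    def section(name, model, default):
        raw = cfg.get(name)
        if raw is None:
            return default()
        try:
            return model.model_validate(raw)
        except ValidationError as exc:
            violations.extend(_fmt_pydantic(f"site.yaml [{name}]", exc))
            return default()

    salaries_raw = cfg.get("salaries", {})
    try:
        salaries = SalarySchedule(
            annual_salary_inr={
                ProviderType(k): float(v)
                for k, v in (salaries_raw.get("annual_salary_inr") or {}).items()
            },
            working_days_per_year=int(salaries_raw.get("working_days_per_year", 240)),
            working_minutes_per_day=int(salaries_raw.get("working_minutes_per_day", 480)),
        )
    except (ValueError, ValidationError) as exc:
        salaries = SalarySchedule()
        if isinstance(exc, ValidationError):
            violations.extend(_fmt_pydantic("site.yaml [salaries]", exc))
        else:
            violations.append(f"site.yaml [salaries]: {exc}")

    incentives = section("incentives", IncentiveSchedule, IncentiveSchedule)
    attribution = section("attribution", AttributionFractions, AttributionFractions)
    operational = section("operational", OperationalInputs, OperationalInputs)

    try:
        prices = PriceList.model_validate(price_kwargs)
    except ValidationError as exc:
        prices = PriceList()
        violations.extend(_fmt_pydantic("prices.csv", exc))

    register = None
    try:
        register = SiteRegister(
            site_name=str(cfg.get("site_name", root.name)),
            period=str(cfg.get("period", "")),
            live_births=int(cfg.get("live_births", 0)),
            exchange_rate_inr_per_usd=float(cfg.get("exchange_rate_inr_per_usd", 68.5)),
            infants=infants,
            activity_coverage=coverage,
            salaries=salaries,
            prices=prices,
            incentives=incentives,
            attribution=attribution,
            operational=operational,
            supply_pools={k: float(v) for k, v in (cfg.get("supply_pools") or {}).items()},
        )
    except (ValueError, TypeError) as exc:
        violations.append(f"site.yaml: {exc}")
    except ValidationError as exc:
        violations.extend(_fmt_pydantic("site.yaml", exc))

    if violations:
        raise RegisterValidationError(violations)
    assert register is not None
    return register


def write_site_register(register: SiteRegister, path: Union[str, Path]) -> Path:
    """Write a register to a directory in the canonical layout."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in register.infants:
        row = {
            "infant_id": i.infant_id,
            "age_days_at_presentation": i.age_days_at_presentation,
            "postnatal_visits": i.postnatal_visits,
            **{
                f: (int(v) if isinstance(v, bool) else v)
                for f, v in i.signs.model_dump().items()
            },
            "mobilised_by_asha": int(i.mobilised_by_asha),
            "referral_accepted": int(i.referral_accepted),
            "pre_referral_dose_given": int(i.pre_referral_dose_given),
            "has_course": int(i.treatment_course is not None),
            "target_class": "",
            "gentamicin_days": 0,
            "amoxicillin_days": 0,
            "amoxicillin_doses": 0,
            "other_antibiotics": "",
            "non_antibiotics_only": 0,
            "followup_visits": i.followup_visits,
        }
        if i.treatment_course is not None:
            c = i.treatment_course
            row.update(
                target_class=c.target_class.value,
                gentamicin_days=c.gentamicin_days,
                amoxicillin_days=c.amoxicillin_days,
                amoxicillin_doses=c.amoxicillin_doses,
                other_antibiotics=";".join(c.other_antibiotics),
                non_antibiotics_only=int(c.non_antibiotics_only),
            )
        rows.append(row)
    infant_cols = (
        ["infant_id", "age_days_at_presentation", "postnatal_visits"]
        + _SIGN_FIELDS
        + [
            "mobilised_by_asha", "referral_accepted", "pre_referral_dose_given",
            "has_course", "target_class", "gentamicin_days", "amoxicillin_days",
            "amoxicillin_doses", "other_antibiotics", "non_antibiotics_only",
            "followup_visits",
        ]
    )
    pd.DataFrame(rows, columns=infant_cols).to_csv(root / "infants.csv", index=False)

    cov_rows = [
        {
            "activity_id": ac.activity_id.value,
            "provider": p.value,
            "coverage_fraction": r.coverage_fraction,
            "mean_minutes": r.mean_minutes,
            "n_units": ac.n_units,
        }
        for ac in register.activity_coverage.values()
        for p, r in ac.rows.items()
    ]
    pd.DataFrame(
        cov_rows,
        columns=["activity_id", "provider", "coverage_fraction", "mean_minutes", "n_units"],
    ).to_csv(root / "activity_coverage.csv", index=False)

    price_rows = [
        {
            "item": item,
            "unit_price_inr": getattr(register.prices, item),
            "unit_basis": _UNIT_BASIS.get(item, "per_item"),
        }
        for item in PRICE_ITEMS
        if getattr(register.prices, item) is not None
    ]
    pd.DataFrame(
        price_rows, columns=["item", "unit_price_inr", "unit_basis"]
    ).to_csv(root / "prices.csv", index=False)

    cfg = {
        "schema_version": SCHEMA_VERSION,
        "site_name": register.site_name,
        "period": register.period,
        "live_births": register.live_births,
        "exchange_rate_inr_per_usd": register.exchange_rate_inr_per_usd,
        "salaries": {
            "annual_salary_inr": {
                p.value: s for p, s in register.salaries.annual_salary_inr.items()
            },
            "working_days_per_year": register.salaries.working_days_per_year,
            "working_minutes_per_day": register.salaries.working_minutes_per_day,
        },
        "incentives": register.incentives.model_dump(),
        "attribution": register.attribution.model_dump(),
        "operational": _operational_dump(register.operational),
        "supply_pools": dict(register.supply_pools),
    }
    (root / "site.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    return root


def _operational_dump(op: OperationalInputs) -> dict:
    d = op.model_dump()
    for row in d["admin_roster"]:
        row["provider"] = row["provider"].value if hasattr(row["provider"], "value") else row["provider"]
    return d
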