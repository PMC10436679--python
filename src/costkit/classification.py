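"""IMNCI sign-based classification and treatment-adherence categorisation.

Two rule sets live here. The first maps presenting signs and age to an
IMNCI class: fast breathing (>=60 breaths/min) alone is pneumonia at 7-59
days but severe pneumonia below 7 days; any of stopped feeding well,
temperature >=38.0 or <35.5 degC, severe chest indrawing, or movement only
when stimulated is clinical severe infection; convulsions, no movement at
all, or inability to feed at all is critical illness. Higher-severity
classes take precedence when signs overlap.

The second categorises what was actually given against the recommended
outpatient regimens: 7 days of once-daily injectable gentamicin plus 7 days
of twice-daily oral amoxicillin for PSBI (severe pneumonia / clinical
severe infection), or 14 doses of oral amoxicillin for pneumonia.
"""

from __future__ import annotations

from .errors import ClassificationError
from .model import (
    COSTED_PSBI_CLASSES,
    ClinicalSigns,
    IMNCIClass,
    TreatmentCategory,
    TreatmentCourse,
)

FAST_BREATHING_THRESHOLD = 60  # breaths per minute
FEVER_THRESHOLD_C = 38.0       # inclusive
HYPOTHERMIA_THRESHOLD_C = 35.5  # exclusive lower bound of normal


def classify_clinical(
    signs: ClinicalSigns,
    age_days: int,
    fast_breathing_threshold: int = FAST_BREATHING_THRESHOLD,
) -> IMNCIClass:
    """Classify a young infant's presenting signs.

    Parameters
    ----------
    signs : ClinicalSigns
    age_days : int
        Age at presentation, 0-59 days.
    fast_breathing_threshold : int
        Breaths per minute at or above which breathing is "fast"; 60 by
        convention.
    """
    if not 0 <= age_days <= 59:
        raise ClassificationError(f"age_days must be in [0, 59], got {age_days}")

    if signs.convulsions or signs.no_movement_at_all or signs.not_able_to_feed_at_all:
        return IMNCIClass.CRITICAL_ILLNESS
    if (
        signs.stopped_feeding_well
        or signs.temperature_c >= FEVER_THRESHOLD_C
        or signs.temperature_c < HYPOTHERMIA_THRESHOLD_C
        or signs.severe_chest_indrawing
        or signs.movement_only_when_stimulated
    ):
        return IMNCIClass.CLINICAL_SEVERE_INFECTION
    if signs.respiratory_rate >= fast_breathing_threshold:
        return IMNCIClass.PNEUMONIA if age_days >= 7 else IMNCIClass.SEVERE_PNEUMONIA
    return IMNCIClass.NO_PSBI_SIGN


def classify_treatment(course: TreatmentCourse) -> TreatmentCategory:
    """Categorise a treatment course as recommended / acceptable / partial /
    non-compliant.

    PSBI arm (severe pneumonia, clinical severe infection), judged on days:

    * RECOMMENDED - gentamicin 7 d and amoxicillin 7 d;
    * ACCEPTABLE  - gentamicin 2-6 d with the full 7 d of amoxicillin;
    * PARTIAL     - gentamicin 0-1 d with 7 d amoxicillin, or any gentamicin
      with under 7 d of amoxicillin;
    * NON_COMPLIANT - any other antibiotic used (alone or combined), or
      non-antibiotics only.

    Pneumonia arm, judged on doses: 14 doses RECOMMENDED, 10-13 ACCEPTABLE,
    under 10 PARTIAL, with the same non-compliance rule.

    Courses exceeding the full regimen (amoxicillin beyond 7 d / 14 doses,
    gentamicin beyond 7 d) are graded as having met it: over-treatment is
    not an adherence failure, and the partition over all syntactically valid
    courses stays total.
    """
    if course.target_class not in COSTED_PSBI_CLASSES and (
        course.target_class is not IMNCIClass.PNEUMONIA
    ):
        raise ClassificationError(
            f"treatment category undefined for class {course.target_class.value}"
        )

    if course.non_antibiotics_only or course.other_antibiotics:
        return TreatmentCategory.NON_COMPLIANT

    if course.target_class in COSTED_PSBI_CLASSES:
        g = min(course.gentamicin_days, 7)
        amox_full = course.amoxicillin_days >= 7
        if amox_full and g == 7:
            return TreatmentCategory.RECOMMENDED
        if amox_full and 2 <= g <= 6:
            return TreatmentCategory.ACCEPTABLE
        return TreatmentCategory.PARTIAL

    doses = course.amoxicillin_doses
    if doses >= 14:
        return TreatmentCategory.RECOMMENDED
    if 10 <= doses <= 13:
        return TreatmentCategory.ACCEPTABLE
    return TreatmentCategory.PARTIAL


def is_treated(category: TreatmentCategory) -> bool:
    """True iff the course counts as 'treated' (recommended or acceptable).

    Headline unit costs are expressed per infant receiving recommended or
    acceptable treatment; partial and non-compliant courses are excluded
    from the denominator.
    """
    return category in (TreatmentCategory.RECOMMENDED, TreatmentCategory.ACCEPTABLE)
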