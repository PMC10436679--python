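"""Sign classification and adherence categorisation, checked against
independent brute-force oracles."""

import itertools

import pytest

from costkit.classification import classify_clinical, classify_treatment, is_treated
from costkit.errors import ClassificationError
from costkit.model import ClinicalSigns, IMNCIClass, TreatmentCategory, TreatmentCourse

CSI = IMNCIClass.CLINICAL_SEVERE_INFECTION
SP = IMNCIClass.SEVERE_PNEUMONIA
PNEU = IMNCIClass.PNEUMONIA


@pytest.mark.parametrize(
    "age, rr, extra, expected",
    [
        (10, 62, {}, PNEU),
        (3, 64, {}, SP),
        (20, 40, {"temperature_c": 38.2}, CSI),
        (20, 40, {"temperature_c": 38.0}, CSI),            # closed bound
        (20, 40, {"temperature_c": 37.9}, IMNCIClass.NO_PSBI_SIGN),
        (20, 40, {"temperature_c": 35.5}, IMNCIClass.NO_PSBI_SIGN),  # open bound
        (20, 40, {"temperature_c": 35.4}, CSI),
        (5, 64, {"convulsions": True}, IMNCIClass.CRITICAL_ILLNESS),  # precedence
        (30, 70, {"severe_chest_indrawing": True}, CSI),             # CSI beats FB
        (6, 59, {}, IMNCIClass.NO_PSBI_SIGN),
        (7, 60, {}, PNEU),                                  # age and RR thresholds
        (6, 60, {}, SP),
    ],
)
def test_clinical_classification_examples(age, rr, extra, expected):
    signs = ClinicalSigns(respiratory_rate=rr, **extra)
    assert classify_clinical(signs, age) is expected


def test_age_out_of_range_rejected():
    with pytest.raises(ClassificationError):
        classify_clinical(ClinicalSigns(), 60)


def _oracle_clinical(flags, temp, rr, age):
    """Independent table-style implementation of the sign rules."""
    critical = {"convulsions", "no_movement_at_all", "not_able_to_feed_at_all"}
    csi_flags = {"stopped_feeding_well", "severe_chest_indrawing", "movement_only_when_stimulated"}
    active = {name for name, v in flags.items() if v}
    if active & critical:
        return IMNCIClass.CRITICAL_ILLNESS
    if (active & csi_flags) or temp >= 38.0 or temp < 35.5:
        return CSI
    if rr >= 60:
        return PNEU if 7 <= age else SP
    return IMNCIClass.NO_PSBI_SIGN


def test_clinical_classification_matches_brute_force_table():
    """Agreement over all 2^6 flag combinations x age bands x RR bands x
    temperature bands."""
    names = [
        "stopped_feeding_well",
        "severe_chest_indrawing",
        "movement_only_when_stimulated",
        "convulsions",
        "no_movement_at_all",
        "not_able_to_feed_at_all",
    ]
    for values in itertools.product([False, True], repeat=6):
        flags = dict(zip(names, values))
        for age in (0, 6, 7, 59):
            for rr in (0, 59, 60, 90):
                for temp in (35.0, 35.5, 37.0, 38.0, 39.5):
                    signs = ClinicalSigns(respiratory_rate=rr, temperature_c=temp, **flags)
                    assert classify_clinical(signs, age) is _oracle_clinical(
                        flags, temp, rr, age
                    ), (flags, age, rr, temp)


@pytest.mark.parametrize(
    "cls, kwargs, expected",
    [
        (CSI, dict(gentamicin_days=7, amoxicillin_days=7), TreatmentCategory.RECOMMENDED),
        (CSI, dict(gentamicin_days=4, amoxicillin_days=7), TreatmentCategory.ACCEPTABLE),
        (CSI, dict(gentamicin_days=7, amoxicillin_days=5), TreatmentCategory.PARTIAL),
        (CSI, dict(gentamicin_days=1, amoxicillin_days=7), TreatmentCategory.PARTIAL),
        (SP, dict(gentamicin_days=2, amoxicillin_days=7), TreatmentCategory.ACCEPTABLE),
        (CSI, dict(gentamicin_days=7, amoxicillin_days=7, other_antibiotics=["cefixime"]),
         TreatmentCategory.NON_COMPLIANT),
        (CSI, dict(non_antibiotics_only=True), TreatmentCategory.NON_COMPLIANT),
        (PNEU, dict(amoxicillin_doses=14, amoxicillin_days=7), TreatmentCategory.RECOMMENDED),
        (PNEU, dict(amoxicillin_doses=12, amoxicillin_days=6), TreatmentCategory.ACCEPTABLE),
        (PNEU, dict(amoxicillin_doses=9, amoxicillin_days=5), TreatmentCategory.PARTIAL),
        (PNEU, dict(amoxicillin_doses=10, amoxicillin_days=5,
                    other_antibiotics=["cefpodoxime"]), TreatmentCategory.NON_COMPLIANT),
    ],
)
def test_treatment_categorisation_examples(cls, kwargs, expected):
    assert classify_treatment(TreatmentCourse(target_class=cls, **kwargs)) is expected


@pytest.mark.parametrize("cls", [IMNCIClass.CRITICAL_ILLNESS, IMNCIClass.NO_PSBI_SIGN])
def test_uncategorisable_classes_rejected(cls):
    with pytest.raises(ClassificationError):
        classify_treatment(TreatmentCourse(target_class=cls))


def test_psbi_partition_exhaustive_by_enumeration():
    """Every syntactically valid PSBI course maps to exactly one category,
    and the categories match a literal restatement of the rules."""
    for g, a, other in itertools.product(range(0, 8), range(0, 10), [False, True]):
        course = TreatmentCourse(
            target_class=CSI,
            gentamicin_days=g,
            amoxicillin_days=a,
            other_antibiotics=["cefixime"] if other else [],
        )
        got = classify_treatment(course)
        if other:
            expected = TreatmentCategory.NON_COMPLIANT
        elif a >= 7 and g == 7:
            expected = TreatmentCategory.RECOMMENDED
        elif a >= 7 and 2 <= g <= 6:
            expected = TreatmentCategory.ACCEPTABLE
        else:
            expected = TreatmentCategory.PARTIAL
        assert got is expected, (g, a, other)


def test_pneumonia_partition_exhaustive_by_enumeration():
    for doses, other in itertools.product(range(0, 15), [False, True]):
        course = TreatmentCourse(
            target_class=PNEU,
            amoxicillin_doses=doses,
            amoxicillin_days=(doses + 1) // 2,
            other_antibiotics=["cefixime"] if other else [],
        )
        got = classify_treatment(course)
        if other:
            expected = TreatmentCategory.NON_COMPLIANT
        elif doses == 14:
            expected = TreatmentCategory.RECOMMENDED
        elif 10 <= doses:
            expected = TreatmentCategory.ACCEPTABLE
        else:
            expected = TreatmentCategory.PARTIAL
        assert got is expected, (doses, other)


def test_more_gentamicin_never_worsens_category():
    """With the full amoxicillin course and no other antibiotics, adding
    gentamicin days moves the category monotonically toward RECOMMENDED."""
    order = {
        TreatmentCategory.PARTIAL: 0,
        TreatmentCategory.ACCEPTABLE: 1,
        TreatmentCategory.RECOMMENDED: 2,
    }
    last = -1
    for g in range(0, 8):
        cat = classify_treatment(
            TreatmentCourse(target_class=CSI, gentamicin_days=g, amoxicillin_days=7)
        )
        assert order[cat] >= last
        last = order[cat]


def test_is_treated_selects_recommended_and_acceptable():
    assert is_treated(TreatmentCategory.RECOMMENDED)
    assert is_treated(TreatmentCategory.ACCEPTABLE)
    assert not is_treated(TreatmentCategory.PARTIAL)
    assert not is_treated(TreatmentCategory.NON_COMPLIANT)
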