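"""Classify presenting signs, then grade the treatment actually given.

Fast breathing alone is pneumonia at 7-59 days but severe pneumonia under
7 days; the recommended outpatient PSBI regimen is 7 days of gentamicin
plus 7 days of amoxicillin, and 2-6 gentamicin days still count as
acceptable.
"""

from costkit import classify_clinical, classify_treatment, is_treated
from costkit.model import ClinicalSigns, IMNCIClass, TreatmentCourse

cases = [
    ("10-day-old, RR 62", ClinicalSigns(respiratory_rate=62), 10),
    ("3-day-old, RR 64", ClinicalSigns(respiratory_rate=64), 3),
    ("20-day-old, 38.2 degC", ClinicalSigns(temperature_c=38.2), 20),
    ("5-day-old, convulsions", ClinicalSigns(convulsions=True, respiratory_rate=64), 5),
]
for label, signs, age in cases:
    print(f"{label:28s} -> {classify_clinical(signs, age).value}")

courses = [
    ("gentamicin 7d + amoxicillin 7d", dict(gentamicin_days=7, amoxicillin_days=7)),
    ("gentamicin 4d + amoxicillin 7d", dict(gentamicin_days=4, amoxicillin_days=7)),
    ("gentamicin 7d + amoxicillin 5d", dict(gentamicin_days=7, amoxicillin_days=5)),
    ("cefixime instead", dict(other_antibiotics=["cefixime"])),
]
for label, kwargs in courses:
    course = TreatmentCourse(target_class=IMNCIClass.CLINICAL_SEVERE_INFECTION, **kwargs)
    cat = classify_treatment(course)
    print(f"{label:32s} -> {cat.value:13s} treated={is_treated(cat)}")
# Only recommended/acceptable courses enter the denominator of the
# headline per-treated-infant unit costs.
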