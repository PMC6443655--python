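"""Preset synthetic-population specification.

``default_population_spec`` describes the study conditions the package is
demonstrated on: reproductive-age women in a weighted annual claims
sample, endometriosis (N80) at a treated-case rate of roughly 6.5 per
1,000, the seven candidate comorbidity families at their control-group
prevalences (benign breast neoplasm 0.6%, mammary dysplasia 0.4%, other
breast disorders 0.6%, cystitis 4.6%, non-toxic goitre 0.8%, iron
deficiency anaemia 1.2%, other anaemias 0.5%) with planted associations
of the magnitude reported for such comorbidities (odds ratios 1.5-3),
gynecologic categories strongly associated with N80 (emulating the
examination bias that motivates the gynecologic exclusion), and
unassociated background diseases.
"""

from __future__ import annotations

from .synth import AssociationSpec, DiseaseSpec, PopulationSpec

#: (category, full-code mixture, control prevalence, test tokens, planted OR to N80)
_CANDIDATES = [
    ("D24", {"D24": 1.0}, 0.006,
     ("MAMMOGRAPHY", "BREAST_TOMO", "BREAST_US"), 2.6),
    ("N60", {"N60.1": 0.6, "N60.9": 0.4}, 0.004,
     ("MAMMOGRAPHY", "BREAST_TOMO", "BREAST_US"), 1.9),
    ("N64", {"N64.4": 0.5, "N64.9": 0.5}, 0.006,
     ("MAMMOGRAPHY", "BREAST_TOMO", "BREAST_US"), 1.8),
    ("N30", {"N30.0": 0.6, "N30.8": 0.1, "N30.9": 0.3}, 0.046,
     ("URINALYSIS", "URINE_MICRO", "URINE_CULTURE"), 1.5),
    ("E04", {"E04.1": 0.5, "E04.2": 0.3, "E04.9": 0.2}, 0.008,
     ("TSH", "FREE_T3", "FREE_T4", "NECK_US"), 1.6),
    ("D50", {"D50.0": 0.3, "D50.8": 0.2, "D50.9": 0.5}, 0.012,
     ("HAEMOGLOBIN",), 3.0),
    ("D64", {"D64.8": 0.4, "D64.9": 0.6}, 0.005,
     ("HAEMOGLOBIN",), 2.1),
]

#: Gynecologic categories carried along with endometriosis because of
#: gynecologic examination (detection bias); all fall in the exclusion
#: ranges and should dominate the raw top-K list.
_GYNECOLOGIC = [
    ("N76", {"N76.0": 0.7, "N76.1": 0.3}, 0.030, 3.5),
    ("N83", {"N83.0": 0.4, "N83.2": 0.6}, 0.015, 4.0),
    ("N84", {"N84.0": 0.6, "N84.1": 0.4}, 0.006, 3.0),
    ("N85", {"N85.0": 0.5, "N85.9": 0.5}, 0.005, 3.0),
    ("N87", {"N87.0": 0.6, "N87.9": 0.4}, 0.008, 2.8),
    ("N89", {"N89.8": 1.0}, 0.010, 2.8),
    ("N92", {"N92.0": 0.5, "N92.1": 0.5}, 0.025, 3.2),
    ("N94", {"N94.4": 0.3, "N94.6": 0.7}, 0.020, 3.6),
    ("D25", {"D25.0": 0.3, "D25.9": 0.7}, 0.012, 3.8),
    ("D27", {"D27": 1.0}, 0.006, 3.4),
    ("N97", {"N97.9": 1.0}, 0.004, 2.6),
    ("O03", {"O03.9": 1.0}, 0.008, 2.0),
]

#: Unassociated background morbidity of reproductive-age women.
_BACKGROUND = [
    ("J06", {"J06.9": 1.0}, 0.080),
    ("J20", {"J20.9": 1.0}, 0.040),
    ("A09", {"A09": 1.0}, 0.035),
    ("K29", {"K29.7": 1.0}, 0.030),
    ("K59", {"K59.0": 1.0}, 0.015),
    ("M54", {"M54.5": 1.0}, 0.025),
    ("J30", {"J30.4": 1.0}, 0.020),
    ("L23", {"L23.9": 1.0}, 0.012),
    ("H10", {"H10.9": 1.0}, 0.010),
    ("G43", {"G43.9": 1.0}, 0.008),
    ("B02", {"B02.9": 1.0}, 0.004),
    ("E11", {"E11.9": 1.0}, 0.006),
]


def default_population_spec(
    n_patients: int = 50_000, seed: int = 0, **overrides
) -> PopulationSpec:
    """The preset study population; keyword overrides pass to PopulationSpec."""
    diseases = [
        DiseaseSpec(
            category="N80",
            full_codes={"N80.0": 0.25, "N80.1": 0.35, "N80.3": 0.25, "N80.9": 0.15},
            base_prevalence=0.008,
        )
    ]
    associations = []
    for cat, codes, prev, tests, or_ in _CANDIDATES:
        diseases.append(
            DiseaseSpec(
                category=cat,
                full_codes=codes,
                base_prevalence=prev,
                linked_test_codes=tests,
                test_code_sensitivity=0.8,
            )
        )
        associations.append(AssociationSpec("N80", cat, or_))
    for cat, codes, prev, or_ in _GYNECOLOGIC:
        diseases.append(
            DiseaseSpec(category=cat, full_codes=codes, base_prevalence=prev)
        )
        associations.append(AssociationSpec("N80", cat, or_))
    for cat, codes, prev in _BACKGROUND:
        diseases.append(
            DiseaseSpec(category=cat, full_codes=codes, base_prevalence=prev)
        )
    return PopulationSpec(
        n_patients=n_patients,
        diseases=diseases,
        associations=associations,
        seed=seed,
        **overrides,
    )
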