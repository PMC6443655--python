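"""Synthetic claims-population generator with plantable disease associations.

Emulates the structure of a weighted national inpatient sample (one row
per patient-year, inpatient/outpatient sampling weights 7.692/100, a low
socioeconomic-status flag, multi-label ICD-10 diagnoses, procedure codes
probabilistically tied to diagnoses) so every downstream stage — the
item-similarity recommender and the case-control confirmation — can be
exercised and validated without access to the non-public source data.

Associations between disease pairs are *planted* as conditional odds
ratios.  Diseases are sampled sequentially in spec order; a disease that
is associated with already-sampled diseases uses a logistic conditional
model whose coefficients are the logs of the specified odds ratios and
whose intercept is solved numerically so the marginal prevalence matches
the requested base prevalence.  This yields exact conditional odds ratios
with calibrated margins, without MCMC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .claims import (
    INPATIENT_WEIGHT,
    OUTPATIENT_WEIGHT,
    ClaimRecord,
    ClaimsDataset,
    ClaimsError,
    ConfigurationError,
    category_of,
    normalize_code,
)

log = logging.getLogger(__name__)

#: Placeholder treatment tokens marking treated endometriosis (gynecologic
#: surgery / GnRH-agonist prescription); the real claims procedure codes
#: are not public, so these are configurable tokens.
DEFAULT_TREATMENT_CODES = ("SURG_GYN", "RX_GNRH")


@dataclass
class DiseaseSpec:
    """One disease category with its full-code mixture and linked test codes.

    ``test_code_sensitivity`` is the probability that a true case also
    carries the linked procedure/test codes in the same year, emulating
    diagnosis definitions of the form "diagnostic code plus clinically
    valid test code".  ``age_log_or_per_year`` plants a log-linear age
    trend in prevalence (0 = age-independent), so that age confounding is
    constructible.
    """

    category: str
    full_codes: dict[str, float]  # full code -> sampling probability
    base_prevalence: float
    linked_test_codes: tuple[str, ...] = ()
    test_code_sensitivity: float = 1.0
    age_log_or_per_year: float = 0.0

    def __post_init__(self) -> None:
        self.category = normalize_code(self.category)
        self.full_codes = {normalize_code(c): p for c, p in self.full_codes.items()}
        if not self.full_codes:
            raise ConfigurationError(f"{self.category}: full_codes must be non-empty")
        total = sum(self.full_codes.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ConfigurationError(
                f"{self.category}: full-code probabilities sum to {total}, not 1"
            )
        for c in self.full_codes:
            if category_of(c) != self.category:
                raise ConfigurationError(
                    f"full code {c} does not belong to category {self.category}"
                )
        if not 0.0 < self.base_prevalence < 1.0:
            raise ConfigurationError(
                f"{self.category}: base_prevalence must be in (0,1)"
            )
        if not 0.0 < self.test_code_sensitivity <= 1.0:
            raise ConfigurationError(
                f"{self.category}: test_code_sensitivity must be in (0,1]"
            )
        self.linked_test_codes = tuple(self.linked_test_codes)


@dataclass(frozen=True)
class AssociationSpec:
    """A planted pairwise association; odds_ratio = 1 means independence."""

    disease_a: str
    disease_b: str
    odds_ratio: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_a", normalize_code(self.disease_a))
        object.__setattr__(self, "disease_b", normalize_code(self.disease_b))
        if not self.odds_ratio > 0:
            raise ConfigurationError("odds_ratio must be positive")


@dataclass
class PopulationSpec:
    """Full description of a synthetic claims population.

    Defaults mirror the emulated sample: reproductive-age women (15-45),
    claim years 2009-2015, a mostly-inpatient sample file, a low-SES rate
    of 2.8% and an 80% treatment rate among endometriosis-coded women.
    """

    n_patients: int
    diseases: list[DiseaseSpec]
    associations: list[AssociationSpec] = field(default_factory=list)
    age_range: tuple[int, int] = (15, 45)
    year_range: tuple[int, int] = (2009, 2015)
    inpatient_fraction: float = 0.6
    low_ses_rate: float = 0.028
    female_fraction: float = 1.0
    endometriosis_treatment_rate: float = 0.8
    treatment_codes: tuple[str, ...] = DEFAULT_TREATMENT_CODES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for name, rate in (
            ("inpatient_fraction", self.inpatient_fraction),
            ("low_ses_rate", self.low_ses_rate),
        ):
            if not 0.0 < rate < 1.0:
                raise ConfigurationError(f"{name} must be in (0,1), got {rate}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0,1]")
        if not 0.0 < self.endometriosis_treatment_rate <= 1.0:
            raise ConfigurationError("endometriosis_treatment_rate must be in (0,1]")
        known = {d.category for d in self.diseases}
        if len(known) != len(self.diseases):
            raise ConfigurationError("duplicate disease categories in spec")
        for a in self.associations:
            for cat in (a.disease_a, a.disease_b):
                if cat not in known:
                    raise ConfigurationError(
                        f"association references unknown disease {cat}"
                    )


def _solve_intercept(offset: np.ndarray, target_prevalence: float) -> float:
    """Intercept alpha with mean(expit(alpha + offset)) = target_prevalence.

    The mean is strictly increasing in alpha, so a bracketed root always
    exists for targets in (0,1).
    """

    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + offset))) - target_prevalence

    lo, hi = -40.0, 40.0
    return brentq(f, lo, hi, xtol=1e-12)


def generate_population(
    spec: PopulationSpec, seed: int | None = None
) -> ClaimsDataset:
    """Draw a synthetic claims population from a :class:`PopulationSpec`.

    Ages and years are uniform over their ranges; admission type is
    Bernoulli(``inpatient_fraction``) with weight 7.692 (inpatient) or 100
    (outpatient); disease indicators follow the sequential conditional
    logistic construction described in the module docstring; each present
    disease contributes one full code and, with probability
    ``test_code_sensitivity``, its linked test codes; endometriosis-coded
    (N80) patients receive treatment codes with probability
    ``endometriosis_treatment_rate``.  Fixed seed implies byte-identical
    output.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients

    ages = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    years = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n)
    inpatient = rng.random(n) < spec.inpatient_fraction
    weights = np.where(inpatient, INPATIENT_WEIGHT, OUTPATIENT_WEIGHT)
    low_ses = rng.random(n) < spec.low_ses_rate
    female = rng.random(n) < spec.female_fraction

    # log-OR matrix keyed by category pair
    beta: dict[tuple[str, str], float] = {}
    for a in spec.associations:
        b = math.log(a.odds_ratio)
        beta[(a.disease_a, a.disease_b)] = b
        beta[(a.disease_b, a.disease_a)] = b

    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    indicators: dict[str, np.ndarray] = {}
    for disease in spec.diseases:
        offset = np.zeros(n)
        if disease.age_log_or_per_year:
            offset += disease.age_log_or_per_year * (ages - mid_age)
        for prev_cat, prev_ind in indicators.items():
            b = beta.get((disease.category, prev_cat))
            if b:
                offset += b * prev_ind
        alpha = _solve_intercept(offset, disease.base_prevalence)
        indicators[disease.category] = (
            rng.random(n) < expit(alpha + offset)
        ).astype(np.int8)

    # full-code assignment, linked test codes, endometriosis treatment
    diagnoses: list[list[str]] = [[] for _ in range(n)]
    procedures: list[list[str]] = [[] for _ in range(n)]
    for disease in spec.diseases:
        present = np.flatnonzero(indicators[disease.category])
        if present.size == 0:
            continue
        codes = list(disease.full_codes)
        probs = np.array([disease.full_codes[c] for c in codes])
        picks = rng.choice(len(codes), size=present.size, p=probs)
        tested = (
            rng.random(present.size) < disease.test_code_sensitivity
            if disease.linked_test_codes
            else np.zeros(present.size, dtype=bool)
        )
        for idx, pick, has_test in zip(present, picks, tested):
            diagnoses[idx].append(codes[pick])
            if has_test:
                procedures[idx].extend(disease.linked_test_codes)

    endo_cats = [d.category for d in spec.diseases if d.category == "N80"]
    if endo_cats:
        endo_present = np.flatnonzero(indicators["N80"])
        treated = rng.random(endo_present.size) < spec.endometriosis_treatment_rate
        for idx, is_treated in zip(endo_present, treated):
            if is_treated:
                procedures[idx].extend(spec.treatment_codes)

    width = len(str(n))
    records = [
        ClaimRecord(
            patient_id=f"P{i:0{width}d}",
            age=int(ages[i]),
            sex="F" if female[i] else "M",
            year=int(years[i]),
            low_ses=bool(low_ses[i]),
            admission="inpatient" if inpatient[i] else "outpatient",
            weight=float(weights[i]),
            diagnoses=frozenset(diagnoses[i]),
            procedures=frozenset(procedures[i]),
        )
        for i in range(n)
    ]
    return ClaimsDataset(records=records, provenance="synthetic")


def pairwise_table(
    dataset: ClaimsDataset, a: str, b: str
) -> tuple[int, int, int, int]:
    """2x2 presence counts (n11, n10, n01, n00) for categories a and b."""
    a, b = normalize_code(a), normalize_code(b)
    n11 = n10 = n01 = n00 = 0
    for rec in dataset:
        cats = rec.categories
        has_a, has_b = a in cats, b in cats
        if has_a and has_b:
            n11 += 1
        elif has_a:
            n10 += 1
        elif has_b:
            n01 += 1
        else:
            n00 += 1
    return n11, n10, n01, n00


def empirical_pairwise_or(dataset: ClaimsDataset, a: str, b: str) -> float:
    """Cross-product odds ratio of the 2x2 presence table for (a, b).

    The Haldane-Anscombe +0.5 correction is applied only when some cell
    is zero, so exact small-table arithmetic stays exact.  Serves as the
    validation oracle for the planted associations of the generator.
    """
    n11, n10, n01, n00 = pairwise_table(dataset, a, b)
    if n11 + n10 == 0:
        raise ClaimsError(f"category {a} absent from dataset")
    if n11 + n01 == 0:
        raise ClaimsError(f"category {b} absent from dataset")
    return cross_product_or(n11, n10, n01, n00)


def cross_product_or(n11: float, n10: float, n01: float, n00: float) -> float:
    """(n11*n00)/(n10*n01), +0.5 to every cell only if some cell is zero."""
    if min(n11, n10, n01, n00) == 0:
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
    return (n11 * n00) / (n10 * n01)


def population_spec_to_dict(spec: PopulationSpec) -> dict:
    """Plain-dict (YAML-serializable) form of a population spec."""
    return {
        "n_patients": spec.n_patients,
        "age_range": list(spec.age_range),
        "year_range": list(spec.year_range),
        "inpatient_fraction": spec.inpatient_fraction,
        "low_ses_rate": spec.low_ses_rate,
        "female_fraction": spec.female_fraction,
        "endometriosis_treatment_rate": spec.endometriosis_treatment_rate,
        "treatment_codes": list(spec.treatment_codes),
        "seed": spec.seed,
        "diseases": [
            {
                "category": d.category,
                "full_codes": dict(d.full_codes),
                "base_prevalence": d.base_prevalence,
                "linked_test_codes": list(d.linked_test_codes),
                "test_code_sensitivity": d.test_code_sensitivity,
                "age_log_or_per_year": d.age_log_or_per_year,
            }
            for d in spec.diseases
        ],
        "associations": [
            {"disease_a": a.disease_a, "disease_b": a.disease_b, "odds_ratio": a.odds_ratio}
            for a in spec.associations
        ],
    }


def population_spec_from_dict(raw: dict) -> PopulationSpec:
    """Inverse of :func:`population_spec_to_dict`."""
    diseases = [
        DiseaseSpec(
            category=d["category"],
            full_codes=d["full_codes"],
            base_prevalence=d["base_prevalence"],
            linked_test_codes=tuple(d.get("linked_test_codes", ())),
            test_code_sensitivity=d.get("test_code_sensitivity", 1.0),
            age_log_or_per_year=d.get("age_log_or_per_year", 0.0),
        )
        for d in raw["diseases"]
    ]
    associations = [
        AssociationSpec(a["disease_a"], a["disease_b"], a["odds_ratio"])
        for a in raw.get("associations", [])
    ]
    kwargs = {
        k: raw[k]
        for k in (
            "inpatient_fraction",
            "low_ses_rate",
            "female_fraction",
            "endometriosis_treatment_rate",
            "seed",
        )
        if k in raw
    }
    if "age_range" in raw:
        kwargs["age_range"] = tuple(raw["age_range"])
    if "year_range" in raw:
        kwargs["year_range"] = tuple(raw["year_range"])
    if "treatment_codes" in raw:
        kwargs["treatment_codes"] = tuple(raw["treatment_codes"])
    return PopulationSpec(
        n_patients=raw["n_patients"],
        diseases=diseases,
        associations=associations,
        **kwargs,
    )
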