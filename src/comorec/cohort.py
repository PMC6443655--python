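"""Case-control cohort construction for the confirmation stage.

Cases are women aged 15-45 carrying an endometriosis diagnosis (N80.x)
together with a concurrent treatment code (gynecologic surgery or
hormonal prescription) in the same patient-year; controls are women of
the same age range with no N80.x code at all.  Women with an N80.x code
but no treatment code satisfy neither definition and are dropped from
both groups (the count is recorded).  Candidate comorbidities are flagged
by a combination of diagnosis codes and, where configured, clinically
valid test codes — e.g. a benign-breast-disease code plus a breast
examination code — which sharpens diagnostic accuracy in claims data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd
import yaml

from .claims import (
    ClaimRecord,
    ClaimsDataset,
    ClaimsError,
    ConfigurationError,
    category_of,
    normalize_code,
)

log = logging.getLogger(__name__)


@dataclass
class DiseaseDefinition:
    """A claims-based disease definition: diagnosis codes + optional test codes.

    ``diagnosis_codes`` are matched at ``match_level``: at "category"
    level a pattern "N30" matches any N30.x diagnosis; at "full" level a
    pattern matches the exact normalized full code.  If
    ``required_test_codes`` is non-empty, at least one of them must appear
    among the record's procedures (any-of semantics).
    """

    name: str
    diagnosis_codes: tuple[str, ...]
    required_test_codes: tuple[str, ...] = ()
    match_level: str = "category"

    def __post_init__(self) -> None:
        if not self.diagnosis_codes:
            raise ConfigurationError(f"{self.name}: diagnosis_codes must be non-empty")
        if self.match_level not in ("category", "full"):
            raise ConfigurationError(f"{self.name}: bad match_level")
        self.diagnosis_codes = tuple(
            normalize_code(c) for c in self.diagnosis_codes
        )
        self.required_test_codes = tuple(self.required_test_codes)


def flag_disease(record: ClaimRecord, definition: DiseaseDefinition) -> bool:
    """True iff the record meets the disease definition.

    Monotone in procedures: adding a procedure code never un-flags.
    """
    if definition.match_level == "category":
        codes = record.categories
        patterns = {category_of(c) for c in definition.diagnosis_codes}
    else:
        codes = record.diagnoses
        patterns = set(definition.diagnosis_codes)
    if not (codes & patterns):
        return False
    if not definition.required_test_codes:
        return True
    return bool(record.procedures & set(definition.required_test_codes))


def age_band_5y(age: int) -> int:
    """5-year age-band index anchored at 15: [15,20) -> 0, ..., 45 -> 6."""
    return min((age - 15) // 5, 6)


@dataclass
class CohortTable:
    """Per-patient case/control labels, covariates and candidate flags.

    ``data`` columns: patient_id, case, age, age_band_5y, year, low_ses,
    weight, and one boolean column per candidate disease name.
    """

    data: pd.DataFrame
    disease_names: list[str]
    n_dropped_untreated: int = 0

    @property
    def n_cases(self) -> int:
        return int(self.data["case"].sum())

    @property
    def n_controls(self) -> int:
        return int((~self.data["case"]).sum())


def build_cohort(
    dataset: ClaimsDataset,
    endo_definition: DiseaseDefinition,
    candidates: list[DiseaseDefinition],
) -> CohortTable:
    """Build the confirmation cohort from a claims dataset.

    Keeps records with sex F and 15 <= age <= 45.  ``case`` is the
    endometriosis definition (diagnosis + treatment code); records with an
    N80.x diagnosis but no treatment code are dropped entirely.  Raises
    when either side of the cohort ends up empty.
    """
    if not endo_definition.required_test_codes:
        raise ConfigurationError(
            "endometriosis definition must require treatment codes"
        )
    endo_cats = {category_of(c) for c in endo_definition.diagnosis_codes}

    rows = []
    n_dropped_untreated = 0
    for rec in dataset:
        if rec.sex != "F" or not 15 <= rec.age <= 45:
            continue
        has_endo_code = bool(rec.categories & endo_cats)
        is_case = flag_disease(rec, endo_definition)
        if has_endo_code and not is_case:
            n_dropped_untreated += 1
            continue
        row = {
            "patient_id": rec.patient_id,
            "case": is_case,
            "age": rec.age,
            "age_band_5y": age_band_5y(rec.age),
            "year": rec.year,
            "low_ses": rec.low_ses,
            "weight": rec.weight,
        }
        for defn in candidates:
            row[defn.name] = flag_disease(rec, defn)
        rows.append(row)

    if n_dropped_untreated:
        log.info(
            "build_cohort: dropped %d N80-coded record(s) without treatment codes",
            n_dropped_untreated,
        )
    names = [d.name for d in candidates]
    data = pd.DataFrame(
        rows,
        columns=["patient_id", "case", "age", "age_band_5y", "year", "low_ses", "weight"]
        + names,
    )
    n_cases = int(data["case"].sum()) if len(data) else 0
    if n_cases == 0:
        raise ClaimsError("cohort has no cases after filtering")
    if n_cases == len(data):
        raise ClaimsError("cohort has no controls after filtering")
    return CohortTable(
        data=data, disease_names=names, n_dropped_untreated=n_dropped_untreated
    )


def percent_1dp(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (9/11273 -> 0.1)."""
    if denominator <= 0:
        raise ClaimsError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_count_percent(numerator: int, denominator: int) -> str:
    """Render "137 (1.2%)" as in a characteristics table."""
    return f"{numerator:,} ({percent_1dp(numerator, denominator):.1f}%)"


def characteristics_table(
    cohort: CohortTable,
    *,
    suppress_below_pct: float = 0.1,
) -> pd.DataFrame:
    """Group-characteristics summary of the cohort (a "Table 1").

    One row per variable: group sizes, weighted mean age with standard
    error and weighted t-test p-value, then count (percent) per group with
    a chi-square (Fisher fallback) p-value for low SES, data year, and
    each candidate disease.  Diseases whose prevalence is below
    ``suppress_below_pct`` percent in *both* groups are suppressed.
    """
    from .stats import chi_square_test, weighted_t_test

    df = cohort.data
    cases = df[df["case"]]
    controls = df[~df["case"]]
    if len(cases) == 0 or len(controls) == 0:
        raise ClaimsError("both groups must be non-empty")
    n1, n0 = len(cases), len(controls)

    rows = []
    rows.append(
        {
            "variable": "Number of patients",
            "control": f"{n0:,}",
            "endometriosis": f"{n1:,}",
            "p_value": float("nan"),
        }
    )
    tt = weighted_t_test(
        controls["age"].to_numpy(float),
        controls["weight"].to_numpy(float),
        cases["age"].to_numpy(float),
        cases["weight"].to_numpy(float),
    )
    rows.append(
        {
            "variable": "Mean age, year",
            "control": f"{tt.mean_a:.1f} ± {tt.se_a:.1f}",
            "endometriosis": f"{tt.mean_b:.1f} ± {tt.se_b:.1f}",
            "p_value": tt.p_value,
        }
    )

    def _categorical_row(name: str, flag0: int, flag1: int) -> dict:
        table = [[flag0, n0 - flag0], [flag1, n1 - flag1]]
        p = chi_square_test(table)
        return {
            "variable": name,
            "control": format_count_percent(flag0, n0),
            "endometriosis": format_count_percent(flag1, n1),
            "p_value": p,
        }

    rows.append(
        _categorical_row(
            "Low SES", int(controls["low_ses"].sum()), int(cases["low_ses"].sum())
        )
    )
    # data year distribution: one chi-square across all years
    years = sorted(df["year"].unique())
    if len(years) > 1:
        year_table = [
            [int((controls["year"] == y).sum()) for y in years],
            [int((cases["year"] == y).sum()) for y in years],
        ]
        p_year = chi_square_test(year_table)
        rows.append(
            {
                "variable": "Data year",
                "control": "",
                "endometriosis": "",
                "p_value": p_year,
            }
        )
        for y in years:
            rows.append(
                {
                    "variable": f"  {y}",
                    "control": format_count_percent(int((controls["year"] == y).sum()), n0),
                    "endometriosis": format_count_percent(int((cases["year"] == y).sum()), n1),
                    "p_value": float("nan"),
                }
            )

    for name in cohort.disease_names:
        f0 = int(controls[name].sum())
        f1 = int(cases[name].sum())
        if (
            percent_1dp(f0, n0) < suppress_below_pct
            and percent_1dp(f1, n1) < suppress_below_pct
        ):
            log.info("characteristics_table: suppressing rare disease %s", name)
            continue
        rows.append(_categorical_row(name, f0, f1))

    return pd.DataFrame(rows, columns=["variable", "control", "endometriosis", "p_value"])


def expand_to_full_codes(
    dataset: ClaimsDataset, definition: DiseaseDefinition
) -> list[DiseaseDefinition]:
    """Split a category-level definition into one definition per observed full code.

    Used for the full-code confirmation stage: each full diagnosis code
    observed in the dataset under the definition's categories becomes its
    own definition, inheriting the required test codes.
    """
    cats = {category_of(c) for c in definition.diagnosis_codes}
    observed = sorted(
        {
            code
            for rec in dataset
            for code in rec.diagnoses
            if category_of(code) in cats
        }
    )
    return [
        DiseaseDefinition(
            name=f"{definition.name}:{code}",
            diagnosis_codes=(code,),
            required_test_codes=definition.required_test_codes,
            match_level="full",
        )
        for code in observed
    ]


def load_catalogue(path=None) -> dict[str, DiseaseDefinition]:
    """Load a YAML disease-definition catalogue.

    With no path, loads the bundled default catalogue (benign breast
    disease families, cystitis, non-toxic goitre, anaemias, and the
    endometriosis case definition with its treatment tokens).
    """
    if path is None:
        text = (
            resources.files("comorec").joinpath("data/disease_catalogue.yaml")
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for name, entry in raw.items():
        out[name] = DiseaseDefinition(
            name=name,
            diagnosis_codes=tuple(entry["diagnosis_codes"]),
            required_test_codes=tuple(entry.get("required_test_codes", ())),
            match_level=entry.get("match_level", "category"),
        )
    return out
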