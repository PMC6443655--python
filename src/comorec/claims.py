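"""Core claims-data domain model and ICD-10 code utilities.

The observational unit throughout the package is the *patient-year*: one
row of a national-claims sample describes one patient in one calendar
year, carrying demographics, a sampling weight, the set of ICD-10
diagnosis codes recorded that year and the set of procedure/prescription
codes.  Multi-year patients appear as independent records, matching the
annual structure of weighted national inpatient samples.

ICD-10 codes are normalized to uppercase with the dot removed
("N80.1" -> "N801"); the three-character *category* ("N80") is the unit
of the recommender stage.  Code ranges such as "C51~C58" use inclusive
lexicographic semantics, which is how ICD-10 categories sort within a
letter block.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

#: Sampling weights of the emulated national inpatient sample: inpatients
#: are a 13% sample (weight 1/0.13 = 7.692), never-hospitalized patients
#: a 1% sample (weight 100).
INPATIENT_WEIGHT = 7.692
OUTPATIENT_WEIGHT = 100.0

_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


class ClaimsError(ValueError):
    """Base class for claims-model validation errors."""


class ConfigurationError(ClaimsError):
    """A configuration (column map, range string, spec) is invalid."""


def normalize_code(code: str) -> str:
    """Normalize an ICD-10 code: uppercase, dot removed, whitespace stripped."""
    return code.strip().upper().replace(".", "")


def display_code(code: str) -> str:
    """Render a normalized code with the conventional dot ("N801" -> "N80.1")."""
    code = normalize_code(code)
    if len(code) > 3:
        return code[:3] + "." + code[3:]
    return code


def category_of(code: str) -> str:
    """Return the three-character ICD-10 category of a full code.

    Examples
    --------
    >>> category_of("N80.1")
    'N80'
    >>> category_of("E04")
    'E04'
    """
    norm = normalize_code(code)
    if len(norm) < 3:
        raise ClaimsError(f"ICD-10 code too short for a category: {code!r}")
    return norm[:3]


def is_category(s: str) -> bool:
    """True iff ``s`` is a syntactically valid three-character category."""
    return bool(_CATEGORY_RE.match(s))


@dataclass(frozen=True)
class CodeRange:
    """An inclusive lexicographic range of ICD-10 categories, e.g. C51~C58."""

    start_category: str
    end_category: str

    def __post_init__(self) -> None:
        start = normalize_code(self.start_category)
        end = normalize_code(self.end_category)
        if not (is_category(start) and is_category(end)):
            raise ConfigurationError(
                f"range bounds must be three-character categories: "
                f"{self.start_category!r}~{self.end_category!r}"
            )
        if start > end:
            raise ConfigurationError(
                f"range start {start!r} exceeds end {end!r}"
            )
        object.__setattr__(self, "start_category", start)
        object.__setattr__(self, "end_category", end)

    def __contains__(self, category: str) -> bool:
        return self.start_category <= normalize_code(category) <= self.end_category

    def __str__(self) -> str:
        return f"{self.start_category}~{self.end_category}"

    @classmethod
    def parse(cls, text: str) -> "CodeRange":
        """Parse "C51~C58" or "C51-C58" into a range."""
        parts = re.split(r"[~\-]", text.strip())
        if len(parts) != 2:
            raise ConfigurationError(f"cannot parse code range {text!r}")
        return cls(parts[0], parts[1])


def in_any_range(category: str, ranges: list[CodeRange] | tuple[CodeRange, ...]) -> bool:
    """True iff some range contains the category (inclusive, lexicographic)."""
    if not is_category(normalize_code(category)):
        raise ClaimsError(f"not a valid three-character category: {category!r}")
    return any(category in r for r in ranges)


#: Gynecologic disease ranges excluded from the recommender's candidate
#: list: malignant neoplasms of female genital organs, carcinoma in situ
#: of cervix/genital organs, benign neoplasms of uterus/ovary/genitals,
#: pregnancy/childbirth/puerperium, inflammatory and noninflammatory
#: disorders of the female genital tract.
GYNECOLOGIC_RANGES: tuple[CodeRange, ...] = (
    CodeRange("C51", "C58"),
    CodeRange("D06", "D07"),
    CodeRange("D25", "D28"),
    CodeRange("O00", "O99"),
    CodeRange("N70", "N77"),
    CodeRange("N80", "N98"),
)


@dataclass(frozen=True)
class ClaimRecord:
    """One patient-year observation of a weighted claims sample."""

    patient_id: str
    age: int
    sex: str  # "F" or "M"
    year: int
    low_ses: bool
    admission: str  # "inpatient" or "outpatient"
    weight: float
    diagnoses: frozenset[str] = field(default_factory=frozenset)
    procedures: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ClaimsError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.admission not in ("inpatient", "outpatient"):
            raise ClaimsError(f"bad admission type {self.admission!r}")
        if not self.weight > 0:
            raise ClaimsError(f"weight must be positive, got {self.weight}")
        object.__setattr__(
            self, "diagnoses", frozenset(normalize_code(c) for c in self.diagnoses)
        )
        object.__setattr__(
            self, "procedures", frozenset(str(p).strip() for p in self.procedures)
        )

    @property
    def categories(self) -> frozenset[str]:
        """Distinct three-character categories of this record's diagnoses."""
        return frozenset(category_of(c) for c in self.diagnoses)


@dataclass
class ClaimsDataset:
    """An ordered collection of patient-year records."""

    records: list[ClaimRecord]
    provenance: str = ""
    n_rejected: int = 0

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ClaimsError("patient_id values must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "age": "age",
    "sex": "sex",
    "year": "year",
    "low_ses": "low_ses",
    "admission": "admission",
    "weight": "weight",
    "diagnoses": "diagnoses",
    "procedures": "procedures",
}

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(s: str) -> bool:
    v = s.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {s!r}")


def read_claims(
    path,
    format_config: dict | None = None,
    *,
    delimiter: str = ",",
    code_separator: str = "|",
    permissive: bool = True,
) -> ClaimsDataset:
    """Read a delimited claims table into a validated :class:`ClaimsDataset`.

    One row per patient-year; diagnosis and procedure codes are packed in
    single columns separated by ``code_separator``.  Rows violating record
    invariants (non-positive weight, unparsable age/year) are rejected and
    counted in ``dataset.n_rejected`` when ``permissive`` is true, and
    raised otherwise.  A missing mandatory column raises
    :class:`ConfigurationError`.
    """
    columns = dict(DEFAULT_COLUMNS)
    if format_config:
        columns.update(format_config)

    records: list[ClaimRecord] = []
    n_rejected = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in columns.values() if c not in header]
        if missing:
            raise ConfigurationError(f"missing mandatory column(s): {missing}")
        for i, row in enumerate(reader):
            try:
                diag = row[columns["diagnoses"]].strip()
                proc = row[columns["procedures"]].strip()
                records.append(
                    ClaimRecord(
                        patient_id=row[columns["patient_id"]].strip(),
                        age=int(row[columns["age"]]),
                        sex=row[columns["sex"]].strip().upper(),
                        year=int(row[columns["year"]]),
                        low_ses=_parse_bool(row[columns["low_ses"]]),
                        admission=row[columns["admission"]].strip().lower(),
                        weight=float(row[columns["weight"]]),
                        diagnoses=frozenset(
                            c for c in diag.split(code_separator) if c.strip()
                        ),
                        procedures=frozenset(
                            p for p in proc.split(code_separator) if p.strip()
                        ),
                    )
                )
            except (ValueError, ClaimsError) as exc:
                if not permissive:
                    raise ClaimsError(f"row {i + 1}: {exc}") from exc
                n_rejected += 1
    if n_rejected:
        log.warning("read_claims: rejected %d invalid row(s) from %s", n_rejected, path)
    return ClaimsDataset(records=records, provenance=str(path), n_rejected=n_rejected)


def write_claims(
    dataset: ClaimsDataset,
    path,
    *,
    delimiter: str = ",",
    code_separator: str = "|",
) -> None:
    """Write a claims table; round-trips through :func:`read_claims`.

    Code sets are written sorted so output is deterministic; an empty set
    is written as an empty string.
    """
    cols = list(DEFAULT_COLUMNS)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(cols)
        for r in dataset.records:
            writer.writerow(
                [
                    r.patient_id,
                    r.age,
                    r.sex,
                    r.year,
                    int(r.low_ses),
                    r.admission,
                    repr(r.weight),
                    code_separator.join(sorted(r.diagnoses)),
                    code_separator.join(sorted(r.procedures)),
                ]
            )
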