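"""Data model and interchange I/O for Individual Case Safety Reports (ICSRs).

A spontaneous pharmacovigilance report couples one patient with one or more
suspected / co-reported medicinal products and one or more adverse reactions
coded to a controlled terminology.  This module provides:

* pydantic models for reports, drug entries and reaction entries, with the
  structural invariants enforced at construction time;
* a minimal MedDRA-like two-level terminology (Preferred Term -> High Level
  Term) with case-insensitive lookup;
* a drug-class dictionary mapping active ingredients to pharmacological
  classes (shipped default: the three immune-checkpoint-inhibitor classes);
* readers/writers for the flat interchange format (JSON-lines, or CSV with
  the nested lists carried as JSON payloads in two columns).

Reports are the counting unit of every downstream analysis, so the format
keeps exactly one record per report.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

__all__ = [
    "ReporterQualification",
    "Sex",
    "Outcome",
    "DrugRole",
    "DrugEntry",
    "ReactionEntry",
    "IcsrReport",
    "MeddraHierarchy",
    "DrugClassDictionary",
    "SchemaError",
    "IntegrityError",
    "TermLookupError",
    "MalformedRecord",
    "IcsrParseError",
    "normalize_term",
    "normalize_ingredient",
    "parse_icsr_date",
    "default_hierarchy",
    "default_drug_classes",
    "read_reports",
    "write_reports",
    "classify_drug",
    "expand_hlt",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """The interchange file does not conform to the expected schema."""


class IntegrityError(ValueError):
    """A dataset-level invariant (e.g. report_id uniqueness) is violated."""


class TermLookupError(KeyError):
    """A dictionary term (PT, HLT, ingredient or class) failed to resolve."""


@dataclass(frozen=True)
class MalformedRecord:
    line: int
    report_id: Optional[str]
    error: str


class IcsrParseError(ValueError):
    """One or more records failed validation; carries the full list."""

    def __init__(self, records: Sequence[MalformedRecord]):
        self.records = list(records)
        head = "; ".join(
            f"line {r.line}" + (f" (report_id={r.report_id!r})" if r.report_id else "")
            + f": {r.error}"
            for r in self.records[:5]
        )
        more = "" if len(self.records) <= 5 else f" (+{len(self.records) - 5} more)"
        super().__init__(f"{len(self.records)} malformed record(s): {head}{more}")


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class ReporterQualification(str, Enum):
    healthcare_professional = "healthcare_professional"
    consumer = "consumer"
    pharmaceutical_company = "pharmaceutical_company"
    unknown = "unknown"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Outcome(str, Enum):
    fatal = "fatal"
    recovered = "recovered"
    recovering = "recovering"
    recovered_with_sequelae = "recovered_with_sequelae"
    not_recovered = "not_recovered"
    unknown = "unknown"


class DrugRole(str, Enum):
    suspect = "suspect"
    concomitant = "concomitant"
    interacting = "interacting"


# ---------------------------------------------------------------------------
# Normalization helpers
# ---------------------------------------------------------------------------

#: Salt/ester suffixes stripped from ingredient names.  Real-world coding uses
#: the WHODrug standardized product dictionary; for interchange data a small
#: deterministic rule is enough.
_SALT_SUFFIXES = (
    "hydrochloride", "dihydrochloride", "sodium", "potassium", "mesylate",
    "mesilate", "maleate", "tartrate", "citrate", "sulfate", "sulphate",
    "acetate", "phosphate", "besylate", "fumarate", "succinate",
)


def normalize_term(term: str) -> str:
    """Case/whitespace normalization used for all dictionary lookups."""
    return re.sub(r"\s+", " ", term.strip()).lower()


def normalize_ingredient(name: str) -> str:
    """Lowercase, trim, collapse whitespace, strip a trailing salt suffix."""
    norm = normalize_term(name)
    for suffix in _SALT_SUFFIXES:
        if norm.endswith(" " + suffix):
            norm = norm[: -len(suffix) - 1].rstrip()
            break
    return norm


_FULL_DATE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_PARTIAL_DATE = re.compile(r"^(\d{4})-(\d{2})$")


def parse_icsr_date(value: str | date | None) -> tuple[Optional[date], bool]:
    """Parse an ISO date, tolerating partial ``YYYY-MM`` values.

    Partial dates are imputed to day 15 (mid-month) so that interval
    arithmetic remains possible; the second element of the returned tuple is
    True when imputation occurred.
    """
    if value is None or value == "":
        return None, False
    if isinstance(value, date):
        return value, False
    m = _FULL_DATE.match(value)
    if m:
        return date(int(m[1]), int(m[2]), int(m[3])), False
    m = _PARTIAL_DATE.match(value)
    if m:
        return date(int(m[1]), int(m[2]), 15), True
    raise ValueError(f"unparseable date {value!r} (expected YYYY-MM-DD or YYYY-MM)")


# ---------------------------------------------------------------------------
# Report model
# ---------------------------------------------------------------------------

class DrugEntry(BaseModel):
    """One medicinal product on a report.

    Partial dates (YYYY-MM) are accepted and imputed to mid-month for
    interval arithmetic; ``date_imputed`` marks that this happened.  The
    mark is parse-time metadata and is not written back by the interchange
    format (which always carries full dates).
    """

    model_config = ConfigDict(frozen=True)

    ingredient: str
    role: DrugRole = DrugRole.suspect
    start_date: Optional[date] = None
    stop_date: Optional[date] = None
    indication: Optional[str] = None
    date_imputed: bool = False

    @field_validator("ingredient")
    @classmethod
    def _norm_ingredient(cls, v: str) -> str:
        norm = normalize_ingredient(v)
        if not norm:
            raise ValueError("ingredient must be nonempty")
        return norm

    @model_validator(mode="before")
    @classmethod
    def _coerce_dates(cls, data):
        if isinstance(data, dict):
            imputed = bool(data.get("date_imputed", False))
            for key in ("start_date", "stop_date"):
                if key in data:
                    data[key], was_partial = parse_icsr_date(data[key])
                    imputed = imputed or was_partial
            data["date_imputed"] = imputed
        return data

    @model_validator(mode="after")
    def _check_interval(self) -> "DrugEntry":
        if self.start_date and self.stop_date and self.start_date > self.stop_date:
            raise ValueError(
                f"start_date {self.start_date} after stop_date {self.stop_date}"
            )
        return self


class ReactionEntry(BaseModel):
    """One coded adverse reaction on a report."""

    model_config = ConfigDict(frozen=True)

    pt: str
    onset_date: Optional[date] = None
    reaction_outcome: Outcome = Outcome.unknown

    @field_validator("pt")
    @classmethod
    def _strip_pt(cls, v: str) -> str:
        v = re.sub(r"\s+", " ", v.strip())
        if not v:
            raise ValueError("pt must be nonempty")
        return v

    @field_validator("onset_date", mode="before")
    @classmethod
    def _coerce_date(cls, v):
        parsed, _ = parse_icsr_date(v)
        return parsed


class IcsrReport(BaseModel):
    """One Individual Case Safety Report (the counting unit)."""

    model_config = ConfigDict(frozen=True)

    report_id: str
    receipt_date: Optional[date] = None
    country: Optional[str] = None
    reporter_qualification: ReporterQualification = ReporterQualification.unknown
    patient_age: Optional[float] = Field(default=None, ge=0, le=120)
    patient_sex: Sex = Sex.unknown
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[ReactionEntry, ...] = ()
    serious: bool = False
    outcome: Outcome = Outcome.unknown

    @field_validator("report_id")
    @classmethod
    def _check_id(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("report_id must be nonempty")
        return v

    @field_validator("country")
    @classmethod
    def _check_country(cls, v):
        if v is None or v == "":
            return None
        v = v.strip().upper()
        if not re.fullmatch(r"[A-Z]{2}", v):
            raise ValueError(f"country must be ISO-3166 alpha-2, got {v!r}")
        return v

    @field_validator("receipt_date", mode="before")
    @classmethod
    def _coerce_date(cls, v):
        parsed, _ = parse_icsr_date(v)
        return parsed

    @model_validator(mode="after")
    def _check_lists(self) -> "IcsrReport":
        if len(self.drugs) < 1:
            raise ValueError("a report must carry at least one drug entry")
        if len(self.reactions) < 1:
            raise ValueError("a report must carry at least one reaction entry")
        return self

    def suspect_ingredients(self) -> set[str]:
        return {d.ingredient for d in self.drugs if d.role is DrugRole.suspect}

    def reaction_pts(self) -> set[str]:
        return {r.pt for r in self.reactions}


# ---------------------------------------------------------------------------
# Terminologies
# ---------------------------------------------------------------------------

class MeddraHierarchy:
    """Two-level PT -> HLT terminology with case-insensitive lookup.

    A Preferred Term may belong to several High Level Terms (multi-axiality);
    both directions of the mapping are kept consistent.
    """

    def __init__(self, pt_to_hlt: dict[str, Iterable[str]]):
        self._pt_display: dict[str, str] = {}
        self._hlt_display: dict[str, str] = {}
        self.pt_to_hlt: dict[str, set[str]] = {}
        self.hlt_to_pts: dict[str, set[str]] = {}
        for pt, hlts in pt_to_hlt.items():
            hlts = {h for h in hlts}
            if not hlts:
                raise ValueError(f"PT {pt!r} maps to no HLT")
            npt = normalize_term(pt)
            self._pt_display.setdefault(npt, pt)
            for hlt in hlts:
                nhlt = normalize_term(hlt)
                self._hlt_display.setdefault(nhlt, hlt)
                self.pt_to_hlt.setdefault(npt, set()).add(nhlt)
                self.hlt_to_pts.setdefault(nhlt, set()).add(npt)

    # -- lookup -------------------------------------------------------------

    def has_pt(self, pt: str) -> bool:
        return normalize_term(pt) in self.pt_to_hlt

    def has_hlt(self, hlt: str) -> bool:
        return normalize_term(hlt) in self.hlt_to_pts

    def hlts_of(self, pt: str) -> set[str]:
        key = normalize_term(pt)
        if key not in self.pt_to_hlt:
            raise TermLookupError(f"unknown PT {pt!r}")
        return {self._hlt_display[h] for h in self.pt_to_hlt[key]}

    def pts_of(self, hlt: str) -> set[str]:
        key = normalize_term(hlt)
        if key not in self.hlt_to_pts:
            known = ", ".join(sorted(self._hlt_display.values()))
            raise TermLookupError(f"unknown HLT {hlt!r}; known HLTs: {known}")
        return {self._pt_display[p] for p in self.hlt_to_pts[key]}

    @property
    def all_pts(self) -> set[str]:
        return {self._pt_display[p] for p in self.pt_to_hlt}

    @property
    def all_hlts(self) -> set[str]:
        return {self._hlt_display[h] for h in self.hlt_to_pts}

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeddraHierarchy":
        """Load a two-column ``pt,hlt`` CSV (header required)."""
        mapping: dict[str, set[str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"pt", "hlt"} <= set(reader.fieldnames):
                raise SchemaError("hierarchy CSV requires columns 'pt' and 'hlt'")
            for row in reader:
                mapping.setdefault(row["pt"], set()).add(row["hlt"])
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pt", "hlt"])
            for pt in sorted(self.all_pts):
                for hlt in sorted(self.hlts_of(pt)):
                    writer.writerow([pt, hlt])


class DrugClassDictionary:
    """Mapping from pharmacological class name to its member ingredients.

    Classes are pairwise disjoint: an ingredient belongs to at most one class.
    """

    def __init__(self, classes: dict[str, Iterable[str]]):
        self.classes: dict[str, set[str]] = {}
        self._ingredient_to_class: dict[str, str] = {}
        for cls_name, ingredients in classes.items():
            members = {normalize_ingredient(i) for i in ingredients}
            self.classes[cls_name] = members
            for ing in members:
                if ing in self._ingredient_to_class:
                    raise ValueError(
                        f"ingredient {ing!r} assigned to both "
                        f"{self._ingredient_to_class[ing]!r} and {cls_name!r}"
                    )
                self._ingredient_to_class[ing] = cls_name

    def class_of(self, ingredient: str) -> Optional[str]:
        return self._ingredient_to_class.get(normalize_ingredient(ingredient))

    def members(self, class_name: str) -> set[str]:
        if class_name not in self.classes:
            known = ", ".join(sorted(self.classes))
            raise TermLookupError(f"unknown drug class {class_name!r}; known: {known}")
        return set(self.classes[class_name])

    def has_class(self, class_name: str) -> bool:
        return class_name in self.classes

    @property
    def all_ingredients(self) -> set[str]:
        return set(self._ingredient_to_class)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugClassDictionary":
        """Load a two-column ``ingredient,class`` CSV (header required)."""
        mapping: dict[str, set[str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"ingredient", "class"} <= set(
                reader.fieldnames
            ):
                raise SchemaError(
                    "drug-class CSV requires columns 'ingredient' and 'class'"
                )
            for row in reader:
                mapping.setdefault(row["class"], set()).add(row["ingredient"])
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ingredient", "class"])
            for cls_name in sorted(self.classes):
                for ing in sorted(self.classes[cls_name]):
                    writer.writerow([ing, cls_name])


# ---------------------------------------------------------------------------
# Shipped default dictionaries
# ---------------------------------------------------------------------------

#: Organ-specific rejection PTs grouped under the transplant-rejection HLT.
TRANSPLANT_REJECTION_HLT = "Transplant Rejection"

_TRANSPLANT_REJECTION_PTS = (
    "Kidney transplant rejection",
    "Liver transplant rejection",
    "Heart transplant rejection",
    "Lung transplant rejection",
    "Pancreas transplant rejection",
    "Bone marrow transplant rejection",
    "Corneal graft rejection",
    "Skin graft rejection",
    "Transplant rejection",
)

_DEFAULT_OTHER_PTS = {
    "Malignant neoplasm progression": "Neoplasm progression NEC",
    "Acute kidney injury": "Renal failure and impairment",
    "Intentional product use issue": "Product use issues NEC",
    "Diarrhoea": "Gastrointestinal signs and symptoms",
    "Colitis": "Gastrointestinal inflammatory conditions",
    "Nausea": "Gastrointestinal signs and symptoms",
    "Pyrexia": "Body temperature conditions",
    "Fatigue": "Asthenic conditions",
    "Rash": "Rashes NEC",
    "Pruritus": "Pruritus NEC",
    "Pneumonitis": "Lower respiratory tract inflammatory conditions",
    "Hepatitis": "Hepatocellular damage NEC",
    "Hypothyroidism": "Thyroid hypofunction disorders",
    "Hyperthyroidism": "Thyroid hyperfunction disorders",
    "Hypophysitis": "Anterior pituitary hypofunction",
    "Myocarditis": "Noninfectious myocarditis",
    "Arthralgia": "Joint-related signs and symptoms",
    "Vomiting": "Gastrointestinal signs and symptoms",
    "Dyspnoea": "Breathing abnormalities",
    "Headache": "Headaches NEC",
    "Anaemia": "Anaemias NEC",
    "Thrombocytopenia": "Thrombocytopenias",
    "Renal impairment": "Renal failure and impairment",
    "Blood creatinine increased": "Renal function analyses",
    "Drug ineffective": "Therapeutic and nontherapeutic responses",
    "Death": "Death and sudden death",
    "Infusion related reaction": "Administration site reactions NEC",
    "Adrenal insufficiency": "Adrenal cortical hypofunction",
    "Pneumonia": "Lower respiratory tract infections",
    "Interstitial lung disease": "Lower respiratory tract inflammatory conditions",
}


def default_hierarchy() -> MeddraHierarchy:
    """The shipped PT->HLT terminology used by the synthetic data generator."""
    mapping: dict[str, set[str]] = {
        pt: {TRANSPLANT_REJECTION_HLT} for pt in _TRANSPLANT_REJECTION_PTS
    }
    for pt, hlt in _DEFAULT_OTHER_PTS.items():
        mapping[pt] = {hlt}
    return MeddraHierarchy(mapping)


def default_drug_classes() -> DrugClassDictionary:
    """The three immune-checkpoint-inhibitor classes.

    CTLA4i holds the single marketed CTLA4-blocking antibody; PD1i the
    receptor-directed antibodies; PDL1i the ligand-directed ones.
    """
    return DrugClassDictionary(
        {
            "CTLA4i": {"ipilimumab"},
            "PD1i": {
                "cemiplimab",
                "dostarlimab",
                "nivolumab",
                "pembrolizumab",
                "retifanlimab",
                "tislelizumab",
                "toripalimab",
            },
            "PDL1i": {"atezolizumab", "avelumab", "durvalumab"},
        }
    )


# ---------------------------------------------------------------------------
# Classification / expansion operations
# ---------------------------------------------------------------------------

def classify_drug(
    ingredient: str, dictionary: Optional[DrugClassDictionary] = None
) -> Optional[str]:
    """Return the unique class containing *ingredient*, or None if unlisted."""
    if dictionary is None:
        dictionary = default_drug_classes()
    return dictionary.class_of(ingredient)


def expand_hlt(hlt_name: str, hierarchy: Optional[MeddraHierarchy] = None) -> set[str]:
    """Return the full set of Preferred Terms grouped under *hlt_name*."""
    if hierarchy is None:
        hierarchy = default_hierarchy()
    return hierarchy.pts_of(hlt_name)


# ---------------------------------------------------------------------------
# Interchange I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "report_id",
    "receipt_date",
    "country",
    "reporter_qualification",
    "patient_age",
    "patient_sex",
    "serious",
    "outcome",
    "drugs",
    "reactions",
]


def _report_to_obj(report: IcsrReport) -> dict:
    return {
        "report_id": report.report_id,
        "receipt_date": report.receipt_date.isoformat() if report.receipt_date else None,
        "country": report.country,
        "reporter_qualification": report.reporter_qualification.value,
        "patient_age": report.patient_age,
        "patient_sex": report.patient_sex.value,
        "serious": report.serious,
        "outcome": report.outcome.value,
        "drugs": [
            {
                "ingredient": d.ingredient,
                "role": d.role.value,
                "start_date": d.start_date.isoformat() if d.start_date else None,
                "stop_date": d.stop_date.isoformat() if d.stop_date else None,
                "indication": d.indication,
            }
            for d in report.drugs
        ],
        "reactions": [
            {
                "pt": r.pt,
                "onset_date": r.onset_date.isoformat() if r.onset_date else None,
                "reaction_outcome": r.reaction_outcome.value,
            }
            for r in report.reactions
        ],
    }


def _obj_to_report(obj: dict) -> IcsrReport:
    if not isinstance(obj, dict):
        raise ValueError("record is not an object")
    missing = {"report_id", "drugs", "reactions"} - set(obj)
    if missing:
        raise ValueError(f"record missing required field(s): {sorted(missing)}")
    return IcsrReport(**obj)


def write_reports(
    reports: Sequence[IcsrReport],
    path: str | Path,
    format: Literal["csv", "jsonl"] = "jsonl",
) -> None:
    """Serialize reports to the flat interchange format.

    All reports are validated models already, so serialization cannot emit an
    invalid file; a duplicate report_id is rejected before any write.
    """
    seen: set[str] = set()
    for r in reports:
        if r.report_id in seen:
            raise IntegrityError(f"duplicate report_id {r.report_id!r}")
        seen.add(r.report_id)

    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in reports:
                fh.write(json.dumps(_report_to_obj(r), separators=(",", ":")))
                fh.write("\n")
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for r in reports:
                obj = _report_to_obj(r)
                row = {k: obj[k] for k in _CSV_COLUMNS}
                row["drugs"] = json.dumps(obj["drugs"], separators=(",", ":"))
                row["reactions"] = json.dumps(obj["reactions"], separators=(",", ":"))
                row = {k: ("" if v is None else v) for k, v in row.items()}
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_reports(
    path: str | Path,
    format: Literal["csv", "jsonl"] = "jsonl",
    on_malformed: Literal["raise", "collect"] = "raise",
) -> list[IcsrReport] | tuple[list[IcsrReport], list[MalformedRecord]]:
    """Parse an interchange file into report models.

    Malformed records are collected with their line numbers; with the default
    ``on_malformed="raise"`` a nonempty collection raises :class:`IcsrParseError`
    (nothing is silently dropped), while ``"collect"`` returns
    ``(reports, malformed)``.  A duplicate report_id always raises.
    """
    path = Path(path)
    reports: list[IcsrReport] = []
    malformed: list[MalformedRecord] = []
    seen: set[str] = set()

    def handle(obj: dict, line: int) -> None:
        rid = obj.get("report_id") if isinstance(obj, dict) else None
        try:
            report = _obj_to_report(obj)
        except Exception as exc:  # validation detail goes in the record list
            malformed.append(MalformedRecord(line, rid, str(exc)))
            return
        if report.report_id in seen:
            raise IntegrityError(
                f"duplicate report_id {report.report_id!r} at line {line}"
            )
        seen.add(report.report_id)
        reports.append(report)

    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    malformed.append(MalformedRecord(line_no, None, f"bad JSON: {exc}"))
                    continue
                handle(obj, line_no)
    elif format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError("empty CSV: header row required")
            missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise SchemaError(f"missing required column(s): {sorted(missing)}")
            for line_no, row in enumerate(reader, start=2):
                obj = dict(row)
                for key in ("drugs", "reactions"):
                    try:
                        obj[key] = json.loads(obj[key]) if obj[key] else []
                    except json.JSONDecodeError as exc:
                        malformed.append(
                            MalformedRecord(
                                line_no, obj.get("report_id"), f"bad {key} JSON: {exc}"
                            )
                        )
                        obj[key] = None
                if obj.get("drugs") is None or obj.get("reactions") is None:
                    continue
                for key in ("patient_age",):
                    obj[key] = float(obj[key]) if obj.get(key) else None
                obj["serious"] = str(obj.get("serious", "")).lower() in (
                    "true", "1", "yes",
                )
                for key in ("receipt_date", "country"):
                    if obj.get(key) == "":
                        obj[key] = None
                handle(obj, line_no)
    else:
        raise ValueError(f"unknown format {format!r}")

    if on_malformed == "collect":
        return reports, malformed
    if malformed:
        raise IcsrParseError(malformed)
    return reports
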