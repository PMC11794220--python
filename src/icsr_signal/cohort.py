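"""Case selection, exposure classification and descriptive summaries.

The case/non-case design underlying disproportionality analysis needs two
predicates on a report: does it carry the adverse event of interest (case),
and does it carry the exposure of interest.  Both are defined here, together
with the report-level counting conventions:

* the counting unit is always the REPORT — a report with several qualifying
  reactions or several qualifying drugs is counted once;
* exposure requires a drug entry with role ``suspect`` (concomitant
  immunosuppressants are co-reported drugs, not exposures);
* a report carrying suspect drugs from two classes contributes to both
  per-class analyses (and is counted once in the union).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .report_store import (
    DrugClassDictionary,
    DrugRole,
    IcsrReport,
    MeddraHierarchy,
    TermLookupError,
    default_drug_classes,
    default_hierarchy,
    normalize_ingredient,
    normalize_term,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CaseLevel",
    "ExposureLevel",
    "CaseDefinition",
    "ExposureDefinition",
    "DescriptiveSummary",
    "select_cases",
    "case_pt_set",
    "exposed",
    "time_to_onset",
    "summarize",
    "annual_trend",
]


class CaseLevel(str, Enum):
    pt = "pt"
    hlt = "hlt"


class ExposureLevel(str, Enum):
    ingredient = "ingredient"
    drug_class = "class"
    class_union = "class_union"


class CaseDefinition(BaseModel):
    """The adverse event of interest, at PT or HLT level."""

    model_config = ConfigDict(frozen=True)

    level: CaseLevel
    term: str

    @field_validator("term")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("term must be nonempty")
        return v.strip()


class ExposureDefinition(BaseModel):
    """The exposure of interest: ingredients, one class, or a class union."""

    model_config = ConfigDict(frozen=True)

    level: ExposureLevel
    targets: frozenset[str]
    name: Optional[str] = None

    @field_validator("targets", mode="before")
    @classmethod
    def _to_set(cls, v):
        if isinstance(v, str):
            v = [v]
        targets = frozenset(v)
        if not targets:
            raise ValueError("targets must be nonempty")
        return targets

    @property
    def display_name(self) -> str:
        return self.name or "+".join(sorted(self.targets))

    def resolve(self, dictionary: DrugClassDictionary) -> None:
        """Raise TermLookupError if any target is absent from *dictionary*."""
        if self.level is ExposureLevel.ingredient:
            for t in self.targets:
                if normalize_ingredient(t) not in dictionary.all_ingredients:
                    raise TermLookupError(f"unknown ingredient {t!r}")
        else:
            for t in self.targets:
                dictionary.members(t)


def case_pt_set(case_def: CaseDefinition, hierarchy: MeddraHierarchy) -> set[str]:
    """The normalized PT names matching a case definition."""
    if case_def.level is CaseLevel.pt:
        if not hierarchy.has_pt(case_def.term):
            raise TermLookupError(f"unknown PT {case_def.term!r}")
        return {normalize_term(case_def.term)}
    return {normalize_term(pt) for pt in hierarchy.pts_of(case_def.term)}


def _is_case(report: IcsrReport, pt_set: set[str]) -> bool:
    return any(normalize_term(r.pt) in pt_set for r in report.reactions)


def select_cases(
    reports: Sequence[IcsrReport],
    case_def: CaseDefinition,
    hierarchy: Optional[MeddraHierarchy] = None,
) -> list[IcsrReport]:
    """Reports carrying at least one qualifying reaction, each counted once."""
    hierarchy = hierarchy or default_hierarchy()
    pt_set = case_pt_set(case_def, hierarchy)
    out: list[IcsrReport] = []
    seen: set[str] = set()
    for report in reports:
        if report.report_id in seen:
            continue
        if _is_case(report, pt_set):
            out.append(report)
            seen.add(report.report_id)
    return out


def exposed(
    report: IcsrReport,
    exposure_def: ExposureDefinition,
    dictionary: Optional[DrugClassDictionary] = None,
    require_suspect: bool = True,
) -> bool:
    """True iff the report carries a qualifying (by default suspect) drug."""
    dictionary = dictionary or default_drug_classes()
    if exposure_def.level is ExposureLevel.ingredient:
        targets = {normalize_ingredient(t) for t in exposure_def.targets}
    else:
        targets = set()
        for cls_name in exposure_def.targets:
            targets |= dictionary.members(cls_name)
    for drug in report.drugs:
        if require_suspect and drug.role is not DrugRole.suspect:
            continue
        if drug.ingredient in targets:
            return True
    return False


def time_to_onset(
    report: IcsrReport,
    exposure_def: ExposureDefinition,
    dictionary: Optional[DrugClassDictionary] = None,
    case_def: Optional[CaseDefinition] = None,
    hierarchy: Optional[MeddraHierarchy] = None,
) -> Optional[int]:
    """Days from first matching suspect-drug start to first qualifying onset.

    The earliest start date among exposure-matching suspect drugs and the
    earliest onset date among qualifying reactions (all reactions when no
    case definition is given) define the interval.  Returns None when either
    date is missing; a negative interval is inconsistent, logged and likewise
    excluded (None).
    """
    dictionary = dictionary or default_drug_classes()
    if exposure_def.level is ExposureLevel.ingredient:
        targets = {normalize_ingredient(t) for t in exposure_def.targets}
    else:
        targets = set()
        for cls_name in exposure_def.targets:
            targets |= dictionary.members(cls_name)

    starts = [
        d.start_date
        for d in report.drugs
        if d.role is DrugRole.suspect and d.ingredient in targets and d.start_date
    ]
    if case_def is not None:
        pt_set = case_pt_set(case_def, hierarchy or default_hierarchy())
        onsets = [
            r.onset_date
            for r in report.reactions
            if r.onset_date and normalize_term(r.pt) in pt_set
        ]
    else:
        onsets = [r.onset_date for r in report.reactions if r.onset_date]
    if not starts or not onsets:
        return None
    delta = (min(onsets) - min(starts)).days
    if delta < 0:
        logger.warning(
            "report %s: onset %s precedes drug start %s; excluded as inconsistent",
            report.report_id, min(onsets), min(starts),
        )
        return None
    return delta


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

def _pct(n: int, denom: int) -> float:
    return round(100.0 * n / denom, 1) if denom else 0.0


def _quantile_block(values: Sequence[float]) -> Optional[dict]:
    """median / IQR / min–max with the inclusive linear-interpolation rule."""
    if not values:
        return None
    arr = np.asarray(sorted(values), dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    return {
        "n": int(arr.size),
        "median": float(med),
        "iqr": [float(q1), float(q3)],
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


@dataclass
class DescriptiveSummary:
    """Counts, proportions (to one decimal, denominator n_reports or the
    non-missing subset as labelled) and quantile summaries over a case series."""

    n_reports: int
    age: Optional[dict]
    sex_counts: dict[str, int]
    sex_pct: dict[str, float]
    country_counts: dict[str, int]
    reporter_counts: dict[str, int]
    ingredient_counts: dict[str, int]
    ingredient_pct: dict[str, float]
    class_counts: dict[str, int]
    dual_class_count: int
    co_reported_drug_counts: dict[str, int]
    co_reported_pt_counts: dict[str, int]
    outcome_counts: dict[str, int]
    outcome_pct: dict[str, float]
    organ_rejection_counts: dict[str, int]
    organ_rejection_pct: dict[str, float]
    tto_days: Optional[dict]
    annual_counts: dict[int, int]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["annual_counts"] = {str(k): v for k, v in self.annual_counts.items()}
        return d

    def to_text(self) -> str:
        lines = [f"Case series: {self.n_reports} reports"]
        if self.age:
            a = self.age
            lines.append(
                f"  age: median {a['median']:.0f} "
                f"(IQR {a['iqr'][0]:.0f}-{a['iqr'][1]:.0f}, "
                f"min-max {a['min']:.0f}-{a['max']:.0f}, n={a['n']})"
            )
        for sex, n in sorted(self.sex_counts.items(), key=lambda kv: -kv[1]):
            lines.append(f"  sex {sex}: n={n} ({self.sex_pct.get(sex, 0.0)}%)")
        for ing, n in sorted(self.ingredient_counts.items(), key=lambda kv: -kv[1]):
            lines.append(f"  suspect {ing}: n={n} ({self.ingredient_pct[ing]}%)")
        for cls_name, n in sorted(self.class_counts.items(), key=lambda kv: -kv[1]):
            lines.append(f"  class {cls_name}: n={n}")
        lines.append(f"  dual-class reports: n={self.dual_class_count}")
        for out, n in sorted(self.outcome_counts.items(), key=lambda kv: -kv[1]):
            lines.append(f"  outcome {out}: n={n} ({self.outcome_pct[out]}%)")
        for pt, n in sorted(self.organ_rejection_counts.items(), key=lambda kv: -kv[1]):
            lines.append(f"  event {pt}: n={n} ({self.organ_rejection_pct[pt]}%)")
        if self.tto_days:
            t = self.tto_days
            lines.append(
                f"  time to onset: median {t['median']:.0f} d "
                f"(IQR {t['iqr'][0]:.0f}-{t['iqr'][1]:.0f}, "
                f"min-max {t['min']:.0f}-{t['max']:.0f}, n={t['n']})"
            )
        return "\n".join(lines)


def summarize(
    cases: Sequence[IcsrReport],
    exposure_def: Optional[ExposureDefinition] = None,
    dictionary: Optional[DrugClassDictionary] = None,
    hierarchy: Optional[MeddraHierarchy] = None,
    case_def: Optional[CaseDefinition] = None,
    top_n: int = 15,
) -> DescriptiveSummary:
    """Descriptive statistics over a (nonempty) case series.

    Proportions use ``n_reports`` as denominator except sex, which uses the
    non-missing count; quantiles use linear interpolation between order
    statistics.
    """
    if not cases:
        raise ValueError("cannot summarize an empty case list")
    dictionary = dictionary or default_drug_classes()
    hierarchy = hierarchy or default_hierarchy()
    n = len(cases)

    ages = [r.patient_age for r in cases if r.patient_age is not None]
    sex_counts: dict[str, int] = {}
    country_counts: dict[str, int] = {}
    reporter_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    annual: dict[int, int] = {}
    for r in cases:
        if r.patient_sex.value != "unknown":
            sex_counts[r.patient_sex.value] = sex_counts.get(r.patient_sex.value, 0) + 1
        if r.country:
            country_counts[r.country] = country_counts.get(r.country, 0) + 1
        q = r.reporter_qualification.value
        reporter_counts[q] = reporter_counts.get(q, 0) + 1
        outcome_counts[r.outcome.value] = outcome_counts.get(r.outcome.value, 0) + 1
        if r.receipt_date:
            annual[r.receipt_date.year] = annual.get(r.receipt_date.year, 0) + 1

    n_sex = sum(sex_counts.values())
    sex_pct = {k: _pct(v, n_sex) for k, v in sex_counts.items()}

    # suspect classified ingredients vs co-reported (non-classified) drugs,
    # counted once per report
    ingredient_counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    co_drug_counts: dict[str, int] = {}
    dual = 0
    for r in cases:
        classified_ings: set[str] = set()
        classes: set[str] = set()
        co: set[str] = set()
        for d in r.drugs:
            cls_name = dictionary.class_of(d.ingredient)
            if cls_name and d.role is DrugRole.suspect:
                classified_ings.add(d.ingredient)
                classes.add(cls_name)
            else:
                co.add(d.ingredient)
        for ing in classified_ings:
            ingredient_counts[ing] = ingredient_counts.get(ing, 0) + 1
        for cls_name in classes:
            class_counts[cls_name] = class_counts.get(cls_name, 0) + 1
        if len(classes) > 1:
            dual += 1
        for ing in co:
            co_drug_counts[ing] = co_drug_counts.get(ing, 0) + 1

    # qualifying (organ-specific) event PTs vs co-reported PTs
    pt_set = case_pt_set(case_def, hierarchy) if case_def else None
    organ_counts: dict[str, int] = {}
    co_pt_counts: dict[str, int] = {}
    for r in cases:
        qualifying: set[str] = set()
        others: set[str] = set()
        for reac in r.reactions:
            key = normalize_term(reac.pt)
            if pt_set is not None and key in pt_set:
                qualifying.add(reac.pt)
            else:
                others.add(reac.pt)
        for pt in qualifying:
            organ_counts[pt] = organ_counts.get(pt, 0) + 1
        for pt in others:
            co_pt_counts[pt] = co_pt_counts.get(pt, 0) + 1

    ttos: list[int] = []
    if exposure_def is not None:
        for r in cases:
            t = time_to_onset(r, exposure_def, dictionary, case_def, hierarchy)
            if t is not None:
                ttos.append(t)

    def top(d: dict[str, int]) -> dict[str, int]:
        return dict(sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n])

    return DescriptiveSummary(
        n_reports=n,
        age=_quantile_block(ages),
        sex_counts=sex_counts,
        sex_pct=sex_pct,
        country_counts=top(country_counts),
        reporter_counts=reporter_counts,
        ingredient_counts=ingredient_counts,
        ingredient_pct={k: _pct(v, n) for k, v in ingredient_counts.items()},
        class_counts=class_counts,
        dual_class_count=dual,
        co_reported_drug_counts=top(co_drug_counts),
        co_reported_pt_counts=top(co_pt_counts),
        outcome_counts=outcome_counts,
        outcome_pct={k: _pct(v, n) for k, v in outcome_counts.items()},
        organ_rejection_counts=organ_counts,
        organ_rejection_pct={k: _pct(v, n) for k, v in organ_counts.items()},
        tto_days=_quantile_block(ttos),
        annual_counts=dict(sorted(annual.items())),
    )


def annual_trend(cases: Sequence[IcsrReport]) -> dict[int, dict[str, float]]:
    """Report counts and percentage of the total by receipt year."""
    counts: dict[int, int] = {}
    for r in cases:
        if r.receipt_date is None:
            raise ValueError(f"report {r.report_id} lacks a receipt_date")
        counts[r.receipt_date.year] = counts.get(r.receipt_date.year, 0) + 1
    total = sum(counts.values())
    return {
        year: {"count": n, "pct": _pct(n, total)}
        for year, n in sorted(counts.items())
    }
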