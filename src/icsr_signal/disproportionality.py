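"""Disproportionality statistics for case/non-case pharmacovigilance designs.

Two measures are implemented on the 2x2 report-count table

    =============  =========  =============
                   event      no event
    exposed        a          b
    not exposed    c          d
    =============  =========  =============

* the **information component** (IC) of the Bayesian confidence propagation
  neural network: ``IC = log2((O + 1/2) / (E + 1/2))`` where ``O = a`` is the
  observed count and ``E = (a+b)(a+c)/N`` the count expected under
  independence of exposure and event.  The 1/2 offsets act as Bayesian
  shrinkage, keeping the measure finite and pulling small-count signals
  toward zero.  The 95% credible interval takes the 2.5% and 97.5% quantiles
  of the Gamma(O + 1/2, rate E + 1/2) posterior of the observed-to-expected
  ratio, on the log2 scale.  The conventional signal threshold is a lower
  credible bound above zero.

* the **reporting odds ratio** (ROR) ``a*d / (b*c)`` with Woolf's log-scale
  interval ``exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d))`` and the
  corresponding two-sided Wald test.  When any cell is zero the
  Haldane–Anscombe correction (add 1/2 to every cell) is applied and flagged.

The comparative (head-to-head) ROR restricts the universe to reports exposed
to exactly one of two drug classes, so the contrast is not diluted by
reports exposed to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import pandas as pd
from scipy import stats

from .cohort import (
    CaseDefinition,
    ExposureDefinition,
    ExposureLevel,
    case_pt_set,
    exposed,
)
from .report_store import (
    DrugClassDictionary,
    IcsrReport,
    MeddraHierarchy,
    default_drug_classes,
    default_hierarchy,
    normalize_term,
)

__all__ = [
    "Z_975",
    "ContingencyTable",
    "DisproportionalityResult",
    "RorResult",
    "expected_count",
    "information_component",
    "ic_credible_bounds",
    "signal_flag",
    "disproportionality",
    "ror",
    "build_table",
    "comparative_ror",
    "run_screen",
]

#: Fixed 97.5% standard-normal quantile (reproducibility over platform
#: quantile functions).
Z_975 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case exposure cross-tabulation of report counts."""

    a: int  # exposure and event
    b: int  # exposure, no event
    c: int  # event, no exposure
    d: int  # neither

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty contingency table (N=0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_adr(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        return expected_count(self.n_drug, self.n_adr, self.n)


@dataclass(frozen=True)
class DisproportionalityResult:
    """Observed/expected counts with the IC and its credible interval."""

    O: int
    E: float
    ic: float
    ic025: float
    ic975: float
    signal: bool

    def rounded(self) -> dict:
        """Display convention: IC and bounds to one decimal."""
        return {
            "O": self.O,
            "E": round(self.E, 1),
            "ic": round(self.ic, 1),
            "ic025": round(self.ic025, 1),
            "ic975": round(self.ic975, 1),
            "signal": self.signal,
        }


@dataclass(frozen=True)
class RorResult:
    """Reporting odds ratio with Woolf interval and Wald test."""

    ror: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    correction_applied: bool
    table: Optional[ContingencyTable] = None


def expected_count(n_drug: int, n_adr: int, n_total: int) -> float:
    """Expected report count under exposure/event independence.

    ``E = n_drug * n_adr / N`` at full floating precision.  A zero margin
    yields E = 0, a degenerate table for which only the shrinkage offsets
    keep the IC defined.
    """
    if n_total <= 0:
        raise ValueError("database size N must be positive")
    if n_drug < 0 or n_adr < 0 or max(n_drug, n_adr) > n_total:
        raise ValueError(
            f"margins must satisfy 0 <= n_drug, n_adr <= N "
            f"(got n_drug={n_drug}, n_adr={n_adr}, N={n_total})"
        )
    return n_drug * n_adr / n_total


def information_component(observed: float, expected: float) -> float:
    """IC point estimate ``log2((O + 1/2)/(E + 1/2))``."""
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected counts must be non-negative")
    return math.log2((observed + 0.5) / (expected + 0.5))


def ic_credible_bounds(
    observed: float, expected: float, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed credible bounds of the IC from the Gamma posterior.

    The observed-to-expected ratio has posterior Gamma(shape ``O + 1/2``,
    rate ``E + 1/2``); the bounds are the log2 of its (1-level)/2 and
    (1+level)/2 quantiles.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    alpha = (1.0 - level) / 2.0
    shape = observed + 0.5
    rate = expected + 0.5
    lo, hi = stats.gamma.ppf([alpha, 1.0 - alpha], shape, scale=1.0 / rate)
    return math.log2(lo), math.log2(hi)


def signal_flag(ic025: float) -> bool:
    """Conventional signal rule: strictly positive lower credible bound."""
    return ic025 > 0.0


def disproportionality(
    observed: int, expected: float, level: float = 0.95
) -> DisproportionalityResult:
    """IC, credible interval and signal flag for one drug–event pair."""
    ic = information_component(observed, expected)
    lo, hi = ic_credible_bounds(observed, expected, level)
    return DisproportionalityResult(
        O=observed, E=expected, ic=ic, ic025=lo, ic975=hi, signal=signal_flag(lo)
    )


def ror(table: ContingencyTable) -> RorResult:
    """Reporting odds ratio with Woolf 95% interval and two-sided Wald p.

    A zero cell triggers the Haldane–Anscombe correction (0.5 added to all
    four cells), flagged in the result.  Two empty margins leave the odds
    ratio undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        raise ValueError("a zero margin leaves the odds ratio undefined")
    correction = 0 in (a, b, c, d)
    if correction:
        fa, fb, fc, fd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    estimate = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    log_ror = math.log(estimate)
    ci_low = math.exp(log_ror - Z_975 * se)
    ci_high = math.exp(log_ror + Z_975 * se)
    z = log_ror / se
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return RorResult(
        ror=estimate, ci_low=ci_low, ci_high=ci_high, z=z, p=p,
        correction_applied=correction, table=table,
    )


# ---------------------------------------------------------------------------
# Report-level table construction and screening
# ---------------------------------------------------------------------------

def build_table(
    reports: Sequence[IcsrReport],
    exposure_def: ExposureDefinition,
    case_def: CaseDefinition,
    dictionary: Optional[DrugClassDictionary] = None,
    hierarchy: Optional[MeddraHierarchy] = None,
) -> ContingencyTable:
    """Cross-tabulate a report universe by exposure and event status."""
    dictionary = dictionary or default_drug_classes()
    hierarchy = hierarchy or default_hierarchy()
    pt_set = case_pt_set(case_def, hierarchy)
    a = b = c = d = 0
    for report in reports:
        is_case = any(normalize_term(r.pt) in pt_set for r in report.reactions)
        is_exposed = exposed(report, exposure_def, dictionary)
        if is_exposed and is_case:
            a += 1
        elif is_exposed:
            b += 1
        elif is_case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def comparative_ror(
    reports: Sequence[IcsrReport],
    class_a: str,
    class_b: str,
    case_def: CaseDefinition,
    dictionary: Optional[DrugClassDictionary] = None,
    hierarchy: Optional[MeddraHierarchy] = None,
    include_dual: bool = False,
) -> RorResult:
    """Head-to-head ROR of *class_a* versus *class_b* for the case event.

    The universe is restricted to reports exposed to exactly one of the two
    classes (dual-exposed reports are uninformative for the contrast and are
    excluded unless ``include_dual``, in which case they count in both arms).
    """
    dictionary = dictionary or default_drug_classes()
    hierarchy = hierarchy or default_hierarchy()
    for cls_name in (class_a, class_b):
        dictionary.members(cls_name)
    pt_set = case_pt_set(case_def, hierarchy)
    def_a = ExposureDefinition(level=ExposureLevel.drug_class, targets=[class_a])
    def_b = ExposureDefinition(level=ExposureLevel.drug_class, targets=[class_b])
    a = b = c = d = 0
    for report in reports:
        in_a = exposed(report, def_a, dictionary)
        in_b = exposed(report, def_b, dictionary)
        if not (in_a or in_b):
            continue
        if in_a and in_b and not include_dual:
            continue
        is_case = any(normalize_term(r.pt) in pt_set for r in report.reactions)
        if in_a:
            a += is_case
            b += not is_case
        if in_b:
            c += is_case
            d += not is_case
    if c + d == 0:
        raise ValueError(
            f"empty comparator arm {class_b!r}: no singly-exposed reports; "
            "consider a wider comparator class (a zero CELL would instead be "
            "handled by the Haldane-Anscombe correction)"
        )
    if a + b == 0:
        raise ValueError(f"empty exposure arm {class_a!r}: no singly-exposed reports")
    return ror(ContingencyTable(a, b, c, d))


def run_screen(
    reports: Sequence[IcsrReport],
    exposures: Sequence[ExposureDefinition],
    case_def: CaseDefinition,
    dictionary: Optional[DrugClassDictionary] = None,
    hierarchy: Optional[MeddraHierarchy] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """One IC row per exposure definition against the full report universe.

    Expected counts use the complete database as denominator, so rows for
    overlapping exposures (e.g. a class union next to its member classes)
    are each computed against the same universe.
    """
    dictionary = dictionary or default_drug_classes()
    hierarchy = hierarchy or default_hierarchy()
    rows = []
    for exp_def in exposures:
        table = build_table(reports, exp_def, case_def, dictionary, hierarchy)
        res = disproportionality(table.a, table.expected, level)
        rows.append(
            {
                "exposure": exp_def.display_name,
                "O": res.O,
                "E": res.E,
                "IC": res.ic,
                "IC025": res.ic025,
                "IC975": res.ic975,
                "signal": res.signal,
            }
        )
    return pd.DataFrame(
        rows, columns=["exposure", "O", "E", "IC", "IC025", "IC975", "signal"]
    )
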