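"""Synthetic spontaneous-report datasets with known ground truth.

Access to the WHO global pharmacovigilance database is restricted, so every
pipeline stage here is exercised on generated data that emulates its
structure: one record per report, a long-tailed multinomial drug exposure,
adverse-event terms assigned at configurable base rates, and drug–event
associations planted at known strength.

Two planting mechanisms are supported:

``rate``
    The conditional probability of the event given a matching exposure is
    the base rate multiplied by the reporting-rate ratio ``rate_ratio``
    (lambda).  Event assignment stays Bernoulli, so realized counts carry
    binomial noise around their expectation; a product exceeding 1 is
    rejected at validation time.

``count``
    Exactly ``n_events`` matching reports, chosen uniformly at random,
    receive the event (conditional-on-target simulation).  Base-rate draws
    of the event terms are suppressed for matching reports so the planted
    count is exact.  This is the mode used by :func:`paper_calibrated_config`,
    where the point of the exercise is a database whose screen realizes a
    known observed/expected table.

For every non-planted drug–event pair, assignment is independent of
exposure by construction.  The generator is fully deterministic given the
configuration seed, and returns alongside the reports a ground-truth ledger
holding the realized 2x2 table of each planted signal.
"""

from __future__ import annotations

import gc
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .report_store import (
    DrugEntry,
    DrugRole,
    IcsrReport,
    Outcome,
    ReactionEntry,
    ReporterQualification,
    Sex,
    TRANSPLANT_REJECTION_HLT,
    default_hierarchy,
    normalize_ingredient,
)

__all__ = [
    "DrugSpec",
    "AdrSpec",
    "ComboRule",
    "PlantedSignal",
    "TtoModel",
    "SyntheticConfig",
    "GroundTruth",
    "SignalTruth",
    "generate",
    "null_config",
    "paper_calibrated_config",
]

_Z_75 = 0.6744897501960817  # 75% standard-normal quantile


class DrugSpec(BaseModel):
    """One catalog drug: sampling weight and suspect-role probability.

    ``draw="multinomial"`` drugs form the long-tailed background: each
    report draws 1-4 of them without replacement with probability
    proportional to ``marginal``.  ``draw="bernoulli"`` drugs (typically
    the exposures under study) are included independently with probability
    exactly ``marginal``, which keeps their report margins — and hence the
    expected counts of planted signals — analytically controlled.
    """

    model_config = ConfigDict(frozen=True)

    ingredient: str
    marginal: float = Field(gt=0, lt=1)
    suspect_prob: float = Field(default=0.9, ge=0, le=1)
    draw: Literal["multinomial", "bernoulli"] = "multinomial"

    @field_validator("ingredient")
    @classmethod
    def _norm(cls, v: str) -> str:
        return normalize_ingredient(v)


class AdrSpec(BaseModel):
    """One event-eligible PT with its per-report base probability."""

    model_config = ConfigDict(frozen=True)

    pt: str
    base_prob: float = Field(gt=0, lt=1)


class ComboRule(BaseModel):
    """Explicit co-prescription rule: reports carrying any trigger drug
    additionally receive *add* with probability *prob*."""

    model_config = ConfigDict(frozen=True)

    trigger: frozenset[str]
    add: str
    prob: float = Field(ge=0, le=1)

    @field_validator("trigger", mode="before")
    @classmethod
    def _norm_trigger(cls, v):
        return frozenset(normalize_ingredient(x) for x in v)

    @field_validator("add")
    @classmethod
    def _norm_add(cls, v: str) -> str:
        return normalize_ingredient(v)


class PlantedSignal(BaseModel):
    """A drug–event association planted into the dataset.

    A report matches when its suspect ingredients contain at least one of
    ``match_any``, all of ``match_all`` and none of ``match_none``.  The
    event is a PT, or an HLT whose member PTs are drawn by ``pt_weights``.
    Exactly one of ``rate_ratio`` (rate mode) / ``n_events`` (count mode)
    is used, according to the configuration's planting mode.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    match_any: frozenset[str]
    match_all: frozenset[str] = frozenset()
    match_none: frozenset[str] = frozenset()
    event: str
    level: Literal["pt", "hlt"] = "pt"
    rate_ratio: Optional[float] = Field(default=None, gt=0)
    n_events: Optional[int] = Field(default=None, ge=0)
    pt_weights: Optional[dict[str, float]] = None

    @field_validator("match_any", "match_all", "match_none", mode="before")
    @classmethod
    def _norm_sets(cls, v):
        return frozenset(normalize_ingredient(x) for x in v)

    @model_validator(mode="after")
    def _check(self) -> "PlantedSignal":
        if not self.match_any:
            raise ValueError("match_any must be nonempty")
        if self.rate_ratio is None and self.n_events is None:
            raise ValueError("a planted signal needs rate_ratio or n_events")
        return self


class TtoModel(BaseModel):
    """Log-normal time-to-onset, parameterized by median and IQR (days).

    The quartile ratio fixes sigma: ``sigma = ln(q3/q1) / (2 z_0.75)``;
    the median fixes mu.
    """

    model_config = ConfigDict(frozen=True)

    median_days: float = Field(default=28.0, gt=0)
    iqr_days: tuple[float, float] = (16.0, 60.0)

    @model_validator(mode="after")
    def _check(self) -> "TtoModel":
        q1, q3 = self.iqr_days
        if not 0 < q1 <= self.median_days <= q3:
            raise ValueError("IQR must bracket the median")
        return self

    @property
    def mu(self) -> float:
        return math.log(self.median_days)

    @property
    def sigma(self) -> float:
        q1, q3 = self.iqr_days
        return math.log(q3 / q1) / (2.0 * _Z_75)


def _prob_dict(d: dict[str, float], what: str) -> dict[str, float]:
    total = sum(d.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"{what} probabilities must sum to 1 (got {total})")
    return d


class SyntheticConfig(BaseModel):
    """Full specification of one synthetic dataset (seed mandatory)."""

    model_config = ConfigDict(frozen=True)

    n_reports: int = Field(gt=0)
    seed: int
    drug_catalog: tuple[DrugSpec, ...]
    adr_catalog: tuple[AdrSpec, ...]
    filler_pts: dict[str, float]
    planted_signals: tuple[PlantedSignal, ...] = ()
    planting: Literal["rate", "count"] = "rate"
    combo_rules: tuple[ComboRule, ...] = ()
    drug_count_probs: dict[int, float] = Field(
        default={1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}
    )
    filler_count_probs: dict[int, float] = Field(default={1: 0.7, 2: 0.3})
    age_mean: float = 61.5
    age_sd: float = 12.5
    age_missing_prob: float = 0.08
    sex_probs: dict[str, float] = Field(
        default={"male": 0.52, "female": 0.45, "unknown": 0.03}
    )
    country_probs: dict[str, float] = Field(default={"US": 0.5, "FR": 0.2, "JP": 0.3})
    reporter_probs: dict[str, float] = Field(
        default={
            "healthcare_professional": 0.85,
            "consumer": 0.10,
            "pharmaceutical_company": 0.04,
            "unknown": 0.01,
        }
    )
    outcome_probs: dict[str, float] = Field(
        default={
            "fatal": 0.03,
            "recovered": 0.35,
            "recovering": 0.12,
            "recovered_with_sequelae": 0.03,
            "not_recovered": 0.17,
            "unknown": 0.30,
        }
    )
    case_outcome_probs: Optional[dict[str, float]] = None
    serious_prob: float = 0.4
    year_weights: dict[int, float] = Field(
        default={y: w for y, w in zip(range(2015, 2024), (1, 2, 3, 5, 7, 9, 11, 13, 15))}
    )
    tto: TtoModel = TtoModel()
    drug_date_missing_prob: float = 0.25
    case_drug_date_missing_prob: float = 0.15
    onset_missing_prob: float = 0.10

    @field_validator(
        "sex_probs", "reporter_probs", "outcome_probs", "country_probs",
        "drug_count_probs", "filler_count_probs",
    )
    @classmethod
    def _check_probs(cls, v, info):
        return _prob_dict(v, info.field_name)

    @model_validator(mode="after")
    def _check_feasibility(self) -> "SyntheticConfig":
        if not self.filler_pts:
            raise ValueError("filler_pts must be nonempty (guarantees >=1 reaction)")
        if not any(d.draw == "multinomial" for d in self.drug_catalog):
            raise ValueError(
                "drug_catalog needs at least one multinomial (background) drug "
                "so every report carries >=1 drug"
            )
        base = {spec.pt: spec.base_prob for spec in self.adr_catalog}
        catalog_ings = {d.ingredient for d in self.drug_catalog}
        for sig in self.planted_signals:
            for ing in sig.match_any | sig.match_all | sig.match_none:
                if ing not in catalog_ings:
                    raise ValueError(
                        f"signal {sig.name!r} references {ing!r}, not in drug_catalog"
                    )
            if self.planting == "rate":
                if sig.rate_ratio is None:
                    raise ValueError(f"signal {sig.name!r} lacks rate_ratio")
                for pt in self._event_pts(sig):
                    if pt not in base:
                        raise ValueError(
                            f"signal {sig.name!r} event PT {pt!r} not in adr_catalog"
                        )
                    if base[pt] * sig.rate_ratio > 1.0:
                        raise ValueError(
                            f"infeasible signal {sig.name!r}: rate_ratio "
                            f"{sig.rate_ratio} pushes P({pt!r}) above 1"
                        )
            else:
                if sig.n_events is None:
                    raise ValueError(f"signal {sig.name!r} lacks n_events")
        if self.case_outcome_probs is not None:
            _prob_dict(self.case_outcome_probs, "case_outcome_probs")
        return self

    def _event_pts(self, sig: PlantedSignal) -> list[str]:
        if sig.level == "pt":
            return [sig.event]
        if sig.pt_weights:
            return list(sig.pt_weights)
        hierarchy = default_hierarchy()
        return sorted(hierarchy.pts_of(sig.event))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalTruth:
    """Realized case/non-case table of one planted signal."""

    name: str
    event_pts: tuple[str, ...]
    mode: str
    rate_ratio: Optional[float]
    n_planted: int
    a: int
    b: int
    c: int
    d: int

    @property
    def n_exposed(self) -> int:
        return self.a + self.b


@dataclass
class GroundTruth:
    """Generation bookkeeping: realized margins and planted-signal tables."""

    n_reports: int
    seed: int
    signals: list[SignalTruth]
    ingredient_margins: dict[str, int]
    event_report_counts: dict[str, int]  # per event term (PT set union), all causes
    case_report_ids: dict[str, list[str]]  # per signal: planted case ids

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "seed": self.seed,
            "signals": [
                {
                    "name": s.name,
                    "event_pts": list(s.event_pts),
                    "mode": s.mode,
                    "rate_ratio": s.rate_ratio,
                    "n_planted": s.n_planted,
                    "table": {"a": s.a, "b": s.b, "c": s.c, "d": s.d},
                }
                for s in self.signals
            ],
            "ingredient_margins": self.ingredient_margins,
            "event_report_counts": self.event_report_counts,
            "case_report_ids": self.case_report_ids,
        }


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _categorical(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray(keys, dtype=object)[idx]


# one fields-set per model class, shared across instances: the generator
# always passes every field, and frozen models never mutate the set
_ALL_FIELDS: dict[type, set[str]] = {}


def _fast_construct(cls, values: dict):
    """Construction bypass for pre-validated complete field dicts (hot loop).

    Equivalent to ``cls.model_construct(**values)`` with all fields given;
    falls back to it if the fast path ever disagrees (guarded at import by
    :data:`_FAST_OK`).
    """
    fields = _ALL_FIELDS.get(cls)
    if fields is None:
        fields = _ALL_FIELDS[cls] = set(cls.model_fields)
    obj = object.__new__(cls)
    object.__setattr__(obj, "__dict__", values)
    object.__setattr__(obj, "__pydantic_fields_set__", fields)
    object.__setattr__(obj, "__pydantic_extra__", None)
    object.__setattr__(obj, "__pydantic_private__", None)
    return obj


def _fast_path_ok() -> bool:
    probe = dict(pt="x", onset_date=None, reaction_outcome=Outcome.unknown)
    try:
        fast = _fast_construct(ReactionEntry, dict(probe))
        ref = ReactionEntry.model_construct(**probe)
        return fast == ref and fast.pt == "x"
    except Exception:
        return False


_FAST_OK = _fast_path_ok()


def _construct(cls, **values):
    if _FAST_OK:
        return _fast_construct(cls, values)
    return cls.model_construct(**values)


def _group_rows(matrix: np.ndarray) -> list[np.ndarray]:
    """Per-row column indices of a boolean matrix (one nonzero pass)."""
    rows, cols = np.nonzero(matrix)
    splits = np.searchsorted(rows, np.arange(1, matrix.shape[0]))
    return np.split(cols, splits)


def _match_mask(
    sig: PlantedSignal, suspect: np.ndarray, col: dict[str, int]
) -> np.ndarray:
    """Boolean mask of reports whose suspect ingredients match the signal."""
    n = suspect.shape[0]
    any_mask = np.zeros(n, dtype=bool)
    for ing in sig.match_any:
        any_mask |= suspect[:, col[ing]]
    mask = any_mask
    for ing in sig.match_all:
        mask = mask & suspect[:, col[ing]]
    for ing in sig.match_none:
        mask = mask & ~suspect[:, col[ing]]
    return mask


def generate(
    config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[list[IcsrReport], GroundTruth]:
    """Generate a synthetic report list plus its ground-truth ledger.

    Deterministic given ``(config, seed)``; ``seed`` overrides the
    configuration seed when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    drugs = config.drug_catalog
    n_drugs = len(drugs)
    col = {d.ingredient: i for i, d in enumerate(drugs)}

    # --- drug draw.  Background (multinomial) drugs: k_i of them without
    # replacement, weight proportional to the catalog marginal, via the
    # Gumbel-top-k trick.  Bernoulli drugs: independent inclusion at exactly
    # their marginal probability.
    multi_idx = np.asarray(
        [i for i, d in enumerate(drugs) if d.draw == "multinomial"], dtype=int
    )
    bern_idx = np.asarray(
        [i for i, d in enumerate(drugs) if d.draw == "bernoulli"], dtype=int
    )
    present = np.zeros((n, n_drugs), dtype=bool)
    first_multi = np.zeros(n, dtype=int)
    if multi_idx.size:
        logw = np.log(np.asarray([drugs[i].marginal for i in multi_idx]))
        count_keys = sorted(config.drug_count_probs)
        k_per_report = _categorical(
            rng, {k: config.drug_count_probs[k] for k in count_keys}, n
        ).astype(int)
        # a report cannot draw more distinct drugs than the catalog holds
        k_per_report = np.minimum(k_per_report, multi_idx.size)
        kmax = min(int(max(count_keys)), int(multi_idx.size))
        gumbel = rng.gumbel(size=(n, multi_idx.size))
        order = np.argsort(-(logw[None, :] + gumbel), axis=1, kind="stable")[:, :kmax]
        rows = np.repeat(np.arange(n), k_per_report)
        cols = order[rows, np.concatenate([np.arange(k) for k in k_per_report])]
        present[rows, multi_idx[cols]] = True
        first_multi = multi_idx[order[:, 0]]
    else:
        kmax = 1
    if bern_idx.size:
        bern_p = np.asarray([drugs[i].marginal for i in bern_idx])
        present[:, bern_idx] = rng.random((n, bern_idx.size)) < bern_p[None, :]

    # --- explicit co-prescription rules
    for rule in config.combo_rules:
        trigger = np.zeros(n, dtype=bool)
        for ing in rule.trigger:
            trigger |= present[:, col[ing]]
        hit = trigger & (rng.random(n) < rule.prob)
        present[hit, col[rule.add]] = True

    # --- roles
    suspect_probs = np.asarray([d.suspect_prob for d in drugs])
    suspect = present & (rng.random((n, n_drugs)) < suspect_probs[None, :])
    # a report whose every drug drew the concomitant role keeps its first
    # background drug as suspect (spontaneous reports name at least one suspect)
    no_suspect = present.any(axis=1) & ~suspect.any(axis=1)
    suspect[no_suspect, first_multi[no_suspect]] = True

    # --- event assignment
    adr_pts = [spec.pt for spec in config.adr_catalog]
    adr_col = {pt: j for j, pt in enumerate(adr_pts)}
    base = np.asarray([spec.base_prob for spec in config.adr_catalog])
    prob_matrix = np.broadcast_to(base, (n, len(adr_pts))).copy()

    sig_masks = [_match_mask(sig, suspect, col) for sig in config.planted_signals]
    planted_case_ids: dict[str, list[int]] = {s.name: [] for s in config.planted_signals}
    planted_pt: dict[int, str] = {}  # report row -> planted event PT

    if config.planting == "rate":
        for sig, mask in zip(config.planted_signals, sig_masks):
            for pt in config._event_pts(sig):
                j = adr_col[pt]
                # overlapping signals on the same pair: strongest boost wins
                prob_matrix[mask, j] = np.maximum(
                    prob_matrix[mask, j], base[j] * sig.rate_ratio
                )
        events = rng.random((n, len(adr_pts))) < prob_matrix
    else:
        # count mode: the planted counts fully determine event placement
        # among exposure-drug reports, so base-rate draws of the planted
        # event PTs are suppressed for every report suspect-exposed to any
        # signal ingredient (not just predicate matches: a report exposed to
        # two arms at once must not pick the event up by chance either)
        events = rng.random((n, len(adr_pts))) < prob_matrix
        suppressed = np.zeros(n, dtype=bool)
        planted_cols: set[int] = set()
        signal_ings: set[str] = set()
        for sig in config.planted_signals:
            signal_ings |= set(sig.match_any) | set(sig.match_all)
            for pt in config._event_pts(sig):
                if pt in adr_col:
                    planted_cols.add(adr_col[pt])
        for ing in signal_ings:
            suppressed |= suspect[:, col[ing]]
        for j in planted_cols:
            events[suppressed, j] = False
        for sig, mask in zip(config.planted_signals, sig_masks):
            pool = np.flatnonzero(mask)
            if sig.n_events > pool.size:
                raise ValueError(
                    f"signal {sig.name!r}: n_events={sig.n_events} exceeds the "
                    f"{pool.size} matching reports"
                )
            chosen = rng.choice(pool, size=sig.n_events, replace=False)
            pts = config._event_pts(sig)
            if sig.pt_weights:
                w = np.asarray([sig.pt_weights[pt] for pt in pts], dtype=float)
                w = w / w.sum()
                picks = rng.choice(len(pts), size=sig.n_events, p=w)
            else:
                picks = rng.integers(0, len(pts), size=sig.n_events)
            for row, pick in zip(chosen.tolist(), picks.tolist()):
                pt = pts[pick]
                planted_pt[row] = pt
                if pt in adr_col:
                    events[row, adr_col[pt]] = True
                planted_case_ids[sig.name].append(row)

    # --- filler reactions (guarantee >=1 reaction per report)
    filler_names = list(config.filler_pts)
    fw = np.asarray([config.filler_pts[p] for p in filler_names], dtype=float)
    log_fw = np.log(fw / fw.sum())
    fill_keys = sorted(config.filler_count_probs)
    kf = _categorical(
        rng, {k: config.filler_count_probs[k] for k in fill_keys}, n
    ).astype(int)
    fgum = rng.gumbel(size=(n, len(filler_names)))
    forder = np.argsort(-(log_fw[None, :] + fgum), axis=1, kind="stable")

    # --- demographics and metadata
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 0, 120)
    age_missing = rng.random(n) < config.age_missing_prob
    sexes = _categorical(rng, config.sex_probs, n)
    countries = _categorical(rng, config.country_probs, n)
    reporters = _categorical(rng, config.reporter_probs, n)
    outcomes = _categorical(rng, config.outcome_probs, n)
    serious = rng.random(n) < config.serious_prob

    is_planted_case = np.zeros(n, dtype=bool)
    if planted_pt:
        is_planted_case[list(planted_pt)] = True
    if config.planting == "rate" and config.planted_signals:
        for sig, mask in zip(config.planted_signals, sig_masks):
            for pt in config._event_pts(sig):
                hit = mask & events[:, adr_col[pt]]
                planted_case_ids[sig.name].extend(np.flatnonzero(hit).tolist())
                is_planted_case |= hit
    if config.case_outcome_probs is not None and is_planted_case.any():
        n_cases = int(is_planted_case.sum())
        outcomes[is_planted_case] = _categorical(
            rng, config.case_outcome_probs, n_cases
        )
        serious[is_planted_case] = True

    years = _categorical(rng, {int(y): w for y, w in config.year_weights.items()}, n)
    day_of_year = rng.integers(0, 365, size=n)
    onset_lag = rng.integers(0, 61, size=n)  # receipt - onset, days
    tto_days = np.maximum(
        1, np.rint(rng.lognormal(config.tto.mu, config.tto.sigma, size=n))
    ).astype(int)
    other_onset_lag = rng.integers(0, 91, size=n)
    bg_start_lag = rng.integers(30, 401, size=(n, kmax))
    drug_date_missing = rng.random((n, n_drugs)) < config.drug_date_missing_prob
    case_date_missing = rng.random(n) < config.case_drug_date_missing_prob
    onset_missing = rng.random(n) < config.onset_missing_prob

    exposure_ings: set[str] = set()
    for sig in config.planted_signals:
        exposure_ings |= set(sig.match_any) | set(sig.match_all)
    exposure_cols = [col[i] for i in sorted(exposure_ings)] if exposure_ings else []

    outcome_enum = {o.value: o for o in Outcome}
    exposure_col_set = set(exposure_cols)

    drug_rows = _group_rows(present)
    event_rows = _group_rows(events)
    ages = np.round(ages, 1)
    ingredient_names = [d.ingredient for d in drugs]
    suspect_role, conc_role = DrugRole.suspect, DrugRole.concomitant

    # vectorized calendar arithmetic: everything becomes python date objects
    # in one C-level pass
    years_int = np.asarray(years, dtype=int)
    receipt64 = (
        (years_int - 1970).astype("datetime64[Y]").astype("datetime64[D]")
        + day_of_year
    )
    receipt_dates = receipt64.tolist()
    case_onset_dates = (receipt64 - onset_lag).tolist()
    other_onset_dates = (receipt64 - other_onset_lag).tolist()
    exposure_start_dates = (receipt64 - onset_lag - tto_days).tolist()
    bg_start_dates = (receipt64[:, None] - bg_start_lag).tolist()

    sex_vals = [Sex(s) for s in sexes]
    rep_vals = [ReporterQualification(r) for r in reporters]
    outcome_vals = [outcome_enum[o] for o in outcomes]
    country_vals = [str(c) for c in countries]
    filler_cache = {
        pt: _construct(
            ReactionEntry, pt=pt, onset_date=None, reaction_outcome=Outcome.unknown
        )
        for pt in filler_names
    }
    kf_list = kf.tolist()
    forder_list = forder[:, : int(max(fill_keys))].tolist()

    reports: list[IcsrReport] = []
    id_width = len(str(n))
    gc_was_on = gc.isenabled()
    gc.disable()
    try:
        for i in range(n):
            receipt = receipt_dates[i]
            case_row = bool(is_planted_case[i])
            if case_row:
                onset = case_onset_dates[i]
                exposure_start = exposure_start_dates[i]
            else:
                onset = other_onset_dates[i]
                exposure_start = None

            drug_entries = []
            bg_slot = 0
            for j in drug_rows[i].tolist():
                is_suspect = bool(suspect[i, j])
                if case_row and is_suspect and j in exposure_col_set:
                    start = None if case_date_missing[i] else exposure_start
                else:
                    start = (
                        None
                        if drug_date_missing[i, j]
                        else bg_start_dates[i][bg_slot % kmax]
                    )
                    bg_slot += 1
                drug_entries.append(
                    _construct(
                        DrugEntry,
                        ingredient=ingredient_names[j],
                        role=suspect_role if is_suspect else conc_role,
                        start_date=start,
                        stop_date=None,
                        indication=None,
                        date_imputed=False,
                    )
                )

            reaction_entries = []
            row_outcome = outcome_vals[i]
            event_onset = None if onset_missing[i] else onset
            for j in event_rows[i].tolist():
                reaction_entries.append(
                    _construct(
                        ReactionEntry,
                        pt=adr_pts[j], onset_date=event_onset,
                        reaction_outcome=row_outcome,
                    )
                )
            if i in planted_pt and planted_pt[i] not in adr_col:
                reaction_entries.append(
                    _construct(
                        ReactionEntry,
                        pt=planted_pt[i], onset_date=event_onset,
                        reaction_outcome=row_outcome,
                    )
                )
            for s in range(kf_list[i]):
                reaction_entries.append(filler_cache[filler_names[forder_list[i][s]]])

            reports.append(
                _construct(
                    IcsrReport,
                    report_id=f"SYN-{i:0{id_width}d}",
                    receipt_date=receipt,
                    country=country_vals[i],
                    reporter_qualification=rep_vals[i],
                    patient_age=None if age_missing[i] else float(ages[i]),
                    patient_sex=sex_vals[i],
                    drugs=tuple(drug_entries),
                    reactions=tuple(reaction_entries),
                    serious=bool(serious[i]) or row_outcome is Outcome.fatal,
                    outcome=row_outcome,
                )
            )
    finally:
        if gc_was_on:
            gc.enable()

    # --- ground-truth ledger
    signals: list[SignalTruth] = []
    event_presence_cache: dict[tuple[str, ...], np.ndarray] = {}

    def event_presence(pts: Sequence[str]) -> np.ndarray:
        key = tuple(sorted(pts))
        if key not in event_presence_cache:
            mask = np.zeros(n, dtype=bool)
            for pt in pts:
                if pt in adr_col:
                    mask |= events[:, adr_col[pt]]
            for row, pt in planted_pt.items():
                if pt in pts:
                    mask[row] = True
            event_presence_cache[key] = mask
        return event_presence_cache[key]

    for sig, mask in zip(config.planted_signals, sig_masks):
        ev = event_presence(config._event_pts(sig))
        a = int((mask & ev).sum())
        b = int((mask & ~ev).sum())
        c = int((~mask & ev).sum())
        d = int((~mask & ~ev).sum())
        signals.append(
            SignalTruth(
                name=sig.name,
                event_pts=tuple(config._event_pts(sig)),
                mode=config.planting,
                rate_ratio=sig.rate_ratio,
                n_planted=len(planted_case_ids[sig.name]),
                a=a, b=b, c=c, d=d,
            )
        )

    all_event_terms: dict[str, int] = {}
    seen_events: set[str] = set()
    for sig in config.planted_signals:
        if sig.event not in seen_events:
            seen_events.add(sig.event)
            all_event_terms[sig.event] = int(event_presence(config._event_pts(sig)).sum())

    truth = GroundTruth(
        n_reports=n,
        seed=config.seed if seed is None else seed,
        signals=signals,
        ingredient_margins={
            d.ingredient: int(present[:, col[d.ingredient]].sum()) for d in drugs
        },
        event_report_counts=all_event_terms,
        case_report_ids={
            name: [f"SYN-{row:0{id_width}d}" for row in sorted(set(rows_))]
            for name, rows_ in planted_case_ids.items()
        },
    )
    return reports, truth


# ---------------------------------------------------------------------------
# Stock configurations
# ---------------------------------------------------------------------------

_BACKGROUND_DRUGS = (
    "mycophenolic acid", "prednisone", "tacrolimus", "sirolimus", "ciclosporin",
    "everolimus", "metformin", "amlodipine", "atorvastatin", "omeprazole",
    "levothyroxine", "aspirin", "furosemide", "insulin", "paracetamol",
    "ibuprofen", "amoxicillin", "salbutamol", "warfarin", "ramipril",
)

_BACKGROUND_ADRS = {
    "Diarrhoea": 0.030, "Nausea": 0.025, "Fatigue": 0.022, "Rash": 0.020,
    "Pyrexia": 0.015, "Vomiting": 0.014, "Headache": 0.012, "Pruritus": 0.010,
    "Dyspnoea": 0.009, "Colitis": 0.006, "Pneumonitis": 0.005,
    "Hepatitis": 0.004, "Hypothyroidism": 0.004, "Myocarditis": 0.002,
    "Anaemia": 0.008,
}

_FILLER_PTS = {
    "Drug ineffective": 5.0, "Malignant neoplasm progression": 3.0,
    "Acute kidney injury": 2.0, "Intentional product use issue": 2.0,
    "Arthralgia": 2.0, "Thrombocytopenia": 1.5, "Renal impairment": 1.5,
    "Blood creatinine increased": 1.5, "Infusion related reaction": 1.0,
    "Adrenal insufficiency": 0.8, "Pneumonia": 1.2, "Hyperthyroidism": 0.8,
    "Hypophysitis": 0.5, "Interstitial lung disease": 0.7, "Death": 1.0,
}

#: Organ distribution of rejection events (kidney and liver shares as
#: reported for the case series; the remainder spread over other organs).
_REJECTION_PT_WEIGHTS = {
    "Kidney transplant rejection": 0.547,
    "Liver transplant rejection": 0.157,
    "Heart transplant rejection": 0.082,
    "Lung transplant rejection": 0.069,
    "Pancreas transplant rejection": 0.044,
    "Bone marrow transplant rejection": 0.038,
    "Corneal graft rejection": 0.025,
    "Skin graft rejection": 0.019,
    "Transplant rejection": 0.019,
}


def _long_tail(n_items: int, total_mass: float) -> list[float]:
    """Zipf-like weights summing to total_mass."""
    raw = [1.0 / (r + 1) for r in range(n_items)]
    s = sum(raw)
    return [total_mass * x / s for x in raw]


def null_config(n_reports: int = 100_000, seed: int = 0) -> SyntheticConfig:
    """A signal-free database: drug exposure and events fully independent."""
    masses = _long_tail(len(_BACKGROUND_DRUGS), 1.0)
    catalog = tuple(
        DrugSpec(ingredient=ing, marginal=m, suspect_prob=0.6)
        for ing, m in zip(_BACKGROUND_DRUGS, masses)
    )
    adrs = tuple(AdrSpec(pt=pt, base_prob=p) for pt, p in _BACKGROUND_ADRS.items())
    return SyntheticConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalog=catalog,
        adr_catalog=adrs,
        filler_pts=dict(_FILLER_PTS),
    )


def paper_calibrated_config(n_reports: int = 100_000, seed: int = 0) -> SyntheticConfig:
    """A database calibrated to the published transplant-rejection screen.

    The margins are chosen so that, with a rejection-event margin of ~1,000
    reports in 100,000, the expected counts of the four screen rows come out
    at ~50 (all checkpoint inhibitors), ~38 (PD1), ~9 (CTLA4) and ~9 (PDL1);
    count-mode planting places exactly 140 PD1-only, 12 dual PD1+CTLA4,
    6 CTLA4-only and 1 PDL1 rejection case, realizing the observed counts
    159/152/18/1.  All counts scale linearly with ``n_reports``.

    Margin arithmetic (at 100,000 reports): PD1-exposed 3,800 of which 600
    dual with the CTLA4 inhibitor (combo probability 600/3800), CTLA4-only
    300, PDL1 900; union 5,000; background rejection rate set so the total
    event margin is ~1,000.
    """
    scale = n_reports / 100_000.0

    # exposure margins per 100k reports: PD1 drugs total 3,800; ipilimumab
    # 300 solo plus the combo rule; PDL1 drugs total 900 — drawn Bernoulli
    # so the expected counts of the screen are analytically controlled
    ici_marginals = {
        "nivolumab": 0.01825, "pembrolizumab": 0.01550, "cemiplimab": 0.00150,
        "dostarlimab": 0.00080, "tislelizumab": 0.00080, "toripalimab": 0.00060,
        "retifanlimab": 0.00055,  # PD1 total 0.038
        "ipilimumab": 0.00300,
        "avelumab": 0.00450, "atezolizumab": 0.00300, "durvalumab": 0.00150,
    }
    bg_weights = _long_tail(len(_BACKGROUND_DRUGS), 1.0)

    catalog = tuple(
        [
            DrugSpec(ingredient=ing, marginal=m, suspect_prob=1.0, draw="bernoulli")
            for ing, m in ici_marginals.items()
        ]
        + [
            DrugSpec(ingredient=ing, marginal=w, suspect_prob=0.5)
            for ing, w in zip(_BACKGROUND_DRUGS, bg_weights)
        ]
    )

    pd1 = ["nivolumab", "pembrolizumab", "cemiplimab", "dostarlimab",
           "tislelizumab", "toripalimab", "retifanlimab"]
    pdl1 = ["avelumab", "atezolizumab", "durvalumab"]

    # background rejection base rates: total event margin ~1000/100k, of
    # which 159 planted among the ~5000 suppressed ICI reports
    bg_rejection_total = 841.0 / 95_000.0
    rejection_adrs = tuple(
        AdrSpec(pt=pt, base_prob=w * bg_rejection_total)
        for pt, w in _REJECTION_PT_WEIGHTS.items()
    )
    background_adrs = tuple(
        AdrSpec(pt=pt, base_prob=p) for pt, p in _BACKGROUND_ADRS.items()
    )

    def n_ev(x: int) -> int:
        return max(0, int(round(x * scale)))

    signals = (
        PlantedSignal(
            name="PD1-only",
            match_any=pd1, match_none=["ipilimumab"] + pdl1,
            event=TRANSPLANT_REJECTION_HLT, level="hlt",
            pt_weights=_REJECTION_PT_WEIGHTS, n_events=n_ev(140), rate_ratio=4.0,
        ),
        PlantedSignal(
            name="PD1+CTLA4",
            match_any=pd1, match_all=["ipilimumab"],
            event=TRANSPLANT_REJECTION_HLT, level="hlt",
            pt_weights=_REJECTION_PT_WEIGHTS, n_events=n_ev(12), rate_ratio=4.0,
        ),
        PlantedSignal(
            name="CTLA4-only",
            match_any=["ipilimumab"], match_none=pd1 + pdl1,
            event=TRANSPLANT_REJECTION_HLT, level="hlt",
            pt_weights=_REJECTION_PT_WEIGHTS, n_events=n_ev(6), rate_ratio=2.0,
        ),
        PlantedSignal(
            name="PDL1",
            match_any=pdl1, match_none=pd1 + ["ipilimumab"],
            event=TRANSPLANT_REJECTION_HLT, level="hlt",
            pt_weights={"Kidney transplant rejection": 1.0},
            n_events=n_ev(1), rate_ratio=0.17,
        ),
    )

    return SyntheticConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalog=catalog,
        adr_catalog=rejection_adrs + background_adrs,
        filler_pts=dict(_FILLER_PTS),
        planted_signals=signals,
        planting="count",
        combo_rules=(
            ComboRule(trigger=pd1, add="ipilimumab", prob=600.0 / 3800.0),
        ),
        sex_probs={"male": 0.66, "female": 0.31, "unknown": 0.03},
        country_probs={
            "US": 0.56, "FR": 0.132, "JP": 0.06, "DE": 0.05, "GB": 0.04,
            "IT": 0.035, "CA": 0.03, "ES": 0.03, "AU": 0.02, "KR": 0.015,
            "CN": 0.015, "NL": 0.013,
        },
        reporter_probs={
            "healthcare_professional": 0.956, "consumer": 0.025,
            "pharmaceutical_company": 0.015, "unknown": 0.004,
        },
        case_outcome_probs={
            "fatal": 0.226, "recovered": 0.151, "recovering": 0.063,
            "recovered_with_sequelae": 0.025, "not_recovered": 0.30,
            "unknown": 0.235,
        },
    )
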