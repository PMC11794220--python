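"""End-to-end analysis runs driven by a single YAML configuration.

One configuration names the input report file, the terminology and
drug-class dictionaries, the case definition, the exposure rows of the
screen, and the head-to-head class comparisons.  A run produces four
artifacts in the output directory:

* ``descriptives.json`` — the case-series summary;
* ``screen.csv``        — one O/E/IC row per exposure;
* ``comparisons.csv``   — one ROR row per class pair;
* ``manifest.json``     — input hashes, stage counts, version, timestamp.

Outputs are written atomically (temp file + rename), and the manifest hash
of a rerun on identical inputs is identical except for the timestamp.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cohort import (
    CaseDefinition,
    ExposureDefinition,
    select_cases,
    summarize,
)
from .disproportionality import comparative_ror, run_screen
from .report_store import (
    DrugClassDictionary,
    MeddraHierarchy,
    default_drug_classes,
    default_hierarchy,
    read_reports,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunManifest", "run_full_analysis"]


class _ExposureSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    name: Optional[str] = None
    level: str
    targets: tuple[str, ...]


class _ComparisonSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    class_a: str
    class_b: str


class AnalysisConfig(BaseModel):
    """Schema of the YAML configuration for a full run."""

    model_config = ConfigDict(frozen=True)

    reports: str
    format: str = "jsonl"
    hierarchy: Optional[str] = None  # None -> shipped default dictionary
    drug_classes: Optional[str] = None
    case_level: str = "hlt"
    case_term: str
    exposures: tuple[_ExposureSpec, ...]
    comparisons: tuple[_ComparisonSpec, ...] = ()
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls(**payload)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    input_hashes: dict[str, str]
    tool_version: str
    stage_counts: dict[str, int]
    timestamp: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @property
    def run_hash(self) -> str:
        """Hash over everything except the timestamp."""
        payload = json.dumps(
            {
                "config": self.config_hash,
                "inputs": self.input_hashes,
                "version": self.tool_version,
                "stages": self.stage_counts,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: Path, payload: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def run_full_analysis(
    config: AnalysisConfig | str | Path,
    output_dir: Optional[str | Path] = None,
) -> RunManifest:
    """Run ingest → describe → screen → compare and write the output bundle."""
    config_path: Optional[Path] = None
    if not isinstance(config, AnalysisConfig):
        config_path = Path(config)
        config = AnalysisConfig.from_yaml(config_path)
    out_dir = Path(output_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.monotonic()
    stage = "ingest"
    try:
        reports = read_reports(config.reports, format=config.format)
        if not reports:
            raise ValueError(f"no reports in {config.reports}")
        logger.info("[%s] %d reports read (%.2fs)", stage, len(reports),
                    time.monotonic() - t0)

        hierarchy = (
            MeddraHierarchy.from_csv(config.hierarchy)
            if config.hierarchy
            else default_hierarchy()
        )
        dictionary = (
            DrugClassDictionary.from_csv(config.drug_classes)
            if config.drug_classes
            else default_drug_classes()
        )
        case_def = CaseDefinition(level=config.case_level, term=config.case_term)
        exposures = [
            ExposureDefinition(name=e.name, level=e.level, targets=e.targets)
            for e in config.exposures
        ]
        for e in exposures:
            e.resolve(dictionary)

        stage = "describe"
        cases = select_cases(reports, case_def, hierarchy)
        if not cases:
            raise ValueError(f"no cases match {config.case_term!r}")
        union_def = exposures[0] if exposures else None
        descriptives = summarize(
            cases, union_def, dictionary, hierarchy, case_def
        ).to_dict()
        logger.info("[%s] %d cases selected", stage, len(cases))

        stage = "screen"
        screen = run_screen(reports, exposures, case_def, dictionary, hierarchy)
        logger.info("[%s] %d exposure rows", stage, len(screen))

        stage = "compare"
        comp_rows = []
        for comp in config.comparisons:
            res = comparative_ror(
                reports, comp.class_a, comp.class_b, case_def, dictionary, hierarchy
            )
            t = res.table
            comp_rows.append(
                {
                    "class_a": comp.class_a, "class_b": comp.class_b,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "ror": res.ror, "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "z": res.z, "p": res.p,
                    "correction_applied": res.correction_applied,
                }
            )
        comparisons = pd.DataFrame(
            comp_rows,
            columns=["class_a", "class_b", "a", "b", "c", "d", "ror",
                     "ci_low", "ci_high", "z", "p", "correction_applied"],
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage_counts = {
        "reports_read": len(reports),
        "cases_selected": len(cases),
        "screen_rows": int(len(screen)),
        "comparison_rows": int(len(comparisons)),
    }
    for _, row in screen.iterrows():
        stage_counts[f"O[{row['exposure']}]"] = int(row["O"])

    config_payload = json.dumps(config.model_dump(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_payload.encode()).hexdigest(),
        input_hashes={"reports": _sha256(config.reports)},
        tool_version=__version__,
        stage_counts=stage_counts,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )

    _atomic_write(out_dir / "descriptives.json", json.dumps(descriptives, indent=2))
    _atomic_write(out_dir / "screen.csv", screen.to_csv(index=False))
    _atomic_write(out_dir / "comparisons.csv", comparisons.to_csv(index=False))
    _atomic_write(out_dir / "manifest.json", json.dumps(manifest.to_dict(), indent=2))
    logger.info("run complete in %.2fs -> %s", time.monotonic() - t0, out_dir)
    return manifest
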