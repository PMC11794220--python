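"""Shared fixtures: hand-built report lists and one calibrated database."""

from __future__ import annotations

from datetime import date

import pytest

from icsr_signal import (
    CaseDefinition,
    DrugEntry,
    ExposureDefinition,
    IcsrReport,
    ReactionEntry,
    generate,
    paper_calibrated_config,
)


def make_report(
    report_id: str,
    ingredients=("nivolumab",),
    pts=("Kidney transplant rejection",),
    roles=None,
    outcome="unknown",
    sex="male",
    receipt=date(2022, 6, 1),
    start=None,
    onset=None,
    country="US",
    age=63.0,
) -> IcsrReport:
    roles = roles or ["suspect"] * len(ingredients)
    return IcsrReport(
        report_id=report_id,
        receipt_date=receipt,
        country=country,
        reporter_qualification="healthcare_professional",
        patient_age=age,
        patient_sex=sex,
        drugs=[
            DrugEntry(ingredient=ing, role=role, start_date=start)
            for ing, role in zip(ingredients, roles)
        ],
        reactions=[ReactionEntry(pt=pt, onset_date=onset) for pt in pts],
        serious=True,
        outcome=outcome,
    )


@pytest.fixture(scope="session")
def transplant_case() -> CaseDefinition:
    return CaseDefinition(level="hlt", term="Transplant Rejection")


@pytest.fixture(scope="session")
def screen_exposures() -> list[ExposureDefinition]:
    return [
        ExposureDefinition(
            level="class_union", targets=["PD1i", "CTLA4i", "PDL1i"], name="ICI"
        ),
        ExposureDefinition(level="class", targets=["PD1i"], name="PD1i"),
        ExposureDefinition(level="class", targets=["CTLA4i"], name="CTLA4i"),
        ExposureDefinition(level="class", targets=["PDL1i"], name="PDL1i"),
    ]


@pytest.fixture(scope="session")
def calibrated_dataset():
    """One full-size calibrated database, shared across the session."""
    config = paper_calibrated_config(n_reports=100_000, seed=1)
    reports, truth = generate(config)
    return config, reports, truth


@pytest.fixture
def small_cohort() -> list[IcsrReport]:
    """Five reports, two of them kidney-transplant-rejection cases."""
    return [
        make_report("R1", pts=("Kidney transplant rejection",)),
        make_report("R2", pts=("Diarrhoea",)),
        make_report(
            "R3",
            pts=("Kidney transplant rejection", "Liver transplant rejection"),
        ),
        make_report("R4", pts=("Rash",), ingredients=("tacrolimus",)),
        make_report("R5", pts=("Nausea",), ingredients=("pembrolizumab",)),
    ]
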