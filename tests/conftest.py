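"""Shared fixtures: small synthetic universes and report builders."""

from __future__ import annotations

from dataclasses import replace
from datetime import date

import pytest

import pvsignals as pv
from pvsignals.report_io import DrugUse, NormalizedReport


def make_report(report_id: str = "r1",
                case_id: str | None = None,
                case_version: int = 1,
                source: str = "FAERS",
                receipt: str | None = "20200601",
                sex: str = "male",
                age: float | None = 50.0,
                country: str = "United States",
                reporter: str = "health_professional",
                outcomes: tuple[str, ...] = (),
                drugs: tuple[tuple[str, str], ...] = (("obinutuzumab", "primary_suspect"),),
                events: tuple[str, ...] = ("Pyrexia",),
                indications: tuple[str, ...] = (),
                start: str | None = None,
                onset: str | None = None) -> NormalizedReport:
    """Compact hand-built report for unit fixtures."""
    return NormalizedReport(
        report_id=report_id,
        case_id=case_id if case_id is not None else report_id,
        case_version=case_version,
        source=source,
        receipt_date=pv.parse_partial_date(receipt) if receipt else None,
        sex=sex,
        age_years=age,
        country=country,
        reporter_type=reporter,
        outcomes=tuple(sorted(outcomes)),
        drugs=tuple(DrugUse(name, name, role) for name, role in drugs),
        events=events,
        indications=indications,
        therapy_start_date=pv.parse_partial_date(start) if start else None,
        event_onset_date=pv.parse_partial_date(onset) if onset else None,
    )


@pytest.fixture(scope="session")
def small_config() -> pv.GeneratorConfig:
    return replace(pv.demo_config(seed=11),
                   n_background_reports=3000, n_drug_reports=300)


@pytest.fixture(scope="session")
def small_universe(small_config):
    """A modest synthetic universe with duplicates and missing dates."""
    reports, truth = pv.generate_reports(small_config)
    return reports, truth


@pytest.fixture(scope="session")
def deduped_universe(small_universe):
    reports, truth = small_universe
    return pv.deduplicate(reports), truth


@pytest.fixture(scope="session")
def lexicon() -> pv.DrugLexicon:
    return pv.DrugLexicon.default()


@pytest.fixture(scope="session")
def dictionary() -> pv.MeddraDictionary:
    return pv.MeddraDictionary.default()
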