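"""Shared fixtures: the shipped lexicon, a clean synthetic corpus, and a
hand-built two-patient warehouse fixture with hand-computed expectations."""

from __future__ import annotations

import pandas as pd
import pytest

from stentminer import (
    GeneratorConfig,
    TermLexicon,
    extract_corpus,
    generate_cohort,
    render_reports,
)


@pytest.fixture(scope="session")
def lexicon() -> TermLexicon:
    return TermLexicon.default()


@pytest.fixture(scope="session")
def clean_cohort():
    """200-report corpus whose surface noise is restricted to registered
    lexicon variants (no typos): extraction should round-trip exactly."""
    config = GeneratorConfig(
        n_patients=200, seed=7, variant_rate=0.3, typo_rate=0.0, decoy_rate=0.2
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def clean_corpus(clean_cohort, lexicon):
    docs = render_reports(clean_cohort, lexicon)
    frame, parsed = extract_corpus(docs, lexicon)
    return docs, frame, parsed


# ---------------------------------------------------------------------------
# hand-built warehouse fixture
#
# P001: index PCI 2011-03-01 (femoral, non-emergent)
#   LAD: Xience 3.0/28 + Xience 2.5/10 -> n=2, total 38, mean 2.75, balloon
#        repeat LAD PCI 2012-04-04 (day 400) -> TVR event, t=400
#   RCA: Nobori 2.5/18 -> censored at the 730-day window
#        (last-contact visit 2013-02-28 = day 730)
#   hypertension: I10 coded; DAPT: aspirin 2011-03-01..2012-09-01 and
#   clopidogrel 2011-03-01..2012-03-01 -> overlap 366 days -> flag True
#   age: born 1950-02-01 -> 61 at index
# P002: index PCI 2012-05-10 (radial)
#   LCx: Cypher 3.0/24 -> censored at last contact 2012-11-06 (day 180)
#   diabetes: E11 coded; single antiplatelet -> DAPT 0
#   age: born 1940-04-01 -> 72 at index


@pytest.fixture()
def toy_extraction() -> pd.DataFrame:
    rows = [
        ("R001", "P001", "2011-03-01", "LAD", "Xience", "DES", "second", "durable", 3.0, 28.0, True, 10, 16),
        ("R001", "P001", "2011-03-01", "LAD", "Xience", "DES", "second", "durable", 2.5, 10.0, True, 30, 36),
        ("R001", "P001", "2011-03-01", "RCA", "Nobori", "DES", "second", "biodegradable", 2.5, 18.0, False, 60, 66),
        ("R002", "P002", "2012-05-10", "LCx", "Cypher", "DES", "first", "none", 3.0, 24.0, False, 8, 14),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "report_id", "patient_id", "procedure_date", "vessel",
            "brand_family", "device_class", "generation", "polymer",
            "diameter_mm", "length_mm", "noncompliant_balloon",
            "char_start", "char_end",
        ],
    )


@pytest.fixture()
def toy_patients() -> dict[str, pd.DataFrame]:
    demographics = pd.DataFrame(
        [
            ("P001", "1950-02-01", "M"),
            ("P002", "1940-04-01", "F"),
        ],
        columns=["patient_id", "birth_date", "sex"],
    )
    diagnoses = pd.DataFrame(
        [
            ("P001", "I10", "2010-01-15"),
            ("P002", "E11", "2011-06-01"),
        ],
        columns=["patient_id", "code", "date"],
    )
    prescriptions = pd.DataFrame(
        [
            ("P001", "aspirin", "2011-03-01", "2012-09-01"),
            ("P001", "clopidogrel", "2011-03-01", "2012-03-01"),
            ("P002", "aspirin", "2012-05-10", "2012-11-06"),
        ],
        columns=["patient_id", "drug_class", "start", "end"],
    )
    procedures = pd.DataFrame(
        [
            ("P001", "2011-03-01", "PCI", "", "femoral", False),
            ("P001", "2012-04-04", "PCI", "LAD", "femoral", False),
            ("P001", "2013-02-28", "visit", "", "", False),
            ("P002", "2012-05-10", "PCI", "", "radial", False),
            ("P002", "2012-11-06", "visit", "", "", False),
        ],
        columns=["patient_id", "date", "type", "vessel", "approach", "emergent"],
    )
    return {
        "demographics": demographics,
        "diagnoses": diagnoses,
        "prescriptions": prescriptions,
        "procedures": procedures,
    }
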