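"""Rule-based extraction of stent implantation records from free-text PCI reports.

PCI/CAG procedure reports are semi-structured: each treated vessel is
announced by a short header line ending in a colon (``LAD:``) and the lines
that follow describe what was implanted (brand name, ``<diameter>/<length>mm``
dimensions, optional non-compliant balloon use). Extraction proceeds in six
steps: (1) segment the document at header lines (the words between a newline
and a colon); (2) resolve each header against the vessel lexicon; (3-4) match
registered stent brand names inside the section body; (5) capture dimension
strings of the shape ``number/number mm``; (6) flag non-compliant
high-pressure balloon use (a standalone ``HP`` token or a registered balloon
brand). A stent record is materialized only when name, diameter and length
are all present — a partial triple means no stent was recorded for that
vessel.

Everything is a pure function of (text, lexicon); unmatched text is simply
skipped, which is what makes the approach robust to mixed-language
(English/Korean) notes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .terminology import StentCategory, TermLexicon, VesselCategory, normalize_token

__all__ = [
    "ReportDocument",
    "SectionCandidate",
    "VesselSection",
    "StentRecord",
    "ProcedureRecord",
    "segment_sections",
    "resolve_vessels",
    "extract_dimensions",
    "extract_stents",
    "detect_noncompliant_balloon",
    "parse_report",
    "read_corpus",
    "extract_corpus",
    "EXTRACTION_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Pre-colon text longer than this is prose, not a vessel header.
HEADER_MAX_CHARS = 40

#: diameter "/" length with an optional space before "mm"; numbers may carry
#: one decimal point. ``(?!\w)`` keeps "mmHg" etc. from matching.
DIMENSION_RE = re.compile(
    r"(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*mm(?!\w)", re.IGNORECASE
)

#: Standalone "HP" token (word-bounded, case-insensitive).
HP_RE = re.compile(r"(?<!\w)hp(?!\w)", re.IGNORECASE)


@dataclass(frozen=True)
class ReportDocument:
    """One free-text report plus the identifiers needed for warehouse linkage."""

    report_id: str
    patient_id: str
    procedure_date: str  # ISO-8601
    text: str


@dataclass(frozen=True)
class SectionCandidate:
    """A header line and its body, before vessel resolution.

    Offsets are 0-based half-open character positions into the document.
    """

    header_token: str  # normalized pre-colon text
    raw_header: str
    body: str
    body_start: int
    start: int
    end: int


@dataclass(frozen=True)
class VesselSection:
    header_token: str
    vessel: VesselCategory
    body: str
    body_start: int
    start: int
    end: int


@dataclass(frozen=True)
class StentRecord:
    """A complete (vessel, stent, diameter, length) assertion with provenance."""

    vessel: VesselCategory
    stent: StentCategory
    diameter_mm: float
    length_mm: float
    char_start: int  # span of the stent-name match in the document
    char_end: int


@dataclass
class ProcedureRecord:
    """Parsed output of one report."""

    report_id: str
    records: list[StentRecord] = field(default_factory=list)
    balloon_by_vessel: dict[VesselCategory, bool] = field(default_factory=dict)
    unparsed_headers: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_sections: int = 0

    def pair_set(self, granularity: str = "category") -> frozenset[tuple[str, str]]:
        """Distinct (vessel, stent label) assertions of this report."""
        if granularity == "category":
            return frozenset(
                (r.vessel.value, r.stent.class_label) for r in self.records
            )
        if granularity == "brand":
            return frozenset(
                (r.vessel.value, r.stent.brand_family) for r in self.records
            )
        raise ValueError(f"unknown granularity {granularity!r}")


def segment_sections(doc: ReportDocument) -> list[SectionCandidate]:
    """Step 1: split the document at header lines.

    A header line contains a colon whose pre-colon text is non-empty and at
    most :data:`HEADER_MAX_CHARS` characters (only the first colon on a line
    counts). The body is the remainder of the header line plus all following
    lines up to, but excluding, the next header line. A document with no
    header lines yields an empty list.
    """
    text = doc.text
    headers: list[tuple[int, int, str]] = []  # (line_start, colon_offset, pre)
    pos = 0
    for line in text.splitlines(keepends=True):
        stripped = line.rstrip("\r\n")
        colon = stripped.find(":")
        if colon != -1:
            pre = stripped[:colon]
            if pre.strip() and len(pre.strip()) <= HEADER_MAX_CHARS:
                headers.append((pos, colon, pre))
        pos += len(line)
    candidates = []
    for i, (start, colon, pre) in enumerate(headers):
        body_start = start + colon + 1
        end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        candidates.append(
            SectionCandidate(
                header_token=normalize_token(pre),
                raw_header=pre.strip(),
                body=text[body_start:end],
                body_start=body_start,
                start=start,
                end=end,
            )
        )
    return candidates


def resolve_vessels(
    candidates: Sequence[SectionCandidate], lexicon: TermLexicon
) -> tuple[list[VesselSection], list[str]]:
    """Step 2: keep candidates whose header is a registered vessel form."""
    sections, unmatched = [], []
    for cand in candidates:
        vessel = lexicon.lookup_vessel(cand.header_token)
        if vessel is None:
            unmatched.append(cand.header_token)
        else:
            sections.append(
                VesselSection(
                    header_token=cand.header_token,
                    vessel=vessel,
                    body=cand.body,
                    body_start=cand.body_start,
                    start=cand.start,
                    end=cand.end,
                )
            )
    return sections, unmatched


@dataclass(frozen=True)
class DimensionMatch:
    diameter_mm: float
    length_mm: float
    start: int  # offset within the section body
    end: int


def extract_dimensions(body: str) -> list[DimensionMatch]:
    """Step 5: every ``<number>/<number>mm`` occurrence, in textual order."""
    return [
        DimensionMatch(
            diameter_mm=float(m.group(1)),
            length_mm=float(m.group(2)),
            start=m.start(),
            end=m.end(),
        )
        for m in DIMENSION_RE.finditer(body)
    ]


def extract_stents(
    section: VesselSection, lexicon: TermLexicon
) -> tuple[list[StentRecord], list[str]]:
    """Steps 3-5: pair stent-name matches with dimension tuples.

    Pairing rule: walking the names in textual order, each takes the nearest
    unused dimension tuple that starts after it; if none remains after it,
    the nearest unused one before it. Names left without a dimension (or
    dimensions without a name) produce no record, only a warning — the
    missing-field rule.
    """
    body = section.body
    names = [
        (m.start(), m.end(), lexicon.lookup_stent(m.group(0)))
        for m in lexicon.stent_pattern().finditer(body)
    ]
    dims = extract_dimensions(body)
    used = [False] * len(dims)
    records, warnings = [], []
    for nstart, nend, stent in names:
        assert stent is not None  # the pattern only matches registered forms
        after = [
            (d.start - nend, i) for i, d in enumerate(dims) if not used[i] and d.start >= nend
        ]
        before = [
            (nstart - d.start, i) for i, d in enumerate(dims) if not used[i] and d.start < nend
        ]
        pick: Optional[int] = None
        if after:
            pick = min(after)[1]
        elif before:
            pick = min(before)[1]
        if pick is None:
            warnings.append(
                f"{section.vessel.value}: stent name {body[nstart:nend]!r} has no "
                "diameter/length — no record emitted"
            )
            continue
        used[pick] = True
        d = dims[pick]
        if not 0 < d.diameter_mm < d.length_mm:
            warnings.append(
                f"{section.vessel.value}: implausible dimensions "
                f"{d.diameter_mm}/{d.length_mm}mm (diameter not < length)"
            )
        records.append(
            StentRecord(
                vessel=section.vessel,
                stent=stent,
                diameter_mm=d.diameter_mm,
                length_mm=d.length_mm,
                char_start=section.body_start + nstart,
                char_end=section.body_start + nend,
            )
        )
    if any(not u for u in used) and not names:
        warnings.append(
            f"{section.vessel.value}: dimension string(s) with no stent name"
        )
    return records, warnings


def detect_noncompliant_balloon(section: VesselSection, lexicon: TermLexicon) -> bool:
    """Step 6: standalone ``HP`` token or any registered balloon brand."""
    body = section.body
    return bool(HP_RE.search(body) or lexicon.balloon_pattern().search(body))


def parse_report(doc: ReportDocument, lexicon: TermLexicon) -> ProcedureRecord:
    """Run the full six-step extraction on one report.

    Deterministic; never raises on unparseable text — a report without header
    lines yields an empty record carrying a parse warning.
    """
    record = ProcedureRecord(report_id=doc.report_id)
    candidates = segment_sections(doc)
    if not candidates:
        record.warnings.append("unparseable report: no header lines found")
        logger.warning("report %s: no header lines found", doc.report_id)
        return record
    sections, unmatched = resolve_vessels(candidates, lexicon)
    record.unparsed_headers = unmatched
    record.n_sections = len(sections)
    for section in sections:
        stents, warnings = extract_stents(section, lexicon)
        record.records.extend(stents)
        record.warnings.extend(warnings)
        balloon = detect_noncompliant_balloon(section, lexicon)
        record.balloon_by_vessel[section.vessel] = (
            record.balloon_by_vessel.get(section.vessel, False) or balloon
        )
    return record


# ---------------------------------------------------------------------------
# corpus I/O


def read_corpus(path: Union[str, Path]) -> list[ReportDocument]:
    """Read a report corpus.

    ``path`` is either a directory holding ``<report_id>.txt`` files plus a
    ``manifest.csv`` (report_id, patient_id, procedure_date), or a single CSV
    with columns report_id, patient_id, procedure_date, text.
    """
    path = Path(path)
    docs = []
    if path.is_dir():
        manifest = pd.read_csv(path / "manifest.csv", dtype=str)
        for row in manifest.itertuples(index=False):
            text = (path / f"{row.report_id}.txt").read_text(encoding="utf-8")
            docs.append(
                ReportDocument(
                    report_id=str(row.report_id),
                    patient_id=str(row.patient_id),
                    procedure_date=str(row.procedure_date),
                    text=text,
                )
            )
    else:
        frame = pd.read_csv(path, dtype=str)
        for row in frame.itertuples(index=False):
            docs.append(
                ReportDocument(
                    report_id=str(row.report_id),
                    patient_id=str(row.patient_id),
                    procedure_date=str(row.procedure_date),
                    text=str(row.text),
                )
            )
    return docs


EXTRACTION_COLUMNS = [
    "report_id",
    "patient_id",
    "procedure_date",
    "vessel",
    "brand_family",
    "device_class",
    "generation",
    "polymer",
    "diameter_mm",
    "length_mm",
    "noncompliant_balloon",
    "char_start",
    "char_end",
]


def extract_corpus(
    docs: Sequence[ReportDocument], lexicon: TermLexicon
) -> tuple[pd.DataFrame, list[ProcedureRecord]]:
    """Parse every document; return the extraction table (one row per
    StentRecord) together with the full per-report parse results."""
    rows = []
    parsed = []
    for doc in docs:
        record = parse_report(doc, lexicon)
        parsed.append(record)
        for r in record.records:
            rows.append(
                {
                    "report_id": doc.report_id,
                    "patient_id": doc.patient_id,
                    "procedure_date": doc.procedure_date,
                    "vessel": r.vessel.value,
                    "brand_family": r.stent.brand_family,
                    "device_class": r.stent.device_class,
                    "generation": r.stent.generation,
                    "polymer": r.stent.polymer,
                    "diameter_mm": r.diameter_mm,
                    "length_mm": r.length_mm,
                    "noncompliant_balloon": bool(
                        record.balloon_by_vessel.get(r.vessel, False)
                    ),
                    "char_start": r.char_start,
                    "char_end": r.char_end,
                }
            )
    frame = pd.DataFrame(rows, columns=EXTRACTION_COLUMNS)
    return frame, parsed


def write_extraction(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, index=False)


def read_extraction(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"report_id": str, "patient_id": str, "procedure_date": str},
    )
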