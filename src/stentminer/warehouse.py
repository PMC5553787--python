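"""Assemble vessel-level analysis episodes from extraction output and patient tables.

The analysis row is the *vessel episode*: one treated target vessel at its
index PCI (the first stent-implanting procedure recorded for that
patient-vessel), carrying per-vessel stent aggregates (count, total length,
mean diameter, balloon use), patient covariates evaluated at the index date
(age, sex, hypertension, diabetes, DAPT), procedural covariates (approach
site, emergent status), and the outcome: target vessel revascularization
(TVR) — a repeat PCI on the same vessel category — within a 2-year (730-day)
window, otherwise censoring at the earlier of last contact and the window.

Covariate rules:

* hypertension — ICD-10 code I10 on or before the index date, or at least
  one antihypertensive prescription started on or before it;
* diabetes — a diabetes code (E11) or at least one antidiabetic
  prescription (a deliberately simplified, config-swappable phenotype);
* DAPT — the number of post-index days on which an aspirin-class and a
  P2Y12-class prescription overlap; the model covariate is the >= 12-month
  (365-day) flag.

Drug-class membership is resolved through a configurable drug-class map so
the prescription table may carry raw drug names.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "WarehouseConfig",
    "DrugClassMap",
    "CohortTable",
    "DataIntegrityError",
    "derive_hypertension",
    "derive_diabetes",
    "derive_dapt",
    "derive_tvr",
    "apply_exclusions",
    "build_warehouse",
    "load_patient_tables",
    "WAREHOUSE_COLUMNS",
    "COMPARISON_GRANULARITY",
]

logger = logging.getLogger(__name__)


class DataIntegrityError(ValueError):
    """Input data contradicts the episode model (e.g. repeat PCI before index)."""


class DrugClassMap:
    """Maps prescription entries (drug names or class names) to drug classes."""

    CLASSES = ("aspirin", "p2y12", "antihypertensive", "antidiabetic")

    def __init__(self, mapping: dict[str, str]):
        self._map = {k.strip().casefold(): v for k, v in mapping.items()}

    def classify(self, name: str) -> str:
        return self._map.get(str(name).strip().casefold(), "other")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "DrugClassMap":
        frame = pd.read_csv(path, sep="\t")
        return cls(dict(zip(frame["drug"], frame["drug_class"])))

    @classmethod
    def default(cls) -> "DrugClassMap":
        with resources.as_file(
            resources.files("stentminer.data") / "drug_classes.tsv"
        ) as path:
            return cls.from_file(path)


@dataclass
class WarehouseConfig:
    window_days: int = 730  # 2 years
    dapt_threshold_days: int = 365  # 12 months
    hypertension_code_prefixes: tuple[str, ...] = ("I10",)
    diabetes_code_prefixes: tuple[str, ...] = ("E11",)
    drug_class_map: Optional[DrugClassMap] = None

    def classmap(self) -> DrugClassMap:
        return self.drug_class_map or DrugClassMap.default()


# ---------------------------------------------------------------------------
# covariate derivations (each takes the patient's sub-tables)


def _has_code(diagnoses: pd.DataFrame, prefixes: tuple[str, ...], index_date) -> bool:
    if diagnoses.empty:
        return False
    dates = pd.to_datetime(diagnoses["date"])
    codes = diagnoses["code"].astype(str)
    mask = dates <= index_date
    return bool(codes[mask].str.startswith(prefixes).any())


def _has_drug(
    prescriptions: pd.DataFrame, drug_class: str, index_date, classmap: DrugClassMap
) -> bool:
    if prescriptions.empty:
        return False
    starts = pd.to_datetime(prescriptions["start"])
    classes = prescriptions["drug_class"].map(classmap.classify)
    return bool(((classes == drug_class) & (starts <= index_date)).any())


def derive_hypertension(
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    index_date,
    config: Optional[WarehouseConfig] = None,
) -> bool:
    """Code I10 on/before index, or any antihypertensive started on/before."""
    config = config or WarehouseConfig()
    return _has_code(
        diagnoses, config.hypertension_code_prefixes, index_date
    ) or _has_drug(prescriptions, "antihypertensive", index_date, config.classmap())


def derive_diabetes(
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    index_date,
    config: Optional[WarehouseConfig] = None,
) -> bool:
    """Simplified phenotype: diabetes code or any antidiabetic prescription."""
    config = config or WarehouseConfig()
    return _has_code(diagnoses, config.diabetes_code_prefixes, index_date) or _has_drug(
        prescriptions, "antidiabetic", index_date, config.classmap()
    )


def _merged_intervals(
    prescriptions: pd.DataFrame, drug_class: str, index_date, classmap: DrugClassMap
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    classes = prescriptions["drug_class"].map(classmap.classify)
    sub = prescriptions[classes == drug_class]
    intervals = []
    for row in sub.itertuples(index=False):
        start = max(pd.to_datetime(row.start), index_date)
        end = pd.to_datetime(row.end)
        if end > start:
            intervals.append((start, end))
    intervals.sort()
    merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def derive_dapt(
    prescriptions: pd.DataFrame,
    index_date,
    config: Optional[WarehouseConfig] = None,
) -> tuple[int, bool]:
    """Post-index days on which aspirin- and P2Y12-class prescriptions overlap."""
    config = config or WarehouseConfig()
    index_date = pd.to_datetime(index_date)
    if prescriptions.empty:
        return 0, False
    classmap = config.classmap()
    aspirin = _merged_intervals(prescriptions, "aspirin", index_date, classmap)
    p2y12 = _merged_intervals(prescriptions, "p2y12", index_date, classmap)
    days = 0
    for a_start, a_end in aspirin:
        for b_start, b_end in p2y12:
            lo, hi = max(a_start, b_start), min(a_end, b_end)
            if hi > lo:
                days += (hi - lo).days
    return days, days >= config.dapt_threshold_days


def derive_tvr(
    index_date,
    vessel: str,
    repeat_pci_dates,
    last_contact,
    window_days: int = 730,
) -> tuple[bool, int]:
    """TVR event status and follow-up time for one episode.

    ``repeat_pci_dates`` are the dates of later PCI procedures on the same
    vessel category; the event time is the first of them within the window,
    otherwise the episode is censored at min(last contact, window). A repeat
    dated before the index is a data-integrity error.
    """
    index_date = pd.to_datetime(index_date)
    dates = sorted(pd.to_datetime(d) for d in repeat_pci_dates)
    if dates and dates[0] < index_date:
        raise DataIntegrityError(
            f"repeat PCI on {vessel} dated {dates[0].date()} before index "
            f"{index_date.date()}"
        )
    for d in dates:
        t = (d - index_date).days
        if 0 < t <= window_days:
            return True, t
    censor = window_days
    if last_contact is not None:
        censor = min(censor, (pd.to_datetime(last_contact) - index_date).days)
    return False, max(1, censor)


# ---------------------------------------------------------------------------
# warehouse assembly

WAREHOUSE_COLUMNS = [
    "patient_id",
    "vessel",
    "index_date",
    "classes",
    "brands",
    "n_stents",
    "total_length_mm",
    "mean_diameter_mm",
    "balloon_used",
    "approach",
    "emergent",
    "age",
    "sex",
    "hypertension",
    "diabetes",
    "dapt_days",
    "dapt_over_12mo",
    "followup_days",
    "tvr_event",
    "excluded",
    "exclude_reason",
]


@dataclass
class CohortTable:
    """One row per (patient, vessel, index procedure), plus provenance."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def analysis_frame(self) -> pd.DataFrame:
        """Rows eligible for analysis export (never the excluded ones)."""
        return self.df[~self.df["excluded"]].reset_index(drop=True)

    def write(self, path: Union[str, Path]) -> None:
        """Deterministic CSV (fixed column order, fixed float format)."""
        path = Path(path)
        out = self.df[WAREHOUSE_COLUMNS].copy()
        out.to_csv(path, index=False, float_format="%.4f")
        path.with_suffix(".provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def read(cls, path: Union[str, Path]) -> "CohortTable":
        df = pd.read_csv(path, dtype={"patient_id": str})
        prov_path = Path(path).with_suffix(".provenance.json")
        prov = (
            json.loads(prov_path.read_text(encoding="utf-8"))
            if prov_path.exists()
            else {}
        )
        return cls(df=df, provenance=prov)


def load_patient_tables(path: Union[str, Path]) -> dict[str, pd.DataFrame]:
    path = Path(path)
    tables = {}
    for name in ("demographics", "diagnoses", "prescriptions", "procedures"):
        tables[name] = pd.read_csv(path / f"{name}.csv", dtype={"patient_id": str})
    return tables


def _stent_class(device_class: str, generation: str, polymer: str) -> str:
    from .terminology import class_label

    return class_label(device_class, generation, polymer)


def build_warehouse(
    extraction: pd.DataFrame,
    patients: dict[str, pd.DataFrame],
    config: Optional[WarehouseConfig] = None,
) -> CohortTable:
    """Deterministically assemble the vessel-episode table.

    Orphan report rows (patient absent from demographics) are dropped and
    counted in the provenance. Episodes start unexcluded; comparison-specific
    exclusions are applied by :func:`apply_exclusions`.
    """
    config = config or WarehouseConfig()
    demographics = patients["demographics"].set_index("patient_id")
    diagnoses = patients["diagnoses"]
    prescriptions = patients["prescriptions"]
    procedures = patients["procedures"].copy()
    procedures["date"] = pd.to_datetime(procedures["date"])

    ext = extraction.copy()
    orphans = 0
    if not ext.empty:
        known = ext["patient_id"].isin(demographics.index)
        orphans = int((~known).sum())
        if orphans:
            logger.warning("dropping %d extraction rows with unknown patients", orphans)
        ext = ext[known]
        ext["procedure_date"] = pd.to_datetime(ext["procedure_date"])
        ext["stent_class"] = [
            _stent_class(dc, g, p)
            for dc, g, p in zip(ext["device_class"], ext["generation"], ext["polymer"])
        ]

    rows = []
    if not ext.empty:
        # last contact per patient: latest date seen anywhere in the tables
        last_contact = {}
        for pid, grp in procedures.groupby("patient_id"):
            last_contact[pid] = grp["date"].max()
        if not prescriptions.empty:
            ends = pd.to_datetime(prescriptions["end"])
            for pid, end in zip(prescriptions["patient_id"], ends):
                last_contact[pid] = max(last_contact.get(pid, end), end)
        if not diagnoses.empty:
            dates = pd.to_datetime(diagnoses["date"])
            for pid, d in zip(diagnoses["patient_id"], dates):
                last_contact[pid] = max(last_contact.get(pid, d), d)

        pci = procedures[procedures["type"].astype(str).str.upper() == "PCI"]
        for (pid, vessel), grp in ext.groupby(["patient_id", "vessel"], sort=True):
            index_date = grp["procedure_date"].min()
            index_rows = grp[grp["procedure_date"] == index_date]
            # repeat PCI evidence: later extraction rows on this vessel, or
            # later procedure-table PCIs naming this vessel
            repeat_dates = list(
                grp.loc[grp["procedure_date"] > index_date, "procedure_date"].unique()
            )
            mine = pci[
                (pci["patient_id"] == pid)
                & (pci["vessel"].astype(str) == str(vessel))
            ]
            repeat_dates.extend(mine["date"].tolist())

            demo = demographics.loc[pid]
            birth = pd.to_datetime(demo["birth_date"])
            age = int((index_date - birth).days / 365.25)
            dx = diagnoses[diagnoses["patient_id"] == pid]
            rx = prescriptions[prescriptions["patient_id"] == pid]
            htn = derive_hypertension(dx, rx, index_date, config)
            dm = derive_diabetes(dx, rx, index_date, config)
            dapt_days, dapt_flag = derive_dapt(rx, index_date, config)
            event, followup = derive_tvr(
                index_date,
                str(vessel),
                repeat_dates,
                last_contact.get(pid),
                config.window_days,
            )
            index_pci = pci[
                (pci["patient_id"] == pid) & (pci["date"] == index_date)
            ]
            approach = (
                str(index_pci.iloc[0]["approach"]) if len(index_pci) else "femoral"
            )
            emergent = bool(index_pci.iloc[0]["emergent"]) if len(index_pci) else False
            rows.append(
                {
                    "patient_id": pid,
                    "vessel": str(vessel),
                    "index_date": index_date.date().isoformat(),
                    "classes": "+".join(sorted(set(index_rows["stent_class"]))),
                    "brands": "+".join(sorted(set(index_rows["brand_family"]))),
                    "n_stents": int(len(index_rows)),
                    "total_length_mm": float(index_rows["length_mm"].sum()),
                    "mean_diameter_mm": float(index_rows["diameter_mm"].mean()),
                    "balloon_used": bool(index_rows["noncompliant_balloon"].any()),
                    "approach": approach,
                    "emergent": emergent,
                    "age": age,
                    "sex": str(demo["sex"]),
                    "hypertension": htn,
                    "diabetes": dm,
                    "dapt_days": int(dapt_days),
                    "dapt_over_12mo": bool(dapt_flag),
                    "followup_days": int(followup),
                    "tvr_event": bool(event),
                    "excluded": False,
                    "exclude_reason": "",
                }
            )

    df = pd.DataFrame(rows, columns=WAREHOUSE_COLUMNS)
    digest = hashlib.sha256(
        extraction.to_csv(index=False).encode("utf-8")
    ).hexdigest()
    provenance = {
        "n_episodes": int(len(df)),
        "n_extraction_rows": int(len(extraction)),
        "n_orphan_rows": orphans,
        "extraction_sha256": digest,
        "window_days": config.window_days,
        "dapt_threshold_days": config.dapt_threshold_days,
    }
    return CohortTable(df=df, provenance=provenance)


#: Class-label -> group-label maps defining each comparison's granularity.
COMPARISON_GRANULARITY = {
    "gen1_vs_gen2": {"DES1": "gen1", "DES2-DP": "gen2", "DES2-BP": "gen2"},
    "dp_vs_bp": {"DES2-DP": "DP", "DES2-BP": "BP"},
}


def apply_exclusions(table: CohortTable, comparison: str) -> CohortTable:
    """Flag episodes for one comparison, at that comparison's granularity.

    Episodes whose stent records span more than one category at the active
    granularity are excluded ("mixed-category"); episodes whose classes fall
    outside the comparison (e.g. BMS in a DES-only contrast) are excluded as
    "not-in-comparison". Eligible episodes receive their group label in a
    ``group`` column.
    """
    df = table.df.copy()
    groups = []
    excluded = []
    reasons = []
    if comparison in COMPARISON_GRANULARITY:
        mapping = COMPARISON_GRANULARITY[comparison]
        for classes in df["classes"]:
            labels = {mapping.get(c) for c in str(classes).split("+")}
            if None in labels:
                groups.append("")
                excluded.append(True)
                reasons.append("not-in-comparison")
            elif len(labels) > 1:
                groups.append("")
                excluded.append(True)
                reasons.append("mixed-category")
            else:
                groups.append(labels.pop())
                excluded.append(False)
                reasons.append("")
    elif comparison == "each_vs_rest":
        # second-generation episodes with a single brand family
        for classes, brands in zip(df["classes"], df["brands"]):
            class_set = set(str(classes).split("+"))
            brand_set = set(str(brands).split("+"))
            if not class_set <= {"DES2-DP", "DES2-BP"}:
                groups.append("")
                excluded.append(True)
                reasons.append("not-in-comparison")
            elif len(brand_set) > 1:
                groups.append("")
                excluded.append(True)
                reasons.append("mixed-category")
            else:
                groups.append(brand_set.pop())
                excluded.append(False)
                reasons.append("")
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    df["group"] = groups
    df["excluded"] = excluded
    df["exclude_reason"] = reasons
    prov = dict(table.provenance)
    prov["comparison"] = comparison
    prov["n_excluded"] = int(sum(excluded))
    return CohortTable(df=df, provenance=prov)
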