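"""Synthetic PCI corpus and cohort generator.

Emulates what the extraction/warehouse/survival stages consume, with the
generator-side truth kept alongside so every stage can be scored exactly:

* semi-structured procedure reports (``<vessel term>:`` headers, stent brand
  + ``<diameter>/<length>mm`` lines, optional "HP"/balloon tokens, surface
  forms sampled from registered lexicon variants, unregistered typos and
  mixed-language decoy filler at configurable rates);
* longitudinal patient tables (demographics, ICD-10-style diagnoses,
  drug prescriptions, procedures including repeat PCIs) generated under an
  exponential proportional-hazards model for target vessel
  revascularization, with administrative censoring;
* the gold standard: per-report vessel-stent pairs, full stent records, and
  per-episode true covariates and event/censoring times.

Default magnitudes are calibrated to a realistic tertiary-centre PCI cohort:
~1.5 treated vessels per patient, stent diameter ~3.0 mm, per-stent length
~24 mm, 2-year TVR around 5%, and a stent-class mix dominated by
second-generation durable-polymer devices. Everything is deterministic under
``GeneratorConfig.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .report_parser import ReportDocument
from .terminology import TermLexicon, VesselCategory

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "render_reports",
    "export_gold",
    "simulate_extractor_variants",
]


#: Non-lexicon filler (English and Hangul) used as decoy body lines. None of
#: these contain a colon or a "<n>/<n>mm" shape, so they can never create a
#: header or a dimension tuple.
DECOY_LINES = [
    "Mild luminal irregularities noted",
    "No significant residual stenosis",
    "TIMI III flow restored",
    "inflated to 14 atm for 10 sec",
    "De novo lesion, type B2",
    "Patient tolerated the procedure well",
    "정상 관상동맥 소견",
    "시술 후 특이사항 없음",
    "잔여 협착 없음",
    "좌측 요골동맥 접근",
]

#: Header-shaped decoys that are not vessel terms (exercise unparsed_headers).
DECOY_HEADERS = ["Findings", "Conclusion", "Impression", "Recommendation", "소견"]


def _normalize_mix(name: str, mix: dict, errors: list[str]) -> None:
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        errors.append(f"{name}: probabilities sum to {total}, expected 1")
    if any(p < 0 for p in mix.values()):
        errors.append(f"{name}: negative probability")


@dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_patients: int = 200
    seed: int = 0

    # cohort structure
    vessels_per_patient: tuple[float, ...] = (0.60, 0.30, 0.10)  # P(1), P(2), P(3)
    vessel_weights: dict[str, float] = field(
        default_factory=lambda: {"LAD": 0.45, "LCx": 0.22, "RCA": 0.25, "LM": 0.08}
    )
    stents_per_vessel: tuple[float, ...] = (0.80, 0.15, 0.05)
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "BMS": 0.05,
            "DES1": 0.20,
            "DES2-DP": 0.55,
            "DES2-BP": 0.20,
        }
    )
    brand_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "BMS": {"Vision": 0.40, "Genoss": 0.30, "Coroflex Blue": 0.20, "Zeta": 0.10},
            "DES1": {"Cypher": 0.50, "Taxus": 0.35, "Coroflex Please": 0.15},
            "DES2-DP": {
                "Promus": 0.33,
                "Xience": 0.30,
                "Resolute": 0.30,
                "Endeavor": 0.07,
            },
            "DES2-BP": {
                "Nobori": 0.60,
                "Biomatrix": 0.30,
                "Orsiro": 0.05,
                "Desyne": 0.05,
            },
        }
    )
    #: chance that an additional stent in the same vessel switches class /
    #: keeps the same brand (mixed-category vessels are rare but real; the
    #: analyses exclude them).
    mixed_class_rate: float = 0.02
    same_brand_rate: float = 0.90

    # stent dimensions (mm)
    diameter_mean: float = 3.0
    diameter_sd: float = 0.4
    diameter_range: tuple[float, float] = (2.0, 4.5)
    length_mean: float = 24.0
    length_sd: float = 8.0
    length_range: tuple[float, float] = (8.0, 48.0)

    # report surface noise
    variant_rate: float = 0.3  # registered lexicon variant instead of canonical
    typo_rate: float = 0.0  # unregistered corruption of a term
    decoy_rate: float = 0.2  # decoy lines / decoy headers
    disagreement_rate: float = 0.039  # simulated inter-extractor disagreement

    # procedural covariates
    balloon_rate: float = 0.52
    radial_rate: float = 0.19
    emergent_rate: float = 0.15

    # patient covariates
    age_mean: float = 63.0
    age_sd: float = 11.8
    male_rate: float = 0.71
    hypertension_rate: float = 0.46
    diabetes_rate: float = 0.20
    dapt_mean_days: float = 572.0
    dapt_sd_days: float = 445.0

    # proportional-hazards outcome model (TVR)
    baseline_rate: float = 6e-5  # events/day for the reference profile
    class_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "BMS": math.log(1.8),
            "DES1": 0.0,
            "DES2-DP": math.log(0.423),
            "DES2-BP": math.log(0.423) + math.log(0.568),
        }
    )
    covariate_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": math.log(3.469),
            "diabetes": math.log(2.100),
            "dapt_over_12mo": math.log(0.389),
            "emergent": math.log(3.270),
            "age_per_year": math.log(0.978),  # centred at age_mean
        }
    )
    window_days: int = 730
    censor_low_days: int = 730  # uniform administrative censoring bounds
    censor_high_days: int = 730

    def validate(self) -> None:
        """Raise ValueError listing every offending field."""
        errors: list[str] = []
        if self.n_patients < 0:
            errors.append("n_patients: must be non-negative")
        for name, probs in (
            ("vessels_per_patient", self.vessels_per_patient),
            ("stents_per_vessel", self.stents_per_vessel),
        ):
            _normalize_mix(name, dict(enumerate(probs)), errors)
        _normalize_mix("vessel_weights", self.vessel_weights, errors)
        _normalize_mix("class_mix", self.class_mix, errors)
        for cls, mix in self.brand_mix.items():
            _normalize_mix(f"brand_mix[{cls}]", mix, errors)
        for name in (
            "variant_rate",
            "typo_rate",
            "decoy_rate",
            "disagreement_rate",
            "balloon_rate",
            "radial_rate",
            "emergent_rate",
            "male_rate",
            "hypertension_rate",
            "diabetes_rate",
            "mixed_class_rate",
            "same_brand_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}: {v} outside [0, 1]")
        for name in ("diameter_sd", "length_sd", "dapt_sd_days", "age_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name}: negative")
        if self.baseline_rate <= 0:
            errors.append("baseline_rate: must be positive")
        if not 0 < self.censor_low_days <= self.censor_high_days:
            errors.append("censoring bounds: need 0 < low <= high")
        if self.window_days <= 0:
            errors.append("window_days: must be positive")
        if errors:
            raise ValueError("invalid generator config: " + "; ".join(errors))


@dataclass
class SyntheticCohort:
    """Generated cohort: patient tables, per-stent/episode truth, manifest."""

    config: GeneratorConfig
    manifest: pd.DataFrame  # report_id, patient_id, procedure_date
    stents: pd.DataFrame  # one row per implanted stent (the full truth)
    episodes: pd.DataFrame  # one row per (patient, vessel): truth covariates & outcome
    demographics: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame

    @property
    def patient_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "demographics": self.demographics,
            "diagnoses": self.diagnoses,
            "prescriptions": self.prescriptions,
            "procedures": self.procedures,
        }

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        (outdir / "patients").mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        for name, frame in self.patient_tables.items():
            frame.to_csv(outdir / "patients" / f"{name}.csv", index=False)
        export_gold(self).to_csv(outdir / "gold.csv", index=False)
        truth = {
            "stents": self.stents.to_dict(orient="records"),
            "episodes": self.episodes.to_dict(orient="records"),
        }
        (outdir / "truth.json").write_text(
            json.dumps(truth, indent=1, default=str), encoding="utf-8"
        )


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = list(mix)
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _round_quarter(x: float) -> float:
    return round(x * 4) / 4


def generate_cohort(
    config: Optional[GeneratorConfig] = None, lexicon: Optional[TermLexicon] = None
) -> SyntheticCohort:
    """Draw a full synthetic cohort under ``config`` (deterministic per seed)."""
    config = config or GeneratorConfig()
    config.validate()
    lexicon = lexicon or TermLexicon.default()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(3)[0]))

    base_date = pd.Timestamp("2010-02-01")
    stent_rows, episode_rows = [], []
    manifest_rows, demo_rows, dx_rows, rx_rows, proc_rows = [], [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        rid = f"R{i:05d}"
        index_date = base_date + pd.Timedelta(days=int(rng.integers(0, 1700)))
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 25, 95))
        age = float(int(age))
        sex = "M" if rng.random() < config.male_rate else "F"
        hypertension = bool(rng.random() < config.hypertension_rate)
        diabetes = bool(rng.random() < config.diabetes_rate)
        approach = "radial" if rng.random() < config.radial_rate else "femoral"
        emergent = bool(rng.random() < config.emergent_rate)
        censor_days = int(
            rng.integers(config.censor_low_days, config.censor_high_days + 1)
        )
        dapt_draw = max(0.0, rng.normal(config.dapt_mean_days, config.dapt_sd_days))
        dapt_days = int(min(dapt_draw, censor_days))  # observable DAPT only
        dapt_over_12mo = dapt_days >= 365

        # demographics: birth date back-computed so that integer age at the
        # index date reproduces the drawn age exactly
        birth_date = (
            index_date
            - pd.Timedelta(days=round(age * 365.25))
            - pd.Timedelta(days=120)
        )
        demo_rows.append(
            {"patient_id": pid, "birth_date": birth_date.date(), "sex": sex}
        )

        # diagnoses / prescriptions establishing the phenotypes
        def _phenotype(code: str, drug: str, present: bool) -> None:
            if not present:
                return
            u = rng.random()
            if u < 0.8:
                dx_rows.append(
                    {
                        "patient_id": pid,
                        "code": code,
                        "date": (index_date - pd.Timedelta(days=int(rng.integers(30, 1000)))).date(),
                    }
                )
            if u >= 0.4:
                start = index_date - pd.Timedelta(days=int(rng.integers(60, 400)))
                rx_rows.append(
                    {
                        "patient_id": pid,
                        "drug_class": drug,
                        "start": start.date(),
                        "end": (start + pd.Timedelta(days=30)).date(),
                    }
                )

        _phenotype("I10", "amlodipine", hypertension)
        _phenotype("E11", "metformin", diabetes)

        # DAPT prescriptions post-index (aspirin runs longer than the P2Y12)
        if dapt_days > 0:
            aspirin_end = min(dapt_days + 180, censor_days)
            rx_rows.append(
                {
                    "patient_id": pid,
                    "drug_class": "aspirin",
                    "start": index_date.date(),
                    "end": (index_date + pd.Timedelta(days=aspirin_end)).date(),
                }
            )
            rx_rows.append(
                {
                    "patient_id": pid,
                    "drug_class": "clopidogrel",
                    "start": index_date.date(),
                    "end": (index_date + pd.Timedelta(days=dapt_days)).date(),
                }
            )

        # index PCI + administrative last-contact visit
        proc_rows.append(
            {
                "patient_id": pid,
                "date": index_date.date(),
                "type": "PCI",
                "vessel": "",
                "approach": approach,
                "emergent": emergent,
            }
        )
        proc_rows.append(
            {
                "patient_id": pid,
                "date": (index_date + pd.Timedelta(days=censor_days)).date(),
                "type": "visit",
                "vessel": "",
                "approach": "",
                "emergent": False,
            }
        )
        manifest_rows.append(
            {
                "report_id": rid,
                "patient_id": pid,
                "procedure_date": index_date.date().isoformat(),
            }
        )

        # treated vessels
        n_vessels = 1 + int(
            rng.choice(len(config.vessels_per_patient), p=config.vessels_per_patient)
        )
        weights = config.vessel_weights
        vessels = list(
            rng.choice(
                list(weights),
                size=min(n_vessels, len(weights)),
                replace=False,
                p=np.asarray(list(weights.values())) / sum(weights.values()),
            )
        )
        for vessel in vessels:
            n_stents = 1 + int(
                rng.choice(len(config.stents_per_vessel), p=config.stents_per_vessel)
            )
            cls = _choice(rng, config.class_mix)
            brand = _choice(rng, config.brand_mix[cls])
            classes, brands = [], []
            diameters, lengths = [], []
            for k in range(n_stents):
                if k > 0 and rng.random() < config.mixed_class_rate:
                    cls = _choice(rng, config.class_mix)
                    brand = _choice(rng, config.brand_mix[cls])
                elif k > 0 and rng.random() >= config.same_brand_rate:
                    brand = _choice(rng, config.brand_mix[cls])
                d = _round_quarter(
                    float(
                        np.clip(
                            rng.normal(config.diameter_mean, config.diameter_sd),
                            *config.diameter_range,
                        )
                    )
                )
                ln = float(
                    int(
                        np.clip(
                            rng.normal(config.length_mean, config.length_sd),
                            *config.length_range,
                        )
                    )
                )
                classes.append(cls)
                brands.append(brand)
                diameters.append(d)
                lengths.append(ln)
                stent_rows.append(
                    {
                        "report_id": rid,
                        "patient_id": pid,
                        "vessel": vessel,
                        "brand_family": brand,
                        "stent_class": cls,
                        "diameter_mm": d,
                        "length_mm": ln,
                    }
                )
            balloon = bool(rng.random() < config.balloon_rate)

            # proportional-hazards event time for this vessel episode
            lp = config.class_log_hr[classes[0]]
            cov = config.covariate_log_hr
            lp += cov.get("hypertension", 0.0) * hypertension
            lp += cov.get("diabetes", 0.0) * diabetes
            lp += cov.get("dapt_over_12mo", 0.0) * dapt_over_12mo
            lp += cov.get("emergent", 0.0) * emergent
            lp += cov.get("age_per_year", 0.0) * (age - config.age_mean)
            lam = config.baseline_rate * math.exp(lp)
            t_event = float(rng.exponential(1.0 / lam))
            horizon = min(censor_days, config.window_days)
            event = t_event <= horizon
            followup = max(1, int(math.ceil(t_event)) if event else horizon)
            if event:
                proc_rows.append(
                    {
                        "patient_id": pid,
                        "date": (index_date + pd.Timedelta(days=followup)).date(),
                        "type": "PCI",
                        "vessel": vessel,
                        "approach": approach,
                        "emergent": False,
                    }
                )
            episode_rows.append(
                {
                    "patient_id": pid,
                    "report_id": rid,
                    "vessel": vessel,
                    "classes": "+".join(sorted(set(classes))),
                    "brands": "+".join(sorted(set(brands))),
                    "hazard_class": classes[0],
                    "n_stents": n_stents,
                    "total_length_mm": float(sum(lengths)),
                    "mean_diameter_mm": float(np.mean(diameters)),
                    "balloon_used": balloon,
                    "approach": approach,
                    "emergent": emergent,
                    "age": age,
                    "sex": sex,
                    "hypertension": hypertension,
                    "diabetes": diabetes,
                    "dapt_days": dapt_days,
                    "dapt_over_12mo": dapt_over_12mo,
                    "index_date": index_date.date().isoformat(),
                    "censor_days": censor_days,
                    "true_event_days": t_event,
                    "tvr_event": event,
                    "followup_days": followup,
                }
            )

    return SyntheticCohort(
        config=config,
        manifest=pd.DataFrame(
            manifest_rows, columns=["report_id", "patient_id", "procedure_date"]
        ),
        stents=pd.DataFrame(
            stent_rows,
            columns=[
                "report_id",
                "patient_id",
                "vessel",
                "brand_family",
                "stent_class",
                "diameter_mm",
                "length_mm",
            ],
        ),
        episodes=pd.DataFrame(episode_rows),
        demographics=pd.DataFrame(
            demo_rows, columns=["patient_id", "birth_date", "sex"]
        ),
        diagnoses=pd.DataFrame(dx_rows, columns=["patient_id", "code", "date"]),
        prescriptions=pd.DataFrame(
            rx_rows, columns=["patient_id", "drug_class", "start", "end"]
        ),
        procedures=pd.DataFrame(
            proc_rows,
            columns=["patient_id", "date", "type", "vessel", "approach", "emergent"],
        ),
    )


# ---------------------------------------------------------------------------
# report rendering


def _corrupt(token: str, rng: np.random.Generator, lexicon: TermLexicon) -> str:
    """Damage a surface form so it no longer resolves in the lexicon."""
    for _ in range(10):
        kind = rng.integers(0, 3)
        if kind == 0 and len(token) > 2:
            i = int(rng.integers(1, len(token)))
            cand = token[:i] + token[i + 1 :]
        elif kind == 1 and len(token) > 2:
            i = int(rng.integers(0, len(token) - 1))
            cand = token[:i] + token[i + 1] + token[i] + token[i + 2 :]
        else:
            cand = token + "q"
        if cand not in lexicon:
            return cand
    return token + "zzq"


def _surface(
    canonical: str,
    forms: list[str],
    rng: np.random.Generator,
    variant_rate: float,
    typo_rate: float,
    lexicon: TermLexicon,
) -> str:
    variants = [f for f in forms if f != canonical]
    form = canonical
    if variants and rng.random() < variant_rate:
        form = variants[int(rng.integers(0, len(variants)))]
    if rng.random() < typo_rate:
        form = _corrupt(form, rng, lexicon)
    return form


def _format_dim(diameter: float, length: float, rng: np.random.Generator) -> str:
    d = f"{diameter:.2f}".rstrip("0").rstrip(".")
    ln = f"{length:.0f}"
    mm = " mm" if rng.random() < 0.25 else "mm"
    return f"{d}/{ln}{mm}"


def render_reports(
    cohort: SyntheticCohort,
    lexicon: Optional[TermLexicon] = None,
) -> list[ReportDocument]:
    """Render one semi-structured report per generated procedure.

    Surface noise (variants, typos, decoys) is drawn from a dedicated stream
    of the cohort seed, so corpus and truth stay hash-linked; the gold
    annotations are unaffected by rendering noise.
    """
    config = cohort.config
    lexicon = lexicon or TermLexicon.default()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(3)[1]))
    balloon_forms = lexicon.forms("balloon")

    stents_by_report = dict(tuple(cohort.stents.groupby("report_id", sort=False)))
    episodes_by_report = dict(tuple(cohort.episodes.groupby("report_id", sort=False)))
    docs = []
    for row in cohort.manifest.itertuples(index=False):
        rid = str(row.report_id)
        lines = ["Coronary angiography and PCI procedure note"]
        if rng.random() < config.decoy_rate:
            header = DECOY_HEADERS[int(rng.integers(0, len(DECOY_HEADERS)))]
            filler = DECOY_LINES[int(rng.integers(0, len(DECOY_LINES)))]
            lines.append(f"{header}: {filler}")
        episodes = episodes_by_report.get(rid)
        stents = stents_by_report.get(rid)
        if episodes is not None:
            for ep in episodes.itertuples(index=False):
                vessel = VesselCategory(ep.vessel)
                header = _surface(
                    vessel.value,
                    lexicon.vessel_forms(vessel),
                    rng,
                    config.variant_rate,
                    config.typo_rate,
                    lexicon,
                )
                lines.append(f"{header}:")
                vessel_stents = stents[stents["vessel"] == ep.vessel]
                for st in vessel_stents.itertuples(index=False):
                    name = _surface(
                        st.brand_family,
                        lexicon.stent_forms(st.brand_family),
                        rng,
                        config.variant_rate,
                        config.typo_rate,
                        lexicon,
                    )
                    dim = _format_dim(st.diameter_mm, st.length_mm, rng)
                    lines.append(f"  {name} {dim}")
                if ep.balloon_used:
                    u = rng.random()
                    if u < 0.5:
                        lines.append("  post-dilation with HP")
                    elif u < 0.8:
                        brand = balloon_forms[int(rng.integers(0, len(balloon_forms)))]
                        dim = _format_dim(
                            _round_quarter(float(rng.uniform(2.5, 4.5))),
                            float(int(rng.uniform(8, 20))),
                            rng,
                        )
                        lines.append(f"  post-dilation with {brand} {dim}")
                    else:
                        brand = balloon_forms[int(rng.integers(0, len(balloon_forms)))]
                        lines.append(f"  {brand} noncompliant balloon used")
                if rng.random() < config.decoy_rate:
                    lines.append(
                        "  " + DECOY_LINES[int(rng.integers(0, len(DECOY_LINES)))]
                    )
        docs.append(
            ReportDocument(
                report_id=rid,
                patient_id=str(row.patient_id),
                procedure_date=str(row.procedure_date),
                text="\n".join(lines) + "\n",
            )
        )
    return docs


def write_corpus(docs: list[ReportDocument], outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in docs:
        (outdir / f"{doc.report_id}.txt").write_text(doc.text, encoding="utf-8")
        rows.append(
            {
                "report_id": doc.report_id,
                "patient_id": doc.patient_id,
                "procedure_date": doc.procedure_date,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)


def export_gold(cohort: SyntheticCohort) -> pd.DataFrame:
    """Gold-standard pair table: one row per distinct
    (report, vessel, brand) assertion, with its class label."""
    cols = ["report_id", "vessel", "brand_family", "stent_class"]
    if cohort.stents.empty:
        return pd.DataFrame(columns=cols)
    gold = cohort.stents[cols].drop_duplicates().reset_index(drop=True)
    return gold.sort_values(cols, kind="mergesort").reset_index(drop=True)


def simulate_extractor_variants(
    cohort: SyntheticCohort,
    granularity: str = "category",
    rate: Optional[float] = None,
    n_extractors: int = 3,
) -> list[dict[str, frozenset[tuple[str, str]]]]:
    """Simulate independently written extraction scripts.

    Each true (report, pair) description is, with probability ``rate``
    (default: the config's disagreement rate), missed by exactly one of the
    extractors — the characteristic failure mode of a pattern that is too
    narrow. Returns ``n_extractors`` plain report->pairs mappings.
    """
    config = cohort.config
    rate = config.disagreement_rate if rate is None else rate
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(3)[2]))
    label_col = "stent_class" if granularity == "category" else "brand_family"
    gold = export_gold(cohort)
    outputs: list[dict[str, set]] = [
        {rid: set() for rid in cohort.manifest["report_id"].astype(str)}
        for _ in range(n_extractors)
    ]
    for row in gold.itertuples(index=False):
        pair = (str(row.vessel), str(getattr(row, label_col)))
        drop = (
            int(rng.integers(0, n_extractors)) if rng.random() < rate else None
        )
        for k, out in enumerate(outputs):
            if k != drop:
                out.setdefault(str(row.report_id), set()).add(pair)
    return [
        {rid: frozenset(pairs) for rid, pairs in out.items()} for out in outputs
    ]
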