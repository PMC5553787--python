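"""Validation machinery for the extraction pipeline.

The unit of validation is the *pair set*: the distinct (target vessel
category, stent category) assertions of one report. Extractor output is
scored against a gold standard with pair-level confusion counts over a closed
negative universe (all vessel x stent-label combinations not asserted),
yielding sensitivity, specificity, PPV, NPV and F-measure. Agreement between
two extractors is summarized by Cohen's kappa over the pooled binary
present/absent slots, and three extractor outputs are merged by unanimity:
pairs asserted by all three are accepted, anything asserted by only one or
two is queued for manual adjudication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .report_parser import ProcedureRecord
from .terminology import CLASS_LABELS, TermLexicon, VesselCategory, class_label

__all__ = [
    "PairSet",
    "ConfusionCounts",
    "AgreementResult",
    "ConsensusOutcome",
    "pair_universe",
    "to_pair_set",
    "pair_sets_from_frame",
    "as_pair_sets",
    "confusion_counts",
    "pooled_confusion",
    "metrics",
    "cohen_kappa",
    "consensus_merge",
]

Pair = tuple[str, str]
PairSetCollection = Mapping[str, "PairSet"]


def pair_universe(
    granularity: str = "category", lexicon: Optional[TermLexicon] = None
) -> frozenset[Pair]:
    """The closed universe of (vessel, stent label) slots for one report.

    ``category`` granularity crosses the four vessel categories with the four
    stent class labels (16 slots); ``brand`` crosses them with the brand
    families of the lexicon (default lexicon if not given).
    """
    vessels = [v.value for v in VesselCategory]
    if granularity == "category":
        labels: Iterable[str] = CLASS_LABELS
    elif granularity == "brand":
        lexicon = lexicon or TermLexicon.default()
        labels = sorted(lexicon.brand_families)
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    return frozenset((v, s) for v in vessels for s in labels)


@dataclass(frozen=True)
class PairSet:
    """The (vessel, stent label) assertions of one report, with its universe."""

    report_id: str
    pairs: frozenset[Pair]
    universe: frozenset[Pair]

    def __post_init__(self) -> None:
        if not self.pairs <= self.universe:
            extra = sorted(self.pairs - self.universe)
            raise ValueError(f"pairs outside the universe: {extra}")


def to_pair_set(
    record: ProcedureRecord,
    granularity: str = "category",
    universe: Optional[frozenset[Pair]] = None,
) -> PairSet:
    universe = universe or pair_universe(granularity)
    return PairSet(
        report_id=record.report_id,
        pairs=record.pair_set(granularity),
        universe=universe,
    )


def pair_sets_from_frame(
    frame: pd.DataFrame,
    granularity: str = "category",
    universe: Optional[frozenset[Pair]] = None,
    report_ids: Optional[Iterable[str]] = None,
) -> dict[str, PairSet]:
    """Build a PairSet per report from an extraction or gold table.

    The frame needs columns ``report_id``, ``vessel`` and a stent label:
    ``stent_class`` (or derivable from device_class/generation/polymer) for
    category granularity, ``brand_family`` for brand granularity. Reports in
    ``report_ids`` that have no rows yield empty pair sets.
    """
    universe = universe or pair_universe(granularity)
    if granularity == "category":
        if "stent_class" in frame.columns:
            labels = frame["stent_class"]
        else:
            labels = [
                class_label(dc, g, p)
                for dc, g, p in zip(
                    frame["device_class"], frame["generation"], frame["polymer"]
                )
            ]
    elif granularity == "brand":
        labels = frame["brand_family"]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    by_report: dict[str, set[Pair]] = {}
    for rid, vessel, label in zip(frame["report_id"], frame["vessel"], labels):
        by_report.setdefault(str(rid), set()).add((str(vessel), str(label)))
    ids = set(map(str, report_ids)) if report_ids is not None else set(by_report)
    return {
        rid: PairSet(rid, frozenset(by_report.get(rid, set())), universe)
        for rid in sorted(ids)
    }


def as_pair_sets(
    mapping: Mapping[str, Iterable[Pair]],
    granularity: str = "category",
    universe: Optional[frozenset[Pair]] = None,
) -> dict[str, PairSet]:
    """Wrap a plain report -> pairs mapping into a PairSet collection."""
    universe = universe or pair_universe(granularity)
    return {
        str(rid): PairSet(str(rid), frozenset(pairs), universe)
        for rid, pairs in mapping.items()
    }


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(predicted: PairSet, gold: PairSet) -> ConfusionCounts:
    """Pair-level confusion for one report over the shared universe."""
    if predicted.universe != gold.universe:
        raise ValueError("predicted and gold pair sets use different universes")
    tp = len(predicted.pairs & gold.pairs)
    fp = len(predicted.pairs - gold.pairs)
    fn = len(gold.pairs - predicted.pairs)
    tn = len(predicted.universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def pooled_confusion(
    predicted: PairSetCollection, gold: PairSetCollection
) -> ConfusionCounts:
    """Sum per-report confusion counts over the union of report ids; a report
    missing from one collection counts as an empty pair set."""
    universes = {ps.universe for ps in list(predicted.values()) + list(gold.values())}
    if len(universes) != 1:
        raise ValueError("all pair sets must share one universe")
    universe = universes.pop()
    total = ConfusionCounts()
    for rid in sorted(set(predicted) | set(gold)):
        p = predicted.get(rid) or PairSet(rid, frozenset(), universe)
        g = gold.get(rid) or PairSet(rid, frozenset(), universe)
        total = total + confusion_counts(p, g)
    return total


@dataclass(frozen=True)
class AgreementResult:
    """Validation metrics; ``None`` marks an undefined (zero-denominator) one."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f_measure: Optional[float]
    kappa: Optional[float] = None


def harmonic_mean(ppv: float, sensitivity: float) -> Optional[float]:
    if ppv + sensitivity == 0:
        return None
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def metrics(counts: ConfusionCounts) -> AgreementResult:
    """Sensitivity, specificity, PPV, NPV and F-measure from pooled counts."""

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    ppv = ratio(counts.tp, counts.tp + counts.fp)
    npv = ratio(counts.tn, counts.tn + counts.fn)
    f = harmonic_mean(ppv, sens) if ppv is not None and sens is not None else None
    return AgreementResult(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f_measure=f
    )


def _slot_vectors(
    a: PairSetCollection, b: PairSetCollection
) -> tuple[list[bool], list[bool]]:
    universes = {ps.universe for ps in list(a.values()) + list(b.values())}
    if len(universes) != 1:
        raise ValueError("all pair sets must share one universe")
    universe = sorted(universes.pop())
    ids = sorted(set(a) | set(b))
    av, bv = [], []
    for rid in ids:
        pa = a[rid].pairs if rid in a else frozenset()
        pb = b[rid].pairs if rid in b else frozenset()
        for slot in universe:
            av.append(slot in pa)
            bv.append(slot in pb)
    return av, bv


def cohen_kappa(a: PairSetCollection, b: PairSetCollection) -> Optional[float]:
    """Chance-corrected agreement between two extractors.

    Each (report, universe slot) is a binary present/absent rating; kappa =
    (p_o - p_e) / (1 - p_e) with p_e from the raters' marginal frequencies.
    Returns ``None`` when both raters are constant (p_e = 1).
    """
    av, bv = _slot_vectors(a, b)
    n = len(av)
    if n == 0:
        return None
    p_o = sum(x == y for x, y in zip(av, bv)) / n
    pa = sum(av) / n
    pb = sum(bv) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1 - p_e)


@dataclass(frozen=True)
class DisputedItem:
    report_id: str
    vessel: str
    stent_label: str


@dataclass
class ConsensusOutcome:
    """Result of the three-extractor unanimity merge."""

    accepted: dict[str, frozenset[Pair]]
    disputed: list[DisputedItem]
    universe: frozenset[Pair]
    n_union_pairs: int = 0

    def disputed_frame(self) -> pd.DataFrame:
        """Adjudication queue, ready to be filled in with verdicts."""
        return pd.DataFrame(
            [
                {
                    "report_id": d.report_id,
                    "vessel": d.vessel,
                    "stent_label": d.stent_label,
                    "verdict": "",
                    "adjudicator": "",
                    "note": "",
                }
                for d in self.disputed
            ],
            columns=["report_id", "vessel", "stent_label", "verdict", "adjudicator", "note"],
        )

    @property
    def disputed_fraction(self) -> float:
        """Share of asserted descriptions that did not reach consensus."""
        return len(self.disputed) / self.n_union_pairs if self.n_union_pairs else 0.0

    def resolve(self, adjudications: pd.DataFrame) -> dict[str, frozenset[Pair]]:
        """Merge adjudicated verdicts into the accepted pairs.

        Every disputed item must receive a verdict in {present, absent}; an
        adjudication row that does not reference a disputed item is an error.
        """
        disputed = {(d.report_id, d.vessel, d.stent_label) for d in self.disputed}
        final: dict[str, set[Pair]] = {
            rid: set(pairs) for rid, pairs in self.accepted.items()
        }
        for row in adjudications.itertuples(index=False):
            key = (str(row.report_id), str(row.vessel), str(row.stent_label))
            if key not in disputed:
                raise ValueError(f"adjudication for unknown item {key}")
            if row.verdict not in ("present", "absent"):
                raise ValueError(f"verdict must be present/absent, got {row.verdict!r}")
            if row.verdict == "present":
                final.setdefault(key[0], set()).add((key[1], key[2]))
        return {rid: frozenset(pairs) for rid, pairs in final.items()}


def consensus_merge(
    a: PairSetCollection, b: PairSetCollection, c: PairSetCollection
) -> ConsensusOutcome:
    """Unanimity merge of three extractor outputs.

    A pair is accepted iff asserted by all three; a pair asserted by one or
    two is disputed and queued for manual adjudication (majority does not
    decide). Permutation-invariant in its three inputs.
    """
    universes = {
        ps.universe for coll in (a, b, c) for ps in coll.values()
    }
    if len(universes) != 1:
        raise ValueError("all pair sets must share one universe")
    universe = universes.pop()
    ids = sorted(set(a) | set(b) | set(c))
    accepted: dict[str, frozenset[Pair]] = {}
    disputed: list[DisputedItem] = []
    n_union = 0
    for rid in ids:
        sets = [
            coll[rid].pairs if rid in coll else frozenset() for coll in (a, b, c)
        ]
        unanimous = sets[0] & sets[1] & sets[2]
        union = sets[0] | sets[1] | sets[2]
        accepted[rid] = frozenset(unanimous)
        n_union += len(union)
        for vessel, label in sorted(union - unanimous):
            disputed.append(DisputedItem(rid, vessel, label))
    return ConsensusOutcome(
        accepted=accepted, disputed=disputed, universe=universe, n_union_pairs=n_union
    )
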