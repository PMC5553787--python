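"""Vessel and stent vocabulary for percutaneous coronary intervention (PCI) reports.

The extraction pipeline is dictionary-driven: every surface form it can
recognise — coronary target-vessel names and their branches, stent brand
names with their device taxonomy (bare-metal vs drug-eluting, generation,
polymer coating), and non-compliant high-pressure balloon brands — lives in
a :class:`TermLexicon`.

The shipped lexicon covers the four target-vessel categories (LAD, LCx, LM,
RCA, each with its named branch vessels) and the stent brand families grouped
as BMS, first-generation DES, and durable- vs biodegradable-polymer
second-generation DES. It is a plain tab-delimited file so the vocabulary can
be revised without touching code; additional spellings and abbreviations are
added at run time with :meth:`TermLexicon.register_variant` — matching is
exact (after normalization), so sensitivity depends entirely on the coverage
of registered forms.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "VesselCategory",
    "StentCategory",
    "TermLexicon",
    "LexiconConflictError",
    "normalize_token",
    "class_label",
]

_NA = "-"


class VesselCategory(str, enum.Enum):
    """The four target-vessel categories of the coronary tree."""

    LAD = "LAD"  # left anterior descending
    LCX = "LCx"  # left circumflex
    LM = "LM"  # left main
    RCA = "RCA"  # right coronary artery

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Stent class labels used throughout the package.
CLASS_LABELS = ("BMS", "DES1", "DES2-DP", "DES2-BP")


def class_label(device_class: str, generation: str, polymer: str) -> str:
    """Collapse the (class, generation, polymer) triple into one of the four
    stent class labels: BMS, DES1 (first-generation DES), DES2-DP
    (durable-polymer second generation), DES2-BP (biodegradable polymer)."""
    if device_class == "BMS":
        return "BMS"
    if generation == "first":
        return "DES1"
    if polymer == "durable":
        return "DES2-DP"
    if polymer == "biodegradable":
        return "DES2-BP"
    raise ValueError(
        f"unclassifiable stent: class={device_class!r} generation={generation!r} "
        f"polymer={polymer!r}"
    )


@dataclass(frozen=True)
class StentCategory:
    """Taxonomic position of a stent brand family.

    Invariants: BMS carry ``generation == polymer == 'none'``; only
    second-generation DES carry a polymer label (the first generation is not
    subdivided by polymer).
    """

    brand_family: str
    device_class: str  # "BMS" | "DES"
    generation: str  # "none" | "first" | "second"
    polymer: str  # "none" | "durable" | "biodegradable"

    def __post_init__(self) -> None:
        if self.device_class not in ("BMS", "DES"):
            raise ValueError(f"unknown device class {self.device_class!r}")
        if (self.device_class == "BMS") != (self.generation == "none"):
            raise ValueError("generation is 'none' exactly for BMS")
        if (self.generation == "second") != (self.polymer != "none"):
            raise ValueError("polymer is set exactly for second-generation DES")
        if self.polymer not in ("none", "durable", "biodegradable"):
            raise ValueError(f"unknown polymer {self.polymer!r}")

    @property
    def class_label(self) -> str:
        return class_label(self.device_class, self.generation, self.polymer)


_EDGE_RE = re.compile(
    r"^[\s\.\,\:\;\!\?\(\)\[\]\{\}\'\"“”‘’\-–—/]+"
    r"|[\s\.\,\:\;\!\?\(\)\[\]\{\}\'\"“”‘’\-–—/]+$"
)
_WS_RE = re.compile(r"\s+")


def normalize_token(raw: str) -> str:
    """Normalize a surface form: strip surrounding whitespace/punctuation,
    collapse internal whitespace, case-fold. Idempotent; '' maps to ''."""
    s = _EDGE_RE.sub("", raw)
    s = _WS_RE.sub(" ", s)
    return s.casefold()


class LexiconConflictError(ValueError):
    """A surface form is already registered with a different target."""


@dataclass(frozen=True)
class LexiconEntry:
    term: str  # original surface form as registered
    kind: str  # "vessel" | "stent" | "balloon"
    target: Optional[Union[VesselCategory, StentCategory]]  # None for balloons


class TermLexicon:
    """Normalized surface form -> (kind, target) dictionary.

    Lookup is total over registered forms and returns at most one target per
    form; matching elsewhere in the package is case-insensitive because every
    key is stored normalized.
    """

    def __init__(self, endeavor_first_generation: bool = False):
        self._entries: dict[str, LexiconEntry] = {}
        self._families: dict[str, StentCategory] = {}
        self.source_path: Optional[Path] = None
        #: Reclassify the Endeavor family as first-generation (durable-polymer
        #: zotarolimus stents are sometimes grouped with the old generation,
        #: e.g. in the SCAAR registry); off by default.
        self.endeavor_first_generation = endeavor_first_generation
        self._stent_rx: Optional[re.Pattern] = None
        self._balloon_rx: Optional[re.Pattern] = None

    # -- construction -----------------------------------------------------

    def add(
        self,
        term: str,
        kind: str,
        target: Optional[Union[VesselCategory, StentCategory]] = None,
    ) -> None:
        if kind not in ("vessel", "stent", "balloon"):
            raise ValueError(f"unknown kind {kind!r}")
        key = normalize_token(term)
        if not key:
            raise ValueError("cannot register an empty surface form")
        existing = self._entries.get(key)
        if existing is not None:
            if existing.kind != kind or existing.target != target:
                raise LexiconConflictError(
                    f"{term!r} already registered as {existing.kind} -> "
                    f"{existing.target!r}"
                )
            return
        if kind == "stent":
            assert isinstance(target, StentCategory)
            self._families.setdefault(target.brand_family, target)
        self._entries[key] = LexiconEntry(term=term.strip(), kind=kind, target=target)
        self._stent_rx = None
        self._balloon_rx = None

    def register_variant(self, variant: str, target: str) -> "TermLexicon":
        """Register ``variant`` as a new spelling of an existing entry.

        ``target`` may be an already-registered surface form, a vessel code,
        or a stent brand family name. Conflicts (variant already mapped to a
        different target) raise :class:`LexiconConflictError`.
        """
        key = normalize_token(target)
        if key in self._entries:
            entry = self._entries[key]
            self.add(variant, entry.kind, entry.target)
            return self
        if target in self._families:
            self.add(variant, "stent", self._families[target])
            return self
        try:
            cat = VesselCategory(target)
        except ValueError:
            raise KeyError(f"unknown registration target {target!r}") from None
        self.add(variant, "vessel", cat)
        return self

    # -- lookup ------------------------------------------------------------

    def lookup(self, token: str) -> Optional[LexiconEntry]:
        return self._entries.get(normalize_token(token))

    def lookup_vessel(self, token: str) -> Optional[VesselCategory]:
        entry = self.lookup(token)
        if entry is not None and entry.kind == "vessel":
            return entry.target  # type: ignore[return-value]
        return None

    def lookup_stent(self, token: str) -> Optional[StentCategory]:
        entry = self.lookup(token)
        if entry is not None and entry.kind == "stent":
            return entry.target  # type: ignore[return-value]
        return None

    def __contains__(self, token: str) -> bool:
        return normalize_token(token) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    # -- enumeration (used by the synthetic corpus generator) --------------

    @property
    def brand_families(self) -> dict[str, StentCategory]:
        return dict(self._families)

    def forms(self, kind: str) -> list[str]:
        return [e.term for e in self._entries.values() if e.kind == kind]

    def vessel_forms(self, category: VesselCategory) -> list[str]:
        return [
            e.term
            for e in self._entries.values()
            if e.kind == "vessel" and e.target == category
        ]

    def stent_forms(self, brand_family: str) -> list[str]:
        return [
            e.term
            for e in self._entries.values()
            if e.kind == "stent" and e.target.brand_family == brand_family
        ]

    # -- compiled patterns for in-text matching ----------------------------

    @staticmethod
    def _compile(forms: Iterable[str]) -> re.Pattern:
        keys = sorted({normalize_token(f) for f in forms}, key=len, reverse=True)
        if not keys:
            return re.compile(r"(?!x)x")  # matches nothing
        # re.escape may render a space as "\ " depending on the version
        alt = "|".join(
            re.escape(k).replace(r"\ ", " ").replace(" ", r"\s+") for k in keys
        )
        return re.compile(rf"(?<!\w)(?:{alt})(?!\w)", re.IGNORECASE)

    def stent_pattern(self) -> re.Pattern:
        if self._stent_rx is None:
            self._stent_rx = self._compile(self.forms("stent"))
        return self._stent_rx

    def balloon_pattern(self) -> re.Pattern:
        if self._balloon_rx is None:
            self._balloon_rx = self._compile(self.forms("balloon"))
        return self._balloon_rx

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_file(
        cls, path: Union[str, Path], endeavor_first_generation: bool = False
    ) -> "TermLexicon":
        """Load a tab-delimited lexicon with columns
        term, kind, category, device_class, generation, polymer."""
        lex = cls(endeavor_first_generation=endeavor_first_generation)
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.lower().startswith("term"):
                raise ValueError(f"{path}: missing lexicon header line")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns")
                term, kind, category, device_class, generation, polymer = fields
                if kind == "vessel":
                    lex.add(term, "vessel", VesselCategory(category))
                elif kind == "stent":
                    if endeavor_first_generation and category == "Endeavor":
                        generation, polymer = "first", "none"
                    cat = lex._families.get(category) or StentCategory(
                        brand_family=category,
                        device_class=device_class,
                        generation=generation,
                        polymer=polymer,
                    )
                    lex.add(term, "stent", cat)
                elif kind == "balloon":
                    lex.add(term, "balloon", None)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
        lex.source_path = path
        return lex

    @classmethod
    def default(cls, endeavor_first_generation: bool = False) -> "TermLexicon":
        """The shipped vessel/stent/balloon lexicon."""
        with resources.as_file(
            resources.files("stentminer.data") / "lexicon.tsv"
        ) as path:
            return cls.from_file(
                path, endeavor_first_generation=endeavor_first_generation
            )

    def to_file(self, path: Union[str, Path]) -> None:
        lines = ["term\tkind\tcategory\tdevice_class\tgeneration\tpolymer"]
        for entry in self._entries.values():
            if entry.kind == "vessel":
                cat = entry.target.value  # type: ignore[union-attr]
                lines.append(f"{entry.term}\tvessel\t{cat}\t{_NA}\t{_NA}\t{_NA}")
            elif entry.kind == "stent":
                t = entry.target
                lines.append(
                    f"{entry.term}\tstent\t{t.brand_family}\t{t.device_class}"
                    f"\t{t.generation}\t{t.polymer}"
                )
            else:
                lines.append(f"{entry.term}\tballoon\t{_NA}\t{_NA}\t{_NA}\t{_NA}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
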