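"""Shared data model for clinical-text pseudonymization.

The package revolves around a nine-class taxonomy of personally identifiable
information (PII) derived from the HIPAA list of protected health information
(PHI): direct identifiers (names, phone numbers) and quasi-identifiers (ages,
dates, locations, care units, organizations).  Documents carry their PII
annotations as character-offset spans; every downstream component — detection,
surrogate replacement, evaluation — consumes and produces this representation.

Offsets are 0-based, half-open, counted in unicode code points.
"""

from __future__ import annotations

import enum
import string
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "PiiClass",
    "EntitySpan",
    "AnnotatedDocument",
    "Gazetteer",
    "CorpusStats",
    "tokenize",
    "corpus_stats",
    "doc_rng",
]


class PiiClass(str, enum.Enum):
    """The nine PII entity classes shared by every component.

    The taxonomy covers direct identifiers (first/last names, phone numbers)
    and quasi-identifiers (ages, full and partial dates, health-care units,
    locations including postal codes, organizations).
    """

    AGE = "Age"
    FIRST_NAME = "FirstName"
    LAST_NAME = "LastName"
    PARTIAL_DATE = "PartialDate"
    FULL_DATE = "FullDate"
    PHONE_NUMBER = "PhoneNumber"
    HEALTH_CARE_UNIT = "HealthCareUnit"
    LOCATION = "Location"
    ORGANIZATION = "Organization"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ValidationError(ValueError):
    """Raised when a document, span, or resource violates an invariant."""


@dataclass(frozen=True)
class EntitySpan:
    """A typed PII mention: character offsets [start, end) plus surface text."""

    start: int
    end: int
    pii_class: PiiClass
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span offsets [{self.start}, {self.end})"
            )
        if not isinstance(self.pii_class, PiiClass):
            object.__setattr__(self, "pii_class", PiiClass(self.pii_class))

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotatedDocument:
    """A clinical note with gold or predicted PII spans and optional task labels.

    ``label`` holds a document-level task label (e.g. a diagnosis group);
    ``token_tags`` holds per-token labels for token-level tasks, aligned with
    :func:`tokenize` applied to ``text``.
    """

    doc_id: str
    text: str
    spans: list[EntitySpan] = field(default_factory=list)
    label: str | None = None
    token_tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -1
        for sp in self.spans:
            if sp.end > len(self.text):
                raise ValidationError(
                    f"doc {self.doc_id!r}: span [{sp.start},{sp.end}) exceeds "
                    f"text length {len(self.text)}"
                )
            if sp.start < prev_end:
                raise ValidationError(
                    f"doc {self.doc_id!r}: span [{sp.start},{sp.end}) overlaps "
                    "or is out of order with a preceding span"
                )
            actual = self.text[sp.start : sp.end]
            if actual != sp.surface:
                raise ValidationError(
                    f"doc {self.doc_id!r}: span [{sp.start},{sp.end}) surface "
                    f"{sp.surface!r} != text substring {actual!r}"
                )
            prev_end = sp.end
        if self.token_tags is not None:
            n_tok = len(tokenize(self.text))
            if len(self.token_tags) != n_tok:
                raise ValidationError(
                    f"doc {self.doc_id!r}: {len(self.token_tags)} token tags "
                    f"for {n_tok} tokens"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedDocument):
            return NotImplemented
        return (
            self.doc_id == other.doc_id
            and self.text == other.text
            and self.spans == other.spans
            and self.label == other.label
            and self.token_tags == other.token_tags
        )


_PUNCT = set(string.punctuation) | {"«", "»", "–", "—", "…"}


def tokenize(text: str) -> list[tuple[int, int]]:
    """Token offsets: whitespace split, then leading/trailing punctuation
    separated into tokens of their own.

    Internal punctuation (hyphens in phone groups, slashes in dates) is kept,
    so ``08-123`` or ``12/05`` are single tokens while a trailing comma is not.
    Returns a list of (start, end) pairs into ``text``.
    """
    out: list[tuple[int, int]] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        a, b = i, j
        while a < b and text[a] in _PUNCT:
            out.append((a, a + 1))
            a += 1
        trailing: list[tuple[int, int]] = []
        while b > a and text[b - 1] in _PUNCT:
            trailing.append((b - 1, b))
            b -= 1
        if a < b:
            out.append((a, b))
        out.extend(reversed(trailing))
        i = j
    return out


@dataclass
class CorpusStats:
    """Per-class span counts plus token-level PII density for a corpus."""

    per_class_counts: dict[PiiClass, int]
    total_tokens: int
    pii_tokens: int

    @property
    def pii_density(self) -> float:
        if self.total_tokens == 0:
            return 0.0
        return self.pii_tokens / self.total_tokens

    def __add__(self, other: "CorpusStats") -> "CorpusStats":
        counts = {
            c: self.per_class_counts.get(c, 0) + other.per_class_counts.get(c, 0)
            for c in PiiClass
        }
        return CorpusStats(
            per_class_counts=counts,
            total_tokens=self.total_tokens + other.total_tokens,
            pii_tokens=self.pii_tokens + other.pii_tokens,
        )


def corpus_stats(docs: Iterable[AnnotatedDocument]) -> CorpusStats:
    """Count spans per class and measure token-level PII density.

    A token counts as PII if it shares at least one character with any span;
    density is (PII tokens) / (total tokens), 0 for an empty or span-free
    corpus.
    """
    counts = {c: 0 for c in PiiClass}
    total = 0
    covered = 0
    for doc in docs:
        toks = tokenize(doc.text)
        total += len(toks)
        for sp in doc.spans:
            counts[sp.pii_class] += 1
        if doc.spans:
            spans = doc.spans  # sorted, non-overlapping by invariant
            si = 0
            for ts, te in toks:
                while si < len(spans) and spans[si].end <= ts:
                    si += 1
                if si < len(spans) and spans[si].start < te:
                    covered += 1
    return CorpusStats(per_class_counts=counts, total_tokens=total, pii_tokens=covered)


@dataclass
class Gazetteer:
    """Surrogate-candidate lexica with the attributes the replacement rules need.

    first_names maps name -> gender tag ("F", "M", or "N" for neutral);
    streets/locations/countries are keyed by city/county/continent so that
    replacements can stay within the original's geographic stratum;
    postal_codes carry population weights (more populous codes are drawn more
    often); phone_area_codes are stored with their leading trunk zero.
    """

    first_names: dict[str, str] = field(default_factory=dict)
    surnames: list[str] = field(default_factory=list)
    streets: dict[str, list[str]] = field(default_factory=dict)
    locations: dict[str, list[str]] = field(default_factory=dict)
    countries: dict[str, list[str]] = field(default_factory=dict)
    care_units: list[str] = field(default_factory=list)
    postal_codes: dict[str, float] = field(default_factory=dict)
    phone_area_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, entries in [
            ("surnames", self.surnames),
            ("care_units", self.care_units),
            ("phone_area_codes", self.phone_area_codes),
        ]:
            if len(set(entries)) != len(entries):
                raise ValidationError(f"duplicate entries in gazetteer {label}")
        for label, mapping in [
            ("streets", self.streets),
            ("locations", self.locations),
            ("countries", self.countries),
        ]:
            for key, entries in mapping.items():
                if len(set(entries)) != len(entries):
                    raise ValidationError(
                        f"duplicate entries in gazetteer {label}[{key!r}]"
                    )

    # --- reverse lookups used by the replacement rules -------------------
    def gender_of(self, name: str) -> str | None:
        return self.first_names.get(name)

    def city_of(self, street: str) -> str | None:
        for city, streets in self.streets.items():
            if street in streets:
                return city
        return None

    def county_of(self, place: str) -> str | None:
        for county, places in self.locations.items():
            if place in places:
                return county
        return None

    def continent_of(self, country: str) -> str | None:
        for continent, countries in self.countries.items():
            if country in countries:
                return continent
        return None

    def all_locations(self) -> list[str]:
        out: list[str] = []
        for places in self.locations.values():
            out.extend(places)
        return out


def doc_rng(master_seed: int, doc_id: str) -> np.random.Generator:
    """Per-document random substream: stable under corpus reordering.

    The stream is keyed by (master_seed, crc32(doc_id)), so a document's
    surrogates do not depend on which other documents are processed.
    """
    return np.random.default_rng(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(doc_id.encode("utf-8"))]
    )
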