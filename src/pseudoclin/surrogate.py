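"""Surrogate selection and document rewriting.

Each of the nine PII classes has a replacement rule that preserves the
semantic stratum of the original while breaking the identifying link:

* first names keep their gender category (gendered-F, gendered-M, neutral),
  last names are drawn from the surname lexicon;
* streets stay within their city, places within their county, countries
  within their continent;
* health-care units are swapped within the known-clinic list;
* postal codes are redrawn weighted by population, so surrogates concentrate
  on common, populous codes;
* full and partial dates are shifted one to two weeks (|delta| uniform on a
  configurable day range, default 7-14, sign uniform, never zero);
* ages and years are moved by a small nonzero number of years (default 1-5),
  clamped to stay non-negative;
* phone numbers keep the original's grouping shape, draw a valid area code
  and randomize subscriber digits;
* organizations have no replacement lexicon and pass through unchanged by
  default (a documented limitation), or are masked on request.

All randomness flows from a single master seed through per-document
substreams keyed by doc_id, so a corpus pseudonymizes to byte-identical
output regardless of processing order.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

from .detect import Detector
from .schema import (
    AnnotatedDocument,
    EntitySpan,
    Gazetteer,
    PiiClass,
    ValidationError,
    corpus_stats,
    doc_rng,
    tokenize,
)

__all__ = [
    "SurrogatePolicy",
    "ReplacementRecord",
    "replace_name",
    "replace_location",
    "replace_care_unit",
    "replace_postal_code",
    "shift_date",
    "perturb_age",
    "replace_phone",
    "pseudonymize_document",
    "pseudonymize_corpus",
    "replacement_report",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """An empty or unusable surrogate resource."""


@dataclass(frozen=True)
class SurrogatePolicy:
    """Tunable knobs of the surrogate engine.

    ``date_shift_days`` and ``age_delta_years`` are inclusive magnitude
    ranges; zero magnitude is excluded so every shifted value moves.
    ``document_consistent_dates`` applies one shared day-shift per document,
    preserving intra-document intervals.  ``referential_name_consistency``
    gives repeated name surfaces within a document the same surrogate.
    """

    master_seed: int = 0
    date_shift_days: tuple[int, int] = (7, 14)
    age_delta_years: tuple[int, int] = (1, 5)
    document_consistent_dates: bool = False
    referential_name_consistency: bool = True
    organization_mode: str = "passthrough"  # or "mask"

    def __post_init__(self) -> None:
        for name, (lo, hi) in [
            ("date_shift_days", tuple(self.date_shift_days)),
            ("age_delta_years", tuple(self.age_delta_years)),
        ]:
            if not (1 <= lo <= hi):
                raise ValidationError(
                    f"{name} must satisfy 1 <= lo <= hi, got ({lo}, {hi})"
                )
        if self.organization_mode not in ("passthrough", "mask"):
            raise ValidationError(
                f"organization_mode must be 'passthrough' or 'mask', "
                f"got {self.organization_mode!r}"
            )


@dataclass
class ReplacementRecord:
    """One applied replacement: what was replaced, with what, by which rule."""

    doc_id: str
    pii_class: PiiClass
    original: str
    surrogate: str
    rule: str
    original_span: EntitySpan
    new_span: EntitySpan


def _signed_magnitude(rng: np.random.Generator, lo: int, hi: int) -> int:
    mag = int(rng.integers(lo, hi + 1))
    return mag if rng.random() < 0.5 else -mag


def _draw_excluding(
    rng: np.random.Generator, candidates: Sequence[str], original: str
) -> tuple[str, bool]:
    """Uniform draw from candidates excluding the original.

    Returns (value, had_alternative); falls back to the original when it is
    the only candidate.
    """
    pool = [c for c in candidates if c != original]
    if not pool:
        return original, False
    return pool[int(rng.integers(0, len(pool)))], True


# ------------------------------------------------------------------ names

def replace_name(
    surface: str,
    pii_class: PiiClass,
    gazetteer: Gazetteer,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Gender-preserving name replacement.

    A gendered first name is replaced with another name of the same gender
    category, a neutral name with a neutral name; first names missing from
    the lexicon fall back to the full first-name list.  Last names are drawn
    from the surname lexicon.  Returns (surrogate, rule id).
    """
    if pii_class is PiiClass.FIRST_NAME:
        if not gazetteer.first_names:
            raise ConfigurationError("gazetteer resource first_names is empty")
        gender = gazetteer.gender_of(surface)
        if gender is None:
            pool = list(gazetteer.first_names)
            rule = "first-name:unknown-gender-fallback"
        else:
            pool = [n for n, g in gazetteer.first_names.items() if g == gender]
            rule = f"first-name:gender-{gender}"
    elif pii_class is PiiClass.LAST_NAME:
        if not gazetteer.surnames:
            raise ConfigurationError("gazetteer resource surnames is empty")
        pool = list(gazetteer.surnames)
        rule = "last-name"
    else:
        raise ValueError(f"replace_name does not handle {pii_class}")
    surrogate, had_alt = _draw_excluding(rng, pool, surface)
    if not had_alt:
        rule += ":no-alternative"
    return surrogate, rule


# ------------------------------------------------------------------ places

def replace_location(
    surface: str, gazetteer: Gazetteer, rng: np.random.Generator
) -> tuple[str, str]:
    """Stratum-preserving geography: street stays in its city, place in its
    county, country in its continent; unknown surfaces fall back to a draw
    from the full location list (logged in the rule id)."""
    city = gazetteer.city_of(surface)
    if city is not None:
        surrogate, had_alt = _draw_excluding(rng, gazetteer.streets[city], surface)
        return surrogate, f"location:street-in-{city}" + (
            "" if had_alt else ":no-alternative"
        )
    county = gazetteer.county_of(surface)
    if county is not None:
        surrogate, had_alt = _draw_excluding(rng, gazetteer.locations[county], surface)
        return surrogate, f"location:county-{county}" + (
            "" if had_alt else ":no-alternative"
        )
    continent = gazetteer.continent_of(surface)
    if continent is not None:
        surrogate, had_alt = _draw_excluding(
            rng, gazetteer.countries[continent], surface
        )
        return surrogate, f"location:continent-{continent}" + (
            "" if had_alt else ":no-alternative"
        )
    pool = gazetteer.all_locations()
    if not pool:
        raise ConfigurationError("gazetteer resource locations is empty")
    surrogate, had_alt = _draw_excluding(rng, pool, surface)
    return surrogate, "location:fallback" + ("" if had_alt else ":no-alternative")


def replace_care_unit(
    surface: str, gazetteer: Gazetteer, rng: np.random.Generator
) -> tuple[str, str]:
    """Swap a health-care unit for another entry of the known-clinic list."""
    if not gazetteer.care_units:
        raise ConfigurationError("gazetteer resource care_units is empty")
    surrogate, had_alt = _draw_excluding(rng, gazetteer.care_units, surface)
    return surrogate, "care-unit" + ("" if had_alt else ":no-alternative")


_POSTAL_RE = re.compile(r"^(\d{3})( ?)(\d{2})$")


def replace_postal_code(
    surface: str, gazetteer: Gazetteer, rng: np.random.Generator
) -> tuple[str, str]:
    """Population-weighted postal-code replacement.

    Codes are drawn with probability proportional to population, so
    surrogates concentrate on common codes.  The original's "NNN NN" spacing
    (with or without the internal space) is preserved.
    """
    if not gazetteer.postal_codes:
        raise ConfigurationError("gazetteer resource postal_codes is empty")
    codes = list(gazetteer.postal_codes)
    weights = np.array([gazetteer.postal_codes[c] for c in codes], dtype=float)
    weights = weights / weights.sum()
    canonical = surface if " " in surface else f"{surface[:3]} {surface[3:]}"
    rule = "postal-code:population-weighted"
    pick = canonical
    for _ in range(64):
        pick = codes[int(rng.choice(len(codes), p=weights))]
        if pick != canonical or len(codes) == 1:
            break
    if pick == canonical:
        rule += ":no-alternative"
    return (pick if " " in surface else pick.replace(" ", "")), rule


# ------------------------------------------------------------------ dates

_DATE_DIALECTS = [
    # (regex, parse -> (date, renderer))
    ("iso_full", re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")),
    ("dmy_full", re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")),
    ("iso_year_month", re.compile(r"^(\d{4})-(\d{2})$")),
    ("dm_partial", re.compile(r"^(\d{1,2})/(\d{1,2})$")),
    ("bare_year", re.compile(r"^(\d{4})$")),
]


def _pad_like(value: int, template: str) -> str:
    # zero-pad only when the original component was zero-padded
    return str(value).zfill(2) if template.startswith("0") else str(value)


def shift_date(
    surface: str,
    pii_class: PiiClass,
    policy: SurrogatePolicy,
    rng: np.random.Generator,
    fixed_delta: int | None = None,
) -> tuple[str, str]:
    """Shift a date one to two weeks earlier or later.

    |delta| is uniform on ``policy.date_shift_days`` (default 7-14 days),
    sign uniform, delta never zero; ``fixed_delta`` overrides the draw (used
    for document-consistent shifting).  The output is re-rendered in the
    input's exact dialect and zero-padding style; calendar arithmetic is
    correct across month and year boundaries.  Partial dates shift only their
    known components: day/month partials move on a leap-year scaffold,
    year-month partials move as if anchored on a random day of the month (so
    the rendered month may legitimately stay the same; such cases carry an
    ``:unchanged`` rule flag), bare years are perturbed like ages.
    Unparseable surfaces pass through with a warning.
    """
    delta = (
        int(fixed_delta)
        if fixed_delta is not None
        else _signed_magnitude(rng, *policy.date_shift_days)
    )
    for dialect, pat in _DATE_DIALECTS:
        m = pat.match(surface.strip())
        if not m:
            continue
        try:
            if dialect == "iso_full":
                d = datetime.date(int(m[1]), int(m[2]), int(m[3]))
                d2 = d + datetime.timedelta(days=delta)
                return f"{d2.year:04d}-{d2.month:02d}-{d2.day:02d}", f"date:{dialect}"
            if dialect == "dmy_full":
                d = datetime.date(int(m[3]), int(m[2]), int(m[1]))
                d2 = d + datetime.timedelta(days=delta)
                return (
                    f"{_pad_like(d2.day, m[1])}/{_pad_like(d2.month, m[2])}/{d2.year:04d}",
                    f"date:{dialect}",
                )
            if dialect == "iso_year_month":
                # day unknown: anchor on a random day so a week-scale shift
                # can cross the month boundary; an unchanged rendering is
                # explicitly flagged
                anchor = int(rng.integers(1, 29))
                d = datetime.date(int(m[1]), int(m[2]), anchor) + datetime.timedelta(days=delta)
                out = f"{d.year:04d}-{d.month:02d}"
                rule = f"date:{dialect}"
                if out == surface.strip():
                    rule += ":unchanged"
                return out, rule
            if dialect == "dm_partial":
                d = datetime.date(2000, int(m[2]), int(m[1])) + datetime.timedelta(days=delta)
                return (
                    f"{_pad_like(d.day, m[1])}/{_pad_like(d.month, m[2])}",
                    f"date:{dialect}",
                )
            if dialect == "bare_year":
                return perturb_age(surface, policy, rng)[0], "date:bare-year-as-age"
        except ValueError:
            break
    logger.warning("unparseable %s surface %r passed through", pii_class.value, surface)
    return surface, "date:unparseable-passthrough"


# ------------------------------------------------------------------ ages

_INT_RE = re.compile(r"\d+")


def perturb_age(
    surface: str, policy: SurrogatePolicy, rng: np.random.Generator
) -> tuple[str, str]:
    """Move an age or year by a small nonzero number of years.

    |delta| uniform on ``policy.age_delta_years`` (default 1-5), sign
    uniform; negative results are redrawn so ages stay >= 0.  Non-digit
    context ("84 år") is preserved.  Non-numeric surfaces pass through with a
    warning.
    """
    m = _INT_RE.search(surface)
    if m is None:
        logger.warning("non-numeric age surface %r passed through", surface)
        return surface, "age:non-numeric-passthrough"
    value = int(m.group())
    for _ in range(64):
        delta = _signed_magnitude(rng, *policy.age_delta_years)
        if value + delta >= 0:
            break
    else:  # pragma: no cover - range (1,5) over value 0 always admits +delta
        delta = policy.age_delta_years[0]
    return surface[: m.start()] + str(value + delta) + surface[m.end() :], "age:delta"


# ------------------------------------------------------------------ phones

def replace_phone(
    surface: str, gazetteer: Gazetteer, rng: np.random.Generator
) -> tuple[str, str]:
    """Phone surrogate preserving the Swedish formatting of the original.

    Separators, digit grouping and total digit count are kept; the area code
    (the first digit group, after any +46 country prefix) is drawn from the
    area-code list among codes of matching length; the remaining subscriber
    digits are randomized.  The surrogate always differs from the original
    when any subscriber digit exists.
    """
    runs = list(_INT_RE.finditer(surface))
    if not runs:
        logger.warning("phone surface %r has no digits; passed through", surface)
        return surface, "phone:no-digits-passthrough"
    has_cc = surface.lstrip().startswith("+46") and runs[0].group().startswith("46")
    area_idx: int | None = None
    if has_cc:
        if runs[0].group() == "46" and len(runs) > 1:
            area_idx = 1
        # "+46701234567": single run, no separable area group
    else:
        area_idx = 0 if len(runs) > 1 else None

    for _ in range(64):
        parts: list[str] = []
        pos = 0
        for i, run in enumerate(runs):
            parts.append(surface[pos : run.start()])
            digits = run.group()
            if has_cc and i == 0 and digits == "46":
                parts.append(digits)
            elif i == area_idx:
                want = len(digits)
                candidates = [
                    c[1:] if has_cc else c
                    for c in gazetteer.phone_area_codes
                    if len(c[1:] if has_cc else c) == want
                ]
                if candidates:
                    parts.append(candidates[int(rng.integers(0, len(candidates)))])
                else:
                    parts.append(digits)
            else:
                parts.append("".join(str(rng.integers(0, 10)) for _ in digits))
            pos = run.end()
        parts.append(surface[pos:])
        surrogate = "".join(parts)
        if surrogate != surface:
            return surrogate, "phone:format-preserving"
    return surface, "phone:format-preserving:no-alternative"


# ------------------------------------------------------------------ engine

def _replace_one(
    span: EntitySpan,
    gazetteer: Gazetteer,
    policy: SurrogatePolicy,
    rng: np.random.Generator,
    doc_delta: int | None,
    name_cache: dict[tuple[PiiClass, str], str],
) -> tuple[str, str] | None:
    """Surrogate for one span, or None for an organization passthrough."""
    cls, surface = span.pii_class, span.surface
    if cls in (PiiClass.FIRST_NAME, PiiClass.LAST_NAME):
        key = (cls, surface)
        if policy.referential_name_consistency and key in name_cache:
            return name_cache[key], "name:referential-consistency"
        surrogate, rule = replace_name(surface, cls, gazetteer, rng)
        name_cache[key] = surrogate
        return surrogate, rule
    if cls is PiiClass.AGE:
        return perturb_age(surface, policy, rng)
    if cls in (PiiClass.FULL_DATE, PiiClass.PARTIAL_DATE):
        return shift_date(surface, cls, policy, rng, fixed_delta=doc_delta)
    if cls is PiiClass.PHONE_NUMBER:
        return replace_phone(surface, gazetteer, rng)
    if cls is PiiClass.HEALTH_CARE_UNIT:
        return replace_care_unit(surface, gazetteer, rng)
    if cls is PiiClass.LOCATION:
        if _POSTAL_RE.match(surface):
            return replace_postal_code(surface, gazetteer, rng)
        return replace_location(surface, gazetteer, rng)
    # Organization
    if policy.organization_mode == "mask":
        return "[ORGANIZATION]", "organization:mask"
    logger.warning(
        "organization %r passed through (no replacement lexicon)", surface
    )
    return None


def pseudonymize_document(
    doc: AnnotatedDocument,
    detector: Detector,
    gazetteer: Gazetteer,
    policy: SurrogatePolicy,
) -> tuple[AnnotatedDocument, list[ReplacementRecord]]:
    """Detect PII in one document and rewrite it with surrogates.

    Text outside detected spans is preserved verbatim; output spans are
    re-aligned to the surrogate positions.  Organizations follow
    ``policy.organization_mode`` (default passthrough, kept as spans in the
    output but not logged).  Deterministic under ``policy.master_seed`` via a
    per-document substream, independent of corpus order.
    """
    spans = sorted(detector.detect(doc.text), key=lambda s: s.start)
    rng = doc_rng(policy.master_seed, doc.doc_id)
    doc_delta = (
        _signed_magnitude(rng, *policy.date_shift_days)
        if policy.document_consistent_dates
        else None
    )
    name_cache: dict[tuple[PiiClass, str], str] = {}
    choices: list[tuple[EntitySpan, str, str] | tuple[EntitySpan, None, None]] = []
    for sp in spans:
        res = _replace_one(sp, gazetteer, policy, rng, doc_delta, name_cache)
        if res is None:
            choices.append((sp, None, None))
        else:
            choices.append((sp, res[0], res[1]))

    pieces: list[str] = []
    new_spans: list[EntitySpan] = []
    records: list[ReplacementRecord] = []
    cursor = 0
    out_len = 0
    for sp, surrogate, rule in choices:
        pieces.append(doc.text[cursor : sp.start])
        out_len += sp.start - cursor
        new_surface = sp.surface if surrogate is None else surrogate
        new_span = EntitySpan(out_len, out_len + len(new_surface), sp.pii_class, new_surface)
        new_spans.append(new_span)
        pieces.append(new_surface)
        out_len += len(new_surface)
        cursor = sp.end
        if surrogate is not None:
            records.append(
                ReplacementRecord(
                    doc_id=doc.doc_id,
                    pii_class=sp.pii_class,
                    original=sp.surface,
                    surrogate=surrogate,
                    rule=rule,
                    original_span=sp,
                    new_span=new_span,
                )
            )
    pieces.append(doc.text[cursor:])
    new_text = "".join(pieces)
    new_doc = AnnotatedDocument(
        doc_id=doc.doc_id,
        text=new_text,
        spans=new_spans,
        label=doc.label,
        token_tags=_realign_tags(doc, new_text),
    )
    return new_doc, records


def _realign_tags(doc: AnnotatedDocument, new_text: str) -> list[str] | None:
    """Carry per-token task tags over to the rewritten text.

    Tokens are mapped positionally; when replacement changes the token count,
    the new tail tokens inherit the last original tag (surrogates replace
    in-span material, whose task tags are uniform in the generated corpora).
    """
    if doc.token_tags is None:
        return None
    new_toks = tokenize(new_text)
    tags = doc.token_tags
    if not tags:
        return ["O"] * len(new_toks)
    if len(new_toks) <= len(tags):
        return list(tags[: len(new_toks)])
    return list(tags) + [tags[-1]] * (len(new_toks) - len(tags))


def pseudonymize_corpus(
    docs: Iterable[AnnotatedDocument],
    detector: Detector,
    gazetteer: Gazetteer,
    policy: SurrogatePolicy,
) -> tuple[list[AnnotatedDocument], list[ReplacementRecord]]:
    """Apply :func:`pseudonymize_document` over a corpus, pooling the logs."""
    out_docs: list[AnnotatedDocument] = []
    records: list[ReplacementRecord] = []
    for doc in docs:
        new_doc, recs = pseudonymize_document(doc, detector, gazetteer, policy)
        out_docs.append(new_doc)
        records.extend(recs)
    return out_docs, records


def replacement_report(
    records: Iterable[ReplacementRecord],
    corpus: Iterable[AnnotatedDocument],
):
    """Per-class replacement counts plus a total-word row for one corpus.

    The shape mirrors per-corpus "sensitive entities detected" tables: one
    row per PII class with the number of replaced entities, and a final
    "Total words" row counting corpus tokens.
    """
    import pandas as pd

    counts = {c.value: 0 for c in PiiClass}
    for rec in records:
        counts[rec.pii_class.value] += 1
    stats = corpus_stats(list(corpus))
    rows = [{"pii_class": k, "count": v} for k, v in counts.items()]
    rows.append({"pii_class": "Total words", "count": stats.total_tokens})
    return pd.DataFrame(rows)
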