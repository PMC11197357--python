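"""PII detection: a pluggable detector contract, a gazetteer+pattern reference
detector, a detector-degradation simulator, and per-class evaluation.

Production de-identifiers use neural named-entity recognition; this module
instead fixes the *interface* such taggers plug into and ships a transparent
rule-based reference detector (regular expressions for dates, ages, phone
numbers and postal codes; gazetteer lookup for names, locations and care
units).  The degradation simulator turns any detector into one with
controllable recall (random span misses) and precision (spurious spans over
text the detector left alone) — the two failure modes that matter for
downstream utility: missed spans leak PII, spurious spans corrupt
task-relevant words.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np

from .schema import (
    AnnotatedDocument,
    EntitySpan,
    Gazetteer,
    PiiClass,
    ValidationError,
    tokenize,
)

__all__ = [
    "Detector",
    "RuleDetector",
    "GoldDetector",
    "DegradedDetector",
    "ClassScore",
    "rule_detect",
    "degrade_detector",
    "evaluate_detector",
    "scores_to_frame",
]


class Detector(Protocol):
    """Behavioural contract: map document text to a list of entity spans."""

    def detect(self, text: str) -> list[EntitySpan]: ...


# ------------------------------------------------------------------ patterns

# Date/number patterns for Swedish-style clinical text.  Order does not
# matter: collisions are resolved longest-match-wins, left to right.
_DEFAULT_PATTERNS: list[tuple[str, PiiClass]] = [
    # full dates: ISO and day/month/year
    (r"\b\d{4}-\d{2}-\d{2}\b", PiiClass.FULL_DATE),
    (r"\b\d{1,2}/\d{1,2}/\d{4}\b", PiiClass.FULL_DATE),
    # partial dates: year-month, day/month
    (r"\b\d{4}-\d{2}(?!\d|-\d)\b", PiiClass.PARTIAL_DATE),
    (r"\b\d{1,2}/\d{1,2}(?!\d|/\d)\b", PiiClass.PARTIAL_DATE),
    # ages: "84 år", "84-årig"; years of birth "född 1943"
    (r"\b\d{1,3}\s?år(?:ig)?\b", PiiClass.AGE),
    (r"(?<=född )\d{4}\b", PiiClass.AGE),
    # phone numbers: "08-123 45 67", "070-123 45 67", "+46 70 123 45 67"
    (
        r"(?<![\d+])(?:\+46[ -]?)?\d{2,4}[- ]\d{2,3}(?: \d{2}){1,2}(?!\d)",
        PiiClass.PHONE_NUMBER,
    ),
    # Swedish postal codes, with or without the internal space -> Location
    (r"(?<!\d)\d{3} ?\d{2}(?!\d)", PiiClass.LOCATION),
    # organizations: "<Name> AB" corporate style
    (r"\b[A-ZÅÄÖ][a-zåäöé]+ AB\b", PiiClass.ORGANIZATION),
]

# deterministic tie-break order when candidates share start and length
_CLASS_PRIORITY = {c: i for i, c in enumerate(PiiClass)}


def _lexicon_regex(entries: Iterable[str]) -> re.Pattern | None:
    entries = [e for e in entries if e]
    if not entries:
        return None
    alts = "|".join(re.escape(e) for e in sorted(entries, key=len, reverse=True))
    # \b is unreliable next to non-ASCII word chars in some dialects; use
    # explicit non-word lookarounds including Swedish letters.
    w = r"0-9A-Za-zÀ-ÖØ-öø-ÿ"
    return re.compile(rf"(?<![{w}])(?:{alts})(?![{w}])")


class RuleDetector:
    """Reference detector: regex patterns plus gazetteer term lookup.

    Deterministic given its configuration; unrecognized text yields no spans.
    """

    def __init__(
        self,
        gazetteer: Gazetteer,
        patterns: Sequence[tuple[str, PiiClass]] | None = None,
    ):
        self.gazetteer = gazetteer
        raw = list(patterns) if patterns is not None else list(_DEFAULT_PATTERNS)
        self._patterns = [(re.compile(p), c) for p, c in raw]
        gz = gazetteer
        self._lexica: list[tuple[re.Pattern | None, PiiClass]] = [
            (_lexicon_regex(gz.first_names), PiiClass.FIRST_NAME),
            (_lexicon_regex(gz.surnames), PiiClass.LAST_NAME),
            (_lexicon_regex(gz.care_units), PiiClass.HEALTH_CARE_UNIT),
            (
                _lexicon_regex(
                    gz.all_locations()
                    + [s for ss in gz.streets.values() for s in ss]
                    + [c for cs in gz.countries.values() for c in cs]
                ),
                PiiClass.LOCATION,
            ),
        ]

    def detect(self, text: str) -> list[EntitySpan]:
        candidates: list[tuple[int, int, PiiClass]] = []
        for pat, cls in self._patterns:
            for m in pat.finditer(text):
                candidates.append((m.start(), m.end(), cls))
        for pat, cls in self._lexica:
            if pat is None:
                continue
            for m in pat.finditer(text):
                candidates.append((m.start(), m.end(), cls))
        return _resolve(candidates, text)


def _resolve(
    candidates: list[tuple[int, int, PiiClass]], text: str
) -> list[EntitySpan]:
    """Longest-match-wins overlap resolution, scanning left to right."""
    candidates.sort(key=lambda t: (t[0], t[0] - t[1], _CLASS_PRIORITY[t[2]]))
    out: list[EntitySpan] = []
    cur_end = -1
    for start, end, cls in candidates:
        if start < cur_end:
            continue
        out.append(EntitySpan(start, end, cls, text[start:end]))
        cur_end = end
    return out


def rule_detect(
    text: str,
    gazetteer: Gazetteer,
    patterns: Sequence[tuple[str, PiiClass]] | None = None,
) -> list[EntitySpan]:
    """One-shot convenience wrapper around :class:`RuleDetector`."""
    return RuleDetector(gazetteer, patterns).detect(text)


class GoldDetector:
    """Oracle detector that replays the gold spans of a known corpus.

    Stands in for a perfect de-identifier when studying the surrogate rules
    in isolation from detection errors.
    """

    def __init__(self, docs: Iterable[AnnotatedDocument]):
        self._by_text: dict[str, list[EntitySpan]] = {}
        for doc in docs:
            self._by_text[doc.text] = list(doc.spans)

    def detect(self, text: str) -> list[EntitySpan]:
        return list(self._by_text.get(text, []))


# ------------------------------------------------------------------ degrade

class DegradedDetector:
    """Wrap a detector with controlled recall and precision loss.

    Each base span is dropped independently with probability ``miss_rate``;
    spurious single- or two-token spans of uniformly random class are injected
    over token stretches *not* covered by the retained spans, at an expected
    ``spurious_rate`` spans per 100 tokens.  Deterministic per text: the
    random substream is keyed by (seed, crc32(text)), so detection does not
    depend on call order.
    """

    def __init__(self, base: Detector, miss_rate: float, spurious_rate: float, seed: int):
        if not (0.0 <= miss_rate <= 1.0):
            raise ValidationError(f"miss_rate must be in [0,1], got {miss_rate}")
        if spurious_rate < 0.0:
            raise ValidationError(f"spurious_rate must be >= 0, got {spurious_rate}")
        self.base = base
        self.miss_rate = miss_rate
        self.spurious_rate = spurious_rate
        self.seed = int(seed)

    def detect(self, text: str) -> list[EntitySpan]:
        rng = np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(text.encode("utf-8"))]
        )
        base_spans = self.base.detect(text)
        kept = [sp for sp in base_spans if rng.random() >= self.miss_rate]
        if self.spurious_rate > 0:
            toks = tokenize(text)
            covered = np.zeros(len(toks), dtype=bool)
            ki = 0
            for i, (ts, te) in enumerate(toks):
                for sp in kept[ki:]:
                    if sp.end <= ts:
                        ki += 1
                        continue
                    if sp.start < te:
                        covered[i] = True
                    break
            classes = list(PiiClass)
            p = self.spurious_rate / 100.0
            hits = rng.random(len(toks)) < p
            lengths = rng.integers(1, 3, size=len(toks))
            cls_idx = rng.integers(0, len(classes), size=len(toks))
            spurious: list[EntitySpan] = []
            taken = covered.copy()
            for i in range(len(toks)):
                if not hits[i] or taken[i]:
                    continue
                j = i
                if lengths[i] == 2 and i + 1 < len(toks) and not taken[i + 1]:
                    j = i + 1
                start, end = toks[i][0], toks[j][1]
                spurious.append(
                    EntitySpan(start, end, classes[cls_idx[i]], text[start:end])
                )
                taken[i : j + 1] = True
            kept = sorted(kept + spurious, key=lambda sp: sp.start)
        return kept


def degrade_detector(
    base: Detector, miss_rate: float, spurious_rate: float, seed: int
) -> DegradedDetector:
    """Simulate an imperfect de-identifier (see :class:`DegradedDetector`)."""
    return DegradedDetector(base, miss_rate, spurious_rate, seed)


# ------------------------------------------------------------------ evaluate

@dataclass
class ClassScore:
    """Per-class detection score in the precision/recall percentage format."""

    pii_class: PiiClass
    true_positives: int
    false_positives: int
    false_negatives: int
    precision_defined: bool = True
    recall_defined: bool = True

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return 100.0 * self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return 100.0 * self.true_positives / denom if denom else 0.0


def _match_doc(
    pred: Sequence[EntitySpan],
    gold: Sequence[EntitySpan],
    matching: str,
    tp: dict[PiiClass, int],
    fp: dict[PiiClass, int],
    fn: dict[PiiClass, int],
) -> None:
    if matching == "strict":
        gold_keys: dict[tuple[int, int, PiiClass], int] = {}
        for sp in gold:
            gold_keys[(sp.start, sp.end, sp.pii_class)] = (
                gold_keys.get((sp.start, sp.end, sp.pii_class), 0) + 1
            )
        for sp in pred:
            key = (sp.start, sp.end, sp.pii_class)
            if gold_keys.get(key, 0) > 0:
                gold_keys[key] -= 1
                tp[sp.pii_class] += 1
            else:
                fp[sp.pii_class] += 1
        for (_, _, cls), left in gold_keys.items():
            fn[cls] += left
    else:  # overlap: same class, >=1 shared character, one-to-one greedy
        unmatched = list(gold)
        for sp in sorted(pred, key=lambda s: s.start):
            hit = None
            for g in unmatched:
                if g.pii_class is sp.pii_class and sp.overlaps(g):
                    hit = g
                    break
            if hit is not None:
                unmatched.remove(hit)
                tp[sp.pii_class] += 1
            else:
                fp[sp.pii_class] += 1
        for g in unmatched:
            fn[g.pii_class] += 1


def evaluate_detector(
    predicted: Mapping[str, Sequence[EntitySpan]],
    gold: Mapping[str, Sequence[EntitySpan]],
    matching: str = "strict",
) -> list[ClassScore]:
    """Per-class precision/recall of predicted spans against gold spans.

    ``strict`` requires identical (start, end, class); ``overlap`` requires
    the same class and at least one shared character (greedy one-to-one
    pairing).  Scores with an empty denominator are reported as 0 with the
    corresponding ``*_defined`` flag cleared, so tables never hold undefined
    cells.
    """
    if matching not in ("strict", "overlap"):
        raise ValueError(f"matching must be 'strict' or 'overlap', got {matching!r}")
    if set(predicted) != set(gold):
        missing = set(predicted) ^ set(gold)
        raise ValidationError(f"doc_id mismatch between predicted and gold: {sorted(missing)[:5]}")
    tp = {c: 0 for c in PiiClass}
    fp = {c: 0 for c in PiiClass}
    fn = {c: 0 for c in PiiClass}
    for doc_id in gold:
        _match_doc(predicted[doc_id], gold[doc_id], matching, tp, fp, fn)
    return [
        ClassScore(
            pii_class=c,
            true_positives=tp[c],
            false_positives=fp[c],
            false_negatives=fn[c],
            precision_defined=(tp[c] + fp[c]) > 0,
            recall_defined=(tp[c] + fn[c]) > 0,
        )
        for c in PiiClass
    ]


def scores_to_frame(scores: Sequence[ClassScore]):
    """Scores as a table with class / recall % / precision % columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pii_class": [s.pii_class.value for s in scores],
            "recall_pct": [round(s.recall, 2) for s in scores],
            "precision_pct": [round(s.precision, 2) for s in scores],
            "tp": [s.true_positives for s in scores],
            "fp": [s.false_positives for s in scores],
            "fn": [s.false_negatives for s in scores],
        }
    )
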