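"""Corpus and gazetteer I/O in plain-text standard formats.

Four corpus dialects are supported:

* ``standoff`` — brat-style directory of ``<doc_id>.txt`` + ``<doc_id>.ann``
  pairs; annotation lines ``T<n>\\t<Class> <start> <end>\\t<surface>``.
* ``bio_tsv`` — CoNLL-style single file, one ``token\\tTAG`` per line with
  ``B-/I-<Class>`` and ``O`` tags, blank line between documents; ``doc_id``
  and an optional document label ride in ``# doc_id = ...`` / ``# label = ...``
  comment lines.  Text is reconstructed by single-space joining tokens, so
  round-trip identity holds for corpora whose text already is single-space
  separated tokens (as emitted by the synthetic generator).
* ``jsonl`` — one JSON object per line: doc_id, text, spans, label,
  token_tags.
* ``plain`` — directory of bare ``.txt`` files, no annotations.

All files are UTF-8.  Unknown entity labels raise instead of being dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .schema import (
    AnnotatedDocument,
    EntitySpan,
    Gazetteer,
    PiiClass,
    ValidationError,
    tokenize,
)

__all__ = ["read_corpus", "write_corpus", "read_gazetteer", "write_gazetteer"]

_FORMATS = ("standoff", "bio_tsv", "jsonl", "plain")


def _parse_class(label: str, where: str) -> PiiClass:
    try:
        return PiiClass(label)
    except ValueError:
        raise ValidationError(f"{where}: unknown entity label {label!r}") from None


# ---------------------------------------------------------------- standoff

def _read_standoff(path: Path) -> list[AnnotatedDocument]:
    docs = []
    for txt_path in sorted(path.glob("*.txt")):
        doc_id = txt_path.stem
        text = txt_path.read_text(encoding="utf-8")
        ann_path = txt_path.with_suffix(".ann")
        spans = []
        if ann_path.exists():
            for line in ann_path.read_text(encoding="utf-8").splitlines():
                if not line.strip() or not line.startswith("T"):
                    continue
                try:
                    _tid, mid, surface = line.split("\t", 2)
                    label, start_s, end_s = mid.split(" ")
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise ValidationError(
                        f"doc {doc_id!r}: malformed standoff line {line!r}"
                    ) from None
                spans.append(
                    EntitySpan(start, end, _parse_class(label, f"doc {doc_id!r}"), surface)
                )
        spans.sort(key=lambda s: s.start)
        docs.append(AnnotatedDocument(doc_id=doc_id, text=text, spans=spans))
    return docs


def _write_standoff(docs: Sequence[AnnotatedDocument], path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        lines = [
            f"T{i + 1}\t{sp.pii_class.value} {sp.start} {sp.end}\t{sp.surface}"
            for i, sp in enumerate(doc.spans)
        ]
        (path / f"{doc.doc_id}.ann").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )


# ---------------------------------------------------------------- bio_tsv

def doc_to_bio(doc: AnnotatedDocument) -> list[tuple[str, str]]:
    """(token, BIO tag) pairs for one document.

    Spans must align with token boundaries; a span that starts or ends inside
    a token raises.
    """
    toks = tokenize(doc.text)
    pairs: list[tuple[str, str]] = []
    si = 0
    prev_in_span = False
    for ts, te in toks:
        while si < len(doc.spans) and doc.spans[si].end <= ts:
            si += 1
            prev_in_span = False
        tag = "O"
        if si < len(doc.spans):
            sp = doc.spans[si]
            if sp.start < te and ts < sp.end:
                if ts < sp.start or te > sp.end:
                    raise ValidationError(
                        f"doc {doc.doc_id!r}: span [{sp.start},{sp.end}) not "
                        "token-aligned; cannot be written as BIO"
                    )
                tag = ("I-" if prev_in_span else "B-") + sp.pii_class.value
                prev_in_span = True
            else:
                prev_in_span = False
        pairs.append((doc.text[ts:te], tag))
    return pairs


def bio_to_doc(
    doc_id: str, pairs: Sequence[tuple[str, str]], label: str | None = None
) -> AnnotatedDocument:
    """Rebuild a document from (token, tag) pairs; tokens joined by one space."""
    text_parts: list[str] = []
    offsets: list[tuple[int, int]] = []
    pos = 0
    for i, (tok, _tag) in enumerate(pairs):
        if i:
            pos += 1
        text_parts.append(tok)
        offsets.append((pos, pos + len(tok)))
        pos += len(tok)
    text = " ".join(text_parts)
    spans: list[EntitySpan] = []
    cur_start = cur_end = -1
    cur_class: PiiClass | None = None

    def flush() -> None:
        nonlocal cur_class
        if cur_class is not None:
            spans.append(
                EntitySpan(cur_start, cur_end, cur_class, text[cur_start:cur_end])
            )
        cur_class = None

    for (tok, tag), (ts, te) in zip(pairs, offsets):
        if tag == "O":
            flush()
            continue
        if len(tag) < 3 or tag[0] not in "BI" or tag[1] != "-":
            raise ValidationError(f"doc {doc_id!r}: malformed BIO tag {tag!r}")
        cls = _parse_class(tag[2:], f"doc {doc_id!r}")
        if tag[0] == "B" or cls is not cur_class:
            flush()
            cur_start, cur_end, cur_class = ts, te, cls
        else:
            cur_end = te
    flush()
    return AnnotatedDocument(doc_id=doc_id, text=text, spans=spans, label=label)


def _read_bio_tsv(path: Path) -> list[AnnotatedDocument]:
    docs: list[AnnotatedDocument] = []
    pairs: list[tuple[str, str]] = []
    doc_id: str | None = None
    label: str | None = None
    idx = 0

    def flush() -> None:
        nonlocal pairs, doc_id, label, idx
        if pairs or doc_id is not None:
            docs.append(bio_to_doc(doc_id if doc_id is not None else f"doc{idx:04d}", pairs, label))
            idx += 1
        pairs, doc_id, label = [], None, None

    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            flush()
            continue
        if line.startswith("# doc_id ="):
            doc_id = line.split("=", 1)[1].strip()
            continue
        if line.startswith("# label ="):
            label = line.split("=", 1)[1].strip()
            continue
        try:
            tok, tag = line.split("\t")
        except ValueError:
            raise ValidationError(f"malformed BIO line {line!r}") from None
        pairs.append((tok, tag))
    flush()
    return docs


def _write_bio_tsv(docs: Sequence[AnnotatedDocument], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    blocks = []
    for doc in docs:
        lines = [f"# doc_id = {doc.doc_id}"]
        if doc.label is not None:
            lines.append(f"# label = {doc.label}")
        lines.extend(f"{tok}\t{tag}" for tok, tag in doc_to_bio(doc))
        blocks.append("\n".join(lines))
    path.write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


# ---------------------------------------------------------------- jsonl

def _doc_to_json(doc: AnnotatedDocument) -> dict:
    obj: dict = {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "spans": [
            {"start": sp.start, "end": sp.end, "class": sp.pii_class.value}
            for sp in doc.spans
        ],
    }
    if doc.label is not None:
        obj["label"] = doc.label
    if doc.token_tags is not None:
        obj["token_tags"] = doc.token_tags
    return obj


def _doc_from_json(obj: dict) -> AnnotatedDocument:
    doc_id = obj["doc_id"]
    text = obj["text"]
    spans = []
    for s in obj.get("spans", []):
        start, end = int(s["start"]), int(s["end"])
        if end > len(text):
            raise ValidationError(
                f"doc {doc_id!r}: span [{start},{end}) exceeds text length"
            )
        spans.append(
            EntitySpan(start, end, _parse_class(s["class"], f"doc {doc_id!r}"), text[start:end])
        )
    spans.sort(key=lambda sp: sp.start)
    return AnnotatedDocument(
        doc_id=doc_id,
        text=text,
        spans=spans,
        label=obj.get("label"),
        token_tags=obj.get("token_tags"),
    )


def _read_jsonl(path: Path) -> list[AnnotatedDocument]:
    docs = []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError:
            raise ValidationError(f"{path}:{i + 1}: malformed JSON") from None
        docs.append(_doc_from_json(obj))
    return docs


def _write_jsonl(docs: Sequence[AnnotatedDocument], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(_doc_to_json(doc), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------- plain

def _read_plain(path: Path) -> list[AnnotatedDocument]:
    return [
        AnnotatedDocument(doc_id=p.stem, text=p.read_text(encoding="utf-8"))
        for p in sorted(path.glob("*.txt"))
    ]


def _write_plain(docs: Sequence[AnnotatedDocument], path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")


# ---------------------------------------------------------------- dispatch

def read_corpus(path: str | Path, format: str) -> list[AnnotatedDocument]:
    """Read a corpus in one of the four supported dialects.

    ``path`` is a directory for ``standoff``/``plain`` and a file for
    ``bio_tsv``/``jsonl``.  Malformed offsets or unknown entity labels raise
    :class:`ValidationError` naming the document.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown corpus format {format!r}; choose from {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    return {
        "standoff": _read_standoff,
        "bio_tsv": _read_bio_tsv,
        "jsonl": _read_jsonl,
        "plain": _read_plain,
    }[format](path)


def write_corpus(
    docs: Iterable[AnnotatedDocument], path: str | Path, format: str
) -> None:
    """Write a corpus; ``read_corpus(write_corpus(docs))`` reproduces docs.

    For ``plain``, spans and labels are dropped by design; for ``bio_tsv``,
    exact text round-trip additionally requires single-space token separation.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown corpus format {format!r}; choose from {_FORMATS}")
    docs = list(docs)
    {
        "standoff": _write_standoff,
        "bio_tsv": _write_bio_tsv,
        "jsonl": _write_jsonl,
        "plain": _write_plain,
    }[format](docs, path)


# ---------------------------------------------------------------- gazetteer

_GZ_FILES = {
    "first_names": "first_names.tsv",
    "surnames": "surnames.tsv",
    "streets": "streets.tsv",
    "locations": "locations.tsv",
    "countries": "countries.tsv",
    "care_units": "care_units.tsv",
    "postal_codes": "postal_codes.tsv",
    "phone_area_codes": "phone_area_codes.tsv",
}


def write_gazetteer(gz: Gazetteer, path: str | Path) -> None:
    """Write gazetteer resources as UTF-8 TSVs, one entry per line."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def dump(name: str, rows: Iterable[Iterable[str]]) -> None:
        lines = ["\t".join(str(c) for c in row) for row in rows]
        (path / _GZ_FILES[name]).write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )

    dump("first_names", sorted(gz.first_names.items()))
    dump("surnames", [[s] for s in sorted(gz.surnames)])
    dump(
        "streets",
        sorted((s, city) for city, streets in gz.streets.items() for s in streets),
    )
    dump(
        "locations",
        sorted((p, county) for county, places in gz.locations.items() for p in places),
    )
    dump(
        "countries",
        sorted((c, cont) for cont, cs in gz.countries.items() for c in cs),
    )
    dump("care_units", [[u] for u in sorted(gz.care_units)])
    dump("postal_codes", [(c, repr(w)) for c, w in sorted(gz.postal_codes.items())])
    dump("phone_area_codes", [[a] for a in sorted(gz.phone_area_codes)])


def read_gazetteer(path: str | Path) -> Gazetteer:
    path = Path(path)

    def rows(name: str) -> list[list[str]]:
        p = path / _GZ_FILES[name]
        if not p.exists():
            return []
        return [
            line.split("\t")
            for line in p.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]

    def keyed(name: str) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for entry, key in rows(name):
            out.setdefault(key, []).append(entry)
        return out

    return Gazetteer(
        first_names={name: g for name, g in rows("first_names")},
        surnames=[r[0] for r in rows("surnames")],
        streets=keyed("streets"),
        locations=keyed("locations"),
        countries=keyed("countries"),
        care_units=[r[0] for r in rows("care_units")],
        postal_codes={c: float(w) for c, w in rows("postal_codes")},
        phone_area_codes=[r[0] for r in rows("phone_area_codes")],
    )
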