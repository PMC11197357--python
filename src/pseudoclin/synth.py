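"""Synthetic gazetteers, annotated clinical notes, and downstream-task corpora.

Real clinical corpora cannot be shared, so every experiment in this package
runs on synthetic material whose statistical structure is controlled by
construction: Swedish-flavoured slot-filling notes with gold PII spans at a
target token-level density (default 1.57%, the ballpark prevalence of PII in
clinical free text, which ranges roughly 0.97-2.19% across note types), and
labeled task corpora whose label signal provably lives either in non-PII
tokens or exclusively inside PII spans.  Realism is explicitly not the goal;
knowing exactly where the signal is lets utility experiments attribute any
performance change to the pseudonymization step itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import write_gazetteer
from .schema import AnnotatedDocument, EntitySpan, Gazetteer, PiiClass, ValidationError

__all__ = [
    "NoteGeneratorConfig",
    "TaskGeneratorConfig",
    "generate_gazetteer",
    "generate_notes",
    "generate_task_corpus",
    "SIGNAL_PREFIX",
]

# ------------------------------------------------------------------ gazetteer

_NAME_ONSETS = ["An", "Er", "Kar", "Lis", "Mal", "Os", "Pel", "Sig", "Tor", "Ulr",
                "Val", "Ing", "Gun", "Hen", "Jo", "Kers", "Len", "Mag", "Nil", "Ro"]
_NAME_CODAS_F = ["a", "ina", "ella", "ilda", "in", "ida", "ott", "ekka"]
_NAME_CODAS_M = ["ar", "ik", "on", "us", "ert", "olf", "vald", "mund"]
_NAME_CODAS_N = ["i", "y", "ou", "is"]
_SURNAME_ROOTS = ["Berg", "Lind", "Strand", "Holm", "Dal", "Sand", "Sjö", "Ek",
                  "Gran", "Ny", "Ås", "Björk", "Alm", "Hag", "Kull", "Sten"]
_SURNAME_SUFFIXES = ["ström", "gren", "qvist", "berg", "lund", "man", "dahl", "stedt"]
_PLACE_ROOTS = ["Björk", "Gran", "Sten", "Dal", "Fors", "Hult", "Mo", "Ryd",
                "Sund", "Tors", "Ulv", "Vik", "Ängs", "Öst", "Norr", "Söder"]
_PLACE_SUFFIXES = ["by", "hamn", "köping", "stad", "vik", "näs", "berga", "sele"]
_STREET_SUFFIXES = ["gatan", "vägen", "gränd", "stigen"]
_UNIT_ROOTS = ["Akut", "Kirurg", "Medicin", "Ortoped", "Geriatrik", "Infektion",
               "Onkolog", "Kardiolog", "Neurolog", "Rehab"]
_UNIT_SUFFIXES = ["mottagningen", "kliniken", "avdelningen"]
_COUNTRY_SUFFIXES = ["ien", "land", "istan", "ia"]

_DEFAULT_SIZES = {
    "first_names": 120,
    "surnames": 80,
    "streets": 40,
    "locations": 40,
    "countries": 25,
    "care_units": 24,
    "postal_codes": 30,
    "phone_area_codes": 6,
}

_CITIES = ["Storstaden", "Åkersta", "Nyfors", "Västerhamn"]
_COUNTIES = ["Norrland", "Västland", "Östland", "Sydland", "Mälardal"]
_CONTINENTS = ["Europa", "Asien", "Afrika", "Amerika", "Oceanien"]
_AREA_CODES = ["08", "070", "073", "031", "040", "090", "046", "054"]


def _unique_names(
    rng: np.random.Generator, n: int, builder, taken: set[str]
) -> list[str]:
    out: list[str] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100 * n + 1000:
            raise ValidationError(f"cannot generate {n} unique entries")
        name = builder(rng)
        if name not in taken:
            taken.add(name)
            out.append(name)
    return out


def generate_gazetteer(
    seed: int,
    sizes: dict[str, int] | None = None,
    out_dir: str | Path | None = None,
) -> Gazetteer:
    """Seeded synthetic gazetteer with every attribute the rules consume.

    ``sizes`` overrides per-resource entry counts (each must be >= 2).  Names
    carry gender tags (~45% F, ~45% M, ~10% neutral), places are partitioned
    over counties, countries over continents, streets over cities, and postal
    codes get heavy-tailed population weights.  With ``out_dir`` set the
    resources are also written as TSVs; identical seed and sizes yield
    byte-identical files.
    """
    cfg = dict(_DEFAULT_SIZES)
    if sizes:
        unknown = set(sizes) - set(cfg)
        if unknown:
            raise ValidationError(f"unknown gazetteer resources: {sorted(unknown)}")
        cfg.update(sizes)
    for k, v in cfg.items():
        if v < 2:
            raise ValidationError(f"gazetteer size for {k} must be >= 2, got {v}")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()

    def first_name(rng: np.random.Generator) -> str:
        onset = _NAME_ONSETS[int(rng.integers(len(_NAME_ONSETS)))]
        u = rng.random()
        codas = _NAME_CODAS_F if u < 0.45 else _NAME_CODAS_M if u < 0.9 else _NAME_CODAS_N
        return onset + codas[int(rng.integers(len(codas)))]

    firsts = {}
    for name in _unique_names(rng, cfg["first_names"], first_name, taken):
        if any(name.endswith(c) for c in _NAME_CODAS_N if len(c) <= 2) and not any(
            name.endswith(c) for c in _NAME_CODAS_M + _NAME_CODAS_F if len(c) > 2
        ):
            firsts[name] = "N"
        elif any(name.endswith(c) for c in _NAME_CODAS_M):
            firsts[name] = "M"
        else:
            firsts[name] = "F"

    def surname(rng: np.random.Generator) -> str:
        return (
            _SURNAME_ROOTS[int(rng.integers(len(_SURNAME_ROOTS)))]
            + _SURNAME_SUFFIXES[int(rng.integers(len(_SURNAME_SUFFIXES)))]
        )

    surnames = _unique_names(rng, cfg["surnames"], surname, taken)

    def place(rng: np.random.Generator) -> str:
        return (
            _PLACE_ROOTS[int(rng.integers(len(_PLACE_ROOTS)))]
            + _PLACE_SUFFIXES[int(rng.integers(len(_PLACE_SUFFIXES)))]
        )

    def street(rng: np.random.Generator) -> str:
        return (
            _PLACE_ROOTS[int(rng.integers(len(_PLACE_ROOTS)))]
            + _STREET_SUFFIXES[int(rng.integers(len(_STREET_SUFFIXES)))]
        )

    def country(rng: np.random.Generator) -> str:
        return (
            _PLACE_ROOTS[int(rng.integers(len(_PLACE_ROOTS)))].rstrip("s")
            + _COUNTRY_SUFFIXES[int(rng.integers(len(_COUNTRY_SUFFIXES)))]
        )

    def unit(rng: np.random.Generator) -> str:
        return (
            _UNIT_ROOTS[int(rng.integers(len(_UNIT_ROOTS)))]
            + _UNIT_SUFFIXES[int(rng.integers(len(_UNIT_SUFFIXES)))]
        )

    def partition(entries: list[str], keys: list[str]) -> dict[str, list[str]]:
        # round-robin so every key gets >= 2 entries when len >= 2*len(keys)
        out: dict[str, list[str]] = {k: [] for k in keys}
        for i, e in enumerate(entries):
            out[keys[i % len(keys)]].append(e)
        return {k: v for k, v in out.items() if v}

    n_cities = min(len(_CITIES), max(1, cfg["streets"] // 2))
    n_counties = min(len(_COUNTIES), max(1, cfg["locations"] // 2))
    n_continents = min(len(_CONTINENTS), max(1, cfg["countries"] // 2))
    streets = partition(
        _unique_names(rng, cfg["streets"], street, taken), _CITIES[:n_cities]
    )
    locations = partition(
        _unique_names(rng, cfg["locations"], place, taken), _COUNTIES[:n_counties]
    )
    countries = partition(
        _unique_names(rng, cfg["countries"], country, taken), _CONTINENTS[:n_continents]
    )
    care_units = _unique_names(rng, cfg["care_units"], unit, taken)

    codes: list[str] = []
    seen_codes: set[str] = set()
    while len(codes) < cfg["postal_codes"]:
        code = f"{rng.integers(100, 1000)} {rng.integers(10, 100)}"
        if code not in seen_codes:
            seen_codes.add(code)
            codes.append(code)
    weights = rng.pareto(1.2, size=len(codes)) + 0.1
    postal_codes = {c: round(float(w), 6) for c, w in zip(codes, weights)}

    gz = Gazetteer(
        first_names=firsts,
        surnames=surnames,
        streets=streets,
        locations=locations,
        countries=countries,
        care_units=care_units,
        postal_codes=postal_codes,
        phone_area_codes=_AREA_CODES[: cfg["phone_area_codes"]],
    )
    if out_dir is not None:
        write_gazetteer(gz, out_dir)
    return gz


# ------------------------------------------------------------------ notes

_FILLER_VOCAB = [
    "patienten", "inkom", "med", "besvär", "från", "buken", "sedan", "två",
    "dagar", "tillbaka", "status", "gott", "opåverkad", "vid", "undersökning",
    "palpation", "ömhet", "utan", "tecken", "till", "peritonit", "bedömning",
    "misstänkt", "gastroenterit", "planeras", "uppföljning", "via", "ordination",
    "enligt", "lista", "fortsatt", "behandling", "smärtlindring", "vätska",
    "per", "os", "anamnes", "tidigare", "frisk", "söker", "för", "huvudvärk",
    "yrsel", "illamående", "kräkningar", "feber", "hosta", "andfåddhet",
    "bröstsmärta", "ingen", "dyspné", "normala", "vitalparametrar", "puls",
    "regelbunden", "blodtryck", "stabilt", "saturation", "luft", "auskultation",
    "rena", "andningsljud", "bilateralt", "hjärttoner", "biljud", "neurologi",
    "grovt", "intakt", "åtgärd", "remiss", "skickas", "provtagning", "visar",
    "lätt", "förhöjda", "värden", "kontroll", "om", "veckor", "återbesök",
]

_DEFAULT_CLASS_MIX = {
    PiiClass.AGE: 0.22,
    PiiClass.FIRST_NAME: 0.14,
    PiiClass.LAST_NAME: 0.17,
    PiiClass.PARTIAL_DATE: 0.12,
    PiiClass.FULL_DATE: 0.10,
    PiiClass.PHONE_NUMBER: 0.02,
    PiiClass.HEALTH_CARE_UNIT: 0.18,
    PiiClass.LOCATION: 0.045,
    PiiClass.ORGANIZATION: 0.005,
}

_ORG_ROOTS = ["Vårdbolaget", "Omsorgsgruppen", "Hälsopartner", "Klinikbolaget"]


@dataclass
class NoteGeneratorConfig:
    """Controls for the synthetic-note generator.

    ``target_density`` is the token-level PII density (fraction of tokens
    covered by PII spans); the default 0.0157 matches the overall prevalence
    typical of clinical notes.  ``class_mix`` must sum to 1.
    """

    n_docs: int = 200
    target_density: float = 0.0157
    class_mix: dict[PiiClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX)
    )
    seed: int = 0
    template_set: str = "minimal-v1"
    tokens_per_doc: tuple[int, int] = (60, 120)

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_density <= 0.2):
            raise ValidationError(
                f"target_density must be in [0, 0.2], got {self.target_density}"
            )
        total = sum(self.class_mix.values())
        if self.class_mix and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_mix must sum to 1, sums to {total}")


def _entity_surface(
    cls: PiiClass, gz: Gazetteer, rng: np.random.Generator
) -> str:
    """A realistic surface for one PII entity, detectable by the rule detector."""
    pick = lambda xs: xs[int(rng.integers(len(xs)))]
    if cls is PiiClass.AGE:
        return f"{rng.integers(18, 100)} år"
    if cls is PiiClass.FIRST_NAME:
        return pick(list(gz.first_names))
    if cls is PiiClass.LAST_NAME:
        return pick(gz.surnames)
    if cls is PiiClass.PARTIAL_DATE:
        if rng.random() < 0.5:
            return f"{rng.integers(1, 29)}/{rng.integers(1, 13)}"
        return f"{rng.integers(2010, 2024)}-{rng.integers(1, 13):02d}"
    if cls is PiiClass.FULL_DATE:
        return (
            f"{rng.integers(2010, 2024)}-{rng.integers(1, 13):02d}"
            f"-{rng.integers(1, 29):02d}"
        )
    if cls is PiiClass.PHONE_NUMBER:
        if rng.random() < 0.5:
            return f"08-{rng.integers(100, 1000)} {rng.integers(10, 100)} {rng.integers(10, 100)}"
        return f"070-{rng.integers(100, 1000)} {rng.integers(10, 100)} {rng.integers(10, 100)}"
    if cls is PiiClass.HEALTH_CARE_UNIT:
        return pick(gz.care_units)
    if cls is PiiClass.LOCATION:
        r = rng.random()
        if r < 0.6:
            return pick(gz.all_locations())
        if r < 0.8:
            pools = [s for ss in gz.streets.values() for s in ss]
            return pick(pools) if pools else pick(gz.all_locations())
        pools = [c for cs in gz.countries.values() for c in cs]
        return pick(pools) if pools else pick(gz.all_locations())
    return f"{pick(_ORG_ROOTS)} AB"  # Organization


def _token_len(surface: str) -> int:
    return len(surface.split(" "))


def _assemble_doc(
    doc_id: str,
    n_tokens: int,
    entities: list[tuple[PiiClass, str]],
    rng: np.random.Generator,
    label: str | None = None,
    extra_tokens: list[str] | None = None,
) -> AnnotatedDocument:
    """Build a space-separated token stream with entities at random slots."""
    ent_tokens = sum(_token_len(s) for _, s in entities)
    n_filler = max(0, n_tokens - ent_tokens)
    filler = [
        _FILLER_VOCAB[int(rng.integers(len(_FILLER_VOCAB)))] for _ in range(n_filler)
    ]
    if extra_tokens:
        for tok in extra_tokens:
            pos = int(rng.integers(0, len(filler) + 1))
            filler.insert(pos, tok)
    slots = sorted(
        rng.choice(len(filler) + 1, size=len(entities), replace=True).tolist()
    )
    pieces: list[str] = []
    spans: list[EntitySpan] = []
    pos = 0
    cursor = 0

    def emit(tok: str) -> None:
        nonlocal pos
        if pieces:
            pos += 1
        pieces.append(tok)
        pos += len(tok)

    for slot, (cls, surface) in zip(slots, entities):
        while cursor < slot:
            emit(filler[cursor])
            cursor += 1
        start = pos + 1 if pieces else 0
        emit(surface)
        spans.append(EntitySpan(start, start + len(surface), cls, surface))
    while cursor < len(filler):
        emit(filler[cursor])
        cursor += 1
    text = " ".join(pieces)
    spans.sort(key=lambda s: s.start)
    return AnnotatedDocument(doc_id=doc_id, text=text, spans=spans, label=label)


def generate_notes(
    config: NoteGeneratorConfig, gazetteer: Gazetteer
) -> list[AnnotatedDocument]:
    """Annotated synthetic notes at a controlled token-level PII density.

    Each note is a stream of Swedish clinical filler tokens with PII entities
    inserted at random slots; gold spans exactly delimit the inserted
    entities.  Entity counts are drawn so the corpus-level density
    concentrates on ``target_density``; class frequencies follow
    ``class_mix`` up to multinomial noise.
    """
    rng = np.random.default_rng(config.seed)
    classes = [c for c, w in config.class_mix.items() if w > 0]
    weights = np.array([config.class_mix[c] for c in classes], dtype=float)
    if classes:
        weights = weights / weights.sum()
        # expected tokens per entity under the class mix (surfaces below)
        mean_len = float(
            weights
            @ np.array(
                [2.0 if c is PiiClass.AGE else 3.0 if c is PiiClass.PHONE_NUMBER
                 else 2.0 if c is PiiClass.ORGANIZATION else 1.0 for c in classes]
            )
        )
    docs: list[AnnotatedDocument] = []
    lo, hi = config.tokens_per_doc
    for i in range(config.n_docs):
        n_tokens = int(rng.integers(lo, hi + 1))
        if config.target_density <= 0 or not classes:
            entities: list[tuple[PiiClass, str]] = []
        else:
            lam = n_tokens * config.target_density / mean_len
            k = int(rng.poisson(lam))
            max_k = max(0, int(n_tokens // (mean_len + 1)))
            k = min(k, max_k)
            idx = rng.choice(len(classes), size=k, p=weights)
            entities = [
                (classes[j], _entity_surface(classes[j], gazetteer, rng)) for j in idx
            ]
        docs.append(_assemble_doc(f"note{i:05d}", n_tokens, entities, rng))
    return docs


# ------------------------------------------------------------------ tasks

SIGNAL_PREFIX = "marker"


@dataclass
class TaskGeneratorConfig:
    """Controls for labeled task corpora with known signal location.

    ``signal_location='non_pii'`` plants label-predictive marker tokens in
    plain text outside every PII span, so an ideal pseudonymizer leaves the
    signal untouched.  ``'pii_dependent'`` encodes the label exclusively in
    first-name PII spans (label-specific name pools), so stripping or
    replacing PII reduces the Bayes-optimal rule to chance.
    ``signal_strength`` in (0, 1] is the probability that a marker carries
    the true label rather than a uniformly random one.
    """

    task_type: str = "doc_classification"  # or "token_ner"
    n_classes: int = 2
    signal_location: str = "non_pii"  # or "pii_dependent"
    signal_strength: float = 1.0
    n_docs: int = 200
    seed: int = 0
    markers_per_doc: int = 4
    tokens_per_doc: tuple[int, int] = (40, 80)
    background_density: float = 0.0157

    def __post_init__(self) -> None:
        if self.task_type not in ("doc_classification", "token_ner"):
            raise ValidationError(f"unknown task_type {self.task_type!r}")
        if self.signal_location not in ("non_pii", "pii_dependent"):
            raise ValidationError(f"unknown signal_location {self.signal_location!r}")
        if not (0.0 < self.signal_strength <= 1.0):
            raise ValidationError("signal_strength must be in (0, 1]")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")


def signal_names(n_classes: int, pool_size: int = 6) -> dict[str, list[str]]:
    """Label-specific first-name pools used in pii_dependent mode."""
    return {
        str(y): [f"Sig{y}nam{j}" for j in range(pool_size)] for y in range(n_classes)
    }


def generate_task_corpus(
    config: TaskGeneratorConfig, gazetteer: Gazetteer
) -> list[AnnotatedDocument]:
    """Labeled documents whose signal location is known by construction.

    Labels are balanced up to multinomial noise.  In non_pii mode a keyword
    lookup over marker tokens attains accuracy ``s + (1-s)/n_classes`` by
    construction (100% at maximal signal strength); in pii_dependent mode the
    same is true of the label-coding name spans, and removing PII tokens
    leaves only chance-level information.
    """
    rng = np.random.default_rng(config.seed)
    n_cls = config.n_classes
    pools = signal_names(n_cls)
    bg_cfg = NoteGeneratorConfig(
        n_docs=1,
        target_density=config.background_density,
        seed=config.seed,
        tokens_per_doc=config.tokens_per_doc,
    )
    bg_classes = [c for c, w in bg_cfg.class_mix.items() if w > 0]
    bg_weights = np.array([bg_cfg.class_mix[c] for c in bg_classes])
    bg_weights = bg_weights / bg_weights.sum()
    mean_len = float(
        bg_weights
        @ np.array(
            [2.0 if c is PiiClass.AGE else 3.0 if c is PiiClass.PHONE_NUMBER
             else 2.0 if c is PiiClass.ORGANIZATION else 1.0 for c in bg_classes]
        )
    )
    lo, hi = config.tokens_per_doc
    docs: list[AnnotatedDocument] = []
    for i in range(config.n_docs):
        y = int(rng.integers(0, n_cls))
        n_tokens = int(rng.integers(lo, hi + 1))
        lam = n_tokens * config.background_density / mean_len
        k = min(int(rng.poisson(lam)), max(0, int(n_tokens // (mean_len + 1))))
        idx = rng.choice(len(bg_classes), size=k, p=bg_weights)
        entities = [
            (bg_classes[j], _entity_surface(bg_classes[j], gazetteer, rng))
            for j in idx
        ]
        marker_tokens: list[str] = []
        for _ in range(config.markers_per_doc):
            lbl = (
                y
                if rng.random() < config.signal_strength
                else int(rng.integers(0, n_cls))
            )
            if config.signal_location == "non_pii":
                marker_tokens.append(f"{SIGNAL_PREFIX}{lbl}x{int(rng.integers(3))}")
            else:
                pool = pools[str(lbl)]
                entities.append(
                    (PiiClass.FIRST_NAME, pool[int(rng.integers(len(pool)))])
                )
        doc = _assemble_doc(
            f"task{i:05d}",
            n_tokens,
            entities,
            rng,
            label=str(y),
            extra_tokens=marker_tokens,
        )
        if config.task_type == "token_ner":
            doc.token_tags = _marker_token_tags(doc)
        docs.append(doc)
    return docs


def _marker_token_tags(doc: AnnotatedDocument) -> list[str]:
    """Token-level tags for token_ner tasks: markers and signal names tagged
    with their encoded label, everything else O."""
    from .schema import tokenize

    tags: list[str] = []
    for ts, te in tokenize(doc.text):
        tok = doc.text[ts:te]
        if tok.startswith(SIGNAL_PREFIX):
            tags.append("B-M" + tok[len(SIGNAL_PREFIX)])
        elif tok.startswith("Sig") and "nam" in tok:
            tags.append("B-M" + tok[3])
        else:
            tags.append("O")
    return tags
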