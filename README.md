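# pseudoclin

Pseudonymization of clinical free text, and measurement of what it costs.

Clinical notes cannot leave the hospital while they contain personally
identifiable information (PII): names, dates, ages, phone numbers, care
units, locations. *Pseudonymization* removes that information in two steps —
detect the sensitive entities, then substitute each with a realistic
surrogate of the same type — so that the text stays fluent and usable for
training NLP models. The open question for anyone applying it is whether the
rewrite damages the *utility* of the data: does a model trained on
pseudonymized notes perform worse than one trained on the originals?

`pseudoclin` is a library (plus a thin CLI) for studying exactly that
question at desk scale, aimed at clinical-NLP researchers and data-protection
engineers. It provides:

- **A nine-class PII schema** derived from the HIPAA PHI categories
  (Age, FirstName, LastName, PartialDate, FullDate, PhoneNumber,
  HealthCareUnit, Location, Organization), with corpus I/O in brat-style
  standoff, CoNLL-style BIO TSV, JSONL and plain text.
- **A surrogate engine** with per-class rules: gendered first names map to
  names of the same gender; streets stay within their city, places within
  their county, countries within their continent; care units are swapped
  within a known-clinic list; postal codes are redrawn weighted by
  population; dates are shifted one to two weeks (|Δ| ~ U{7,…,14} days,
  sign random, never zero); ages and years move by a small nonzero number of
  years; phone numbers keep their exact formatting while area codes and
  subscriber digits are replaced. Organizations have no replacement lexicon
  and pass through by default (a documented limitation), or can be masked.
- **A detector contract** with a rule-based reference implementation
  (patterns + gazetteers) and a *degradation simulator* that turns any
  detector into one with controllable recall (missed spans) and precision
  (spurious spans over non-detected text) — the two failure modes that decide
  whether pseudonymization leaks PII or corrupts task-relevant words.
- **Synthetic data generators** for gazetteers, annotated notes at a
  controlled token-level PII density (default 1.57%), and labeled task
  corpora whose label signal provably lives either outside all PII spans or
  exclusively inside them.
- **The utility-evaluation protocol**: a full factorial plan over models ×
  data versions × tasks, k-fold cross-validation (default k = 10) with a
  lightweight term-frequency classifier capped at 10 training epochs with
  early stopping, and, for every task, a one-sided Mann–Whitney U test per
  ordered pair of configurations over the fold-wise F1 samples:

  U = #{(i, j) : x_i > y_j} + ½·#{(i, j) : x_i = y_j},

  with the p-value computed *exactly* (enumeration of the permutation null,
  mid-ranks under ties) whenever n + m ≤ 20, and by the tie-corrected normal
  approximation otherwise.

## Worked example

```python
from pseudoclin import RuleDetector, SurrogatePolicy, generate_gazetteer
from pseudoclin.schema import AnnotatedDocument
from pseudoclin.surrogate import pseudonymize_document

gz = generate_gazetteer(seed=7)
note = AnnotatedDocument(doc_id="note-001", text=(
    "Nilolf Bergberg, 84 år, inkom till Neurologkliniken 2019-03-05 "
    "med buksmärta. Åter 12/3 för kontroll, ring 08-123 45 67."))
rewritten, log = pseudonymize_document(
    note, RuleDetector(gz), gz, SurrogatePolicy(master_seed=17))
print(rewritten.text)
```

prints

```
Magus Stranddahl, 79 år, inkom till Kirurgmottagningen 2019-03-16 med
buksmärta. Åter 23/3 för kontroll, ring 08-184 98 11.
```

The male first name became another male name, the age moved 5 years, the
admission date and the follow-up partial date each moved 7–14 days, the
phone number kept its `NN-NNN NN NN` shape with a valid area code, and every
character outside the detected spans is byte-identical to the input. The
replacement log records one `(original, surrogate, rule)` triple per entity.
Re-running with the same `master_seed` reproduces the rewrite exactly;
surrogates are drawn from per-document substreams, so corpus order does not
matter.

The `examples/` directory has one short script per capability: single-note
pseudonymization, synthetic corpus generation (500 notes realize 1.60%
density against the 1.57% target), detector degradation and per-class
precision/recall scoring, and the full utility experiment (on a task whose
signal lives outside PII, the original-vs-pseudonymized comparison finds 0
of 6 pairwise tests significant).

A thin CLI mirrors the library:

```bash
pseudoclin simulate notes --n 500 --density 0.0157 --seed 7 --out corpus.jsonl
pseudoclin pseudonymize --in corpus.jsonl --format jsonl --gazetteer gz/ \
    --seed 17 --out pseudo.jsonl --log replacements.csv
pseudoclin end-to-end --seed 17 --out runs/demo
```

## Scope

The package studies the *protocol* — detection, surrogate rules, and the
statistics of utility comparison — on synthetic corpora with known ground
truth. It does not train neural NER models or transformers, does not score
re-identification risk, and makes no claim that its lightweight classifier
scores are comparable to fine-tuned language-model scores. See
`docs/methods.md` for the model, its assumptions, and known limitations.
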