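# Methods

This note documents the models and procedures implemented in `pseudoclin`,
the assumptions behind them, the parameters that matter, and what results on
the synthetic corpora do and do not show about real clinical data.

## The pseudonymization model

De-identification is modeled as the standard two-step pipeline: a *detector*
maps document text to typed character-offset spans over a nine-class PII
taxonomy (Age, FirstName, LastName, PartialDate, FullDate, PhoneNumber,
HealthCareUnit, Location, Organization — the HIPAA PHI categories collapsed
to the classes that occur in clinical free text), and a *surrogate engine*
replaces each detected span with a realistic value of the same type.
Offsets are 0-based, half-open, in unicode code points; spans within a
document are non-overlapping and sorted, and overlapping input is rejected
rather than merged because the replacement engine needs a unique rule per
character.

### Surrogate rules and their parameters

| class | rule | tunables (default) |
|---|---|---|
| FirstName | same gender category (F/M/neutral); unknown names draw from the union list | — |
| LastName | uniform from the surname lexicon | — |
| Location (street) | uniform within the same city | — |
| Location (place) | uniform within the same county | — |
| Location (country) | uniform within the same continent | — |
| Location (postal code) | population-weighted redraw, spacing preserved | — |
| FullDate / PartialDate | shift by Δ days, \|Δ\| ~ U{lo..hi}, sign uniform | `date_shift_days` (7, 14) |
| Age / year | move by Δ years, \|Δ\| ~ U{lo..hi}, sign uniform, result ≥ 0 | `age_delta_years` (1, 5) |
| PhoneNumber | keep separators/grouping/digit count; valid area code; random subscriber digits | — |
| HealthCareUnit | uniform within the known-clinic list | — |
| Organization | passthrough (default) or mask | `organization_mode` |

"One or two weeks" is read as |Δ| uniform on the *integer day range* 7–14
rather than Δ ∈ {±7, ±14}; the range is configurable and nothing downstream
depends on the reading. Date surfaces are re-rendered in their input dialect
(ISO, `D/M/YYYY` with per-component zero-padding preserved) with correct
calendar arithmetic across month and year boundaries. Partial dates shift
only their known components: `D/M` partials move on a leap-year scaffold
(year 2000) so 29/2 stays representable; `YYYY-MM` partials move from a
uniformly drawn anchor day, so a week-scale shift may legitimately render
the same month — such cases are flagged `:unchanged` in the rule id rather
than forced to move a full month; bare years are perturbed like ages.

Two policy flags cover choices the replacement literature leaves open.
`referential_name_consistency` (default on) gives repeated name surfaces in
one document the same surrogate, which keeps the rewritten note readable.
`document_consistent_dates` (default off) applies a single Δ to every date
in a document, preserving clinically meaningful intervals at the cost of a
correlated shift; the default is per-entity independence.

Determinism: all randomness flows from `master_seed` through per-document
substreams keyed by `crc32(doc_id)`, so outputs are byte-identical across
runs and invariant to corpus order. Pseudonymization is deliberately *not*
idempotent — a second pass with a different seed re-replaces surrogates —
and the suite asserts this rather than hiding it.

### Degenerate inputs

Single-candidate lexica return the original with a `no-alternative` flag;
unparseable dates/ages/phones pass through with a warning rather than
failing the pipeline (a detector with imperfect precision routinely hands
the rules non-date, non-numeric text); empty lexica raise a configuration
error naming the resource.

## The reference detector and the degradation simulator

The rule detector combines regular expressions (ISO and `D/M/Y` dates,
`D/M` and `YYYY-MM` partials, `NN år` ages, birth years, Swedish phone and
postal-code shapes, `<Name> AB` organizations) with gazetteer term lookup
for names, care units and geography. Pattern collisions are resolved
longest-match-wins with left-to-right tie-breaking, so a full date subsumes
the partial date inside it. This detector is a transparent, deterministic
stand-in for the neural NER models used in production de-identifiers; the
`Detector` protocol (text → spans) is the seam where such models plug in.

`degrade_detector(base, miss_rate, spurious_rate, seed)` simulates an
imperfect de-identifier: each base span is dropped independently with
probability `miss_rate` (recall loss), and spurious one-to-two-token spans
of uniformly random class are injected at `spurious_rate` per 100 tokens
over stretches the detector did not claim (precision loss). Crucially,
stretches containing *missed* PII are eligible for spurious injection; this
is what lets the simulator reproduce the empirically observed failure mode
in which a low-precision pseudonymizer replaces task-relevant or
signal-bearing words with surrogates.

Evaluation is span-level with per-class precision and recall in percent.
Strict matching (identical start, end, class) is the default; overlap
matching (same class, ≥ 1 shared character, greedy one-to-one pairing) is
available for sensitivity analysis and can only score higher. Cells with an
empty denominator are reported as 0 with an explicit `*_defined` flag so
aggregate tables contain no undefined entries.

## Synthetic data

The generators produce *controlled statistical structure*, not realistic
prose. Notes are streams of Swedish clinical filler tokens with PII
entities inserted at random slots; entity surfaces are drawn from the
gazetteer and from the detector's date/phone/age dialects, so the gold
spans are simultaneously detectable by the reference detector. Token-level
PII density is controlled by drawing the per-document entity count from a
Poisson law scaled by the expected entity token length under the class mix;
at 200+ documents the realized corpus density concentrates within a few
hundredths of a percentage point of the target. The default target is
1.57%, with the per-note-type plausible range being roughly 1–2%; the
default class mix weights ages, names, dates and care units as the dominant
classes, with phones and organizations rare.

Task corpora add a label whose information location is known by
construction. In `non_pii` mode, lowercase marker tokens (never matching
any PII pattern or lexicon) carry the label; with signal strength *s*, each
marker encodes the true label with probability *s* and a uniformly random
one otherwise, so a majority-vote keyword rule attains *s* + (1−*s*)/C
accuracy and 100% at *s* = 1. In `pii_dependent` mode the markers are
instead capitalized name-like tokens annotated as FirstName spans and drawn
from label-specific pools — stripping or replacing PII provably reduces the
Bayes rule to chance.

What the generator does **not** emulate: discourse structure, spelling
variation, abbreviations, section headers, label noise correlated with
text length, and PII surface ambiguity (e.g., eponyms shared between
diseases and surnames). Tests passing on this material validate the
*mechanics and statistics* of the pipeline, not detection difficulty on
real notes.

## The utility-evaluation protocol

An experiment plan is the full factorial of models × data versions ×
tasks; each configuration is scored with k-fold cross-validation (default
k = 10). Folds are split once per task on document indices and shared
across data versions, so a configuration trained on pseudonymized data is
also tested on pseudonymized folds while comparisons across versions are
fold-matched — pseudonymization is treated as a deterministic preprocessing
step, which it is.

The classifier is a deliberate desk-scale stand-in for fine-tuning a
language model: a term-count linear model trained by SGD for at most 10
epochs with tolerance-based early stopping (`tf-linear`), or multinomial
naive Bayes (`tf-nb`) as a second model axis; token-level tasks use a
per-token majority lexical tagger scored with span-level micro F1. Each
cross-validation run gets its own fit seed (derived from the plan seed,
configuration id and fold index), playing the role of per-run training
stochasticity. Absolute scores are not comparable to transformer scores
and are never treated as such; the object of study is the comparison
protocol.

F1 averaging defaults to weighted for document classification and
span-level micro for token tasks, both configurable, since the convention
is not standardized across studies.

### The Mann–Whitney U test

For every task, each ordered pair (A, B) of distinct configurations is
tested one-sided: does A score below B across the k folds? With c
configurations per task this yields c(c−1) tests per task — the convention
that makes 6 configurations × 5 tasks come out at 150 tests. No
multiple-testing correction is applied by default (the comparison-matrix
summary is meant to be read with the ~1-in-20 false-positive rate in mind);
Holm adjustment is available via a flag.

U is computed with mid-ranks. For n + m ≤ 20 the p-value is exact: the
no-tie null distribution comes from the classical counting recurrence
f(u; n, m) = f(u−m; n−1, m) + f(u; n, m−1), and tied samples are handled by
enumerating all C(n+m, n) assignments of the pooled values. Beyond 20 the
normal approximation with tie correction and a ½ continuity correction is
used. The suite cross-checks the exact path against scipy (untied) and
against a brute-force enumeration oracle (tied), and verifies type-I
calibration: under a continuous null with n = m = 10 the test rejects at
α = 0.05 in ≈ 4.6% of draws — slightly below α because the exact null is
discrete.

### The replicated utility experiment

`pseudoclin.experiments` packages the end-to-end question as a replicable
unit: generate a task corpus, pseudonymize it with a configured detector,
cross-validate both versions, and test whether the pseudonymized arm is
weaker. Two regimes are exercised:

* **Null regime** — signal outside PII, perfect detector, stochastic
  `tf-linear` runs: the comparison is a true null and the rejection
  frequency over seeds sits at or slightly below α (fold-score ties make
  the exact test conservative).
* **Power regime** — signal inside PII spans the rule detector's lexicon
  does not contain, degraded with increasing `spurious_rate`, deterministic
  `tf-nb` model (chosen because the 10-epoch SGD underfits at 200 documents
  and its fold variance would mask the corruption effect): spurious
  replacements destroy signal tokens at a rate growing with the spurious
  rate, and the pseudonymized arm is flagged weaker with frequency rising
  from ~0 to above 50% across spurious rates 1 → 8 per 100 tokens.

Problem sizes (120–200 documents of 40–80 tokens, k = 10, 40–200
replicates) were chosen so the full replication battery completes in a few
minutes on one CPU while keeping binomial standard errors on the rejection
rates below ~0.08.

## Known limitations

* The BIO TSV dialect reconstructs text by single-space joining tokens, so
  byte-exact round-trip holds only for corpora already in that form (the
  synthetic generator's output is); standoff and JSONL round-trip
  arbitrary text exactly.
* Token tags are realigned positionally after replacement; a surrogate
  that changes the token count inherits the last original tag for its
  extra tokens. Token-level utility experiments should use surrogates of
  stable token length (names, units, dates all are).
* Organizations pass through unreplaced by default; mask mode is the safer
  alternative when organization leakage matters.
* Gazetteer reverse lookups (county-of, city-of) are linear scans — fine at
  desk scale, worth indexing for lexica in the 10⁵ range.
* The detector's pattern dialects cover common Swedish date/phone/postal
  shapes, not the full variety of real EHR text.
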