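"""Surrogate rules: class constraints, formatting preservation, determinism,
and document-rewrite conservation."""

import datetime

import numpy as np
import pytest

from pseudoclin import (
    AnnotatedDocument,
    EntitySpan,
    GoldDetector,
    NoteGeneratorConfig,
    PiiClass,
    RuleDetector,
    SurrogatePolicy,
    generate_notes,
    perturb_age,
    pseudonymize_corpus,
    pseudonymize_document,
    replace_care_unit,
    replace_location,
    replace_name,
    replace_phone,
    replace_postal_code,
    replacement_report,
    shift_date,
)
from pseudoclin.surrogate import ConfigurationError

POLICY = SurrogatePolicy(master_seed=0)


class TestReplaceName:
    def test_forced_same_gender_alternative(self, tiny_gazetteer, rng):
        import dataclasses

        gz = dataclasses.replace(
            tiny_gazetteer, first_names={"Anna": "F", "Karin": "F", "Erik": "M"}
        )
        surrogate, rule = replace_name("Anna", PiiClass.FIRST_NAME, gz, rng)
        assert surrogate == "Karin"
        assert "gender-F" in rule

    def test_forced_neutral_alternative(self, tiny_gazetteer, rng):
        surrogate, _ = replace_name("Kim", PiiClass.FIRST_NAME, tiny_gazetteer, rng)
        assert surrogate == "Alex"

    def test_gender_category_always_preserved(self, gen_gazetteer, rng):
        by_gender = {}
        for name, g in gen_gazetteer.first_names.items():
            by_gender.setdefault(g, name)
        for gender, name in by_gender.items():
            for _ in range(2000):
                surrogate, _ = replace_name(name, PiiClass.FIRST_NAME, gen_gazetteer, rng)
                assert gen_gazetteer.first_names[surrogate] == gender
                assert surrogate != name

    def test_unknown_name_falls_back_to_union(self, tiny_gazetteer, rng):
        surrogate, rule = replace_name("Zorro", PiiClass.FIRST_NAME, tiny_gazetteer, rng)
        assert surrogate in tiny_gazetteer.first_names
        assert "fallback" in rule

    def test_last_name_from_surname_list(self, tiny_gazetteer, rng):
        for _ in range(200):
            surrogate, _ = replace_name("Lund", PiiClass.LAST_NAME, tiny_gazetteer, rng)
            assert surrogate in tiny_gazetteer.surnames
            assert surrogate != "Lund"

    def test_empty_resource_is_configuration_error(self, rng):
        from pseudoclin import Gazetteer

        with pytest.raises(ConfigurationError, match="first_names"):
            replace_name("Anna", PiiClass.FIRST_NAME, Gazetteer(), rng)


class TestReplaceLocation:
    def test_forced_same_county(self, tiny_gazetteer, rng):
        surrogate, rule = replace_location("Åre", tiny_gazetteer, rng)
        assert surrogate == "Kluk"
        assert "Jämtland" in rule

    def test_forced_same_continent(self, tiny_gazetteer, rng):
        surrogate, _ = replace_location("Italien", tiny_gazetteer, rng)
        assert surrogate == "Spanien"

    def test_street_stays_in_city(self, tiny_gazetteer, rng):
        surrogate, _ = replace_location("Storgatan", tiny_gazetteer, rng)
        assert surrogate == "Lillgatan"

    def test_no_cross_county_replacement_in_seeded_draws(self, gen_gazetteer, rng):
        county_of = gen_gazetteer.county_of
        originals = [places[0] for places in gen_gazetteer.locations.values()]
        for _ in range(1000):
            for original in originals:
                surrogate, _ = replace_location(original, gen_gazetteer, rng)
                assert county_of(surrogate) == county_of(original)
                assert surrogate != original


class TestReplaceCareUnit:
    def test_two_entry_list_is_forced(self, tiny_gazetteer, rng):
        surrogate, _ = replace_care_unit("Akutmottagningen", tiny_gazetteer, rng)
        assert surrogate == "Kirurgkliniken"

    def test_single_entry_flags_no_alternative(self, rng, tiny_gazetteer):
        import dataclasses

        gz = dataclasses.replace(tiny_gazetteer, care_units=["Enda"])
        surrogate, rule = replace_care_unit("Enda", gz, rng)
        assert surrogate == "Enda"
        assert "no-alternative" in rule

    def test_membership_over_draws(self, gen_gazetteer, rng):
        for _ in range(500):
            surrogate, _ = replace_care_unit(gen_gazetteer.care_units[0], gen_gazetteer, rng)
            assert surrogate in gen_gazetteer.care_units


class TestReplacePostalCode:
    def test_degenerate_weight_always_wins(self, rng, tiny_gazetteer):
        import dataclasses

        gz = dataclasses.replace(tiny_gazetteer, postal_codes={"111 22": 1.0})
        for _ in range(20):
            assert replace_postal_code("333 44", gz, rng)[0] == "111 22"

    def test_population_weighted_frequencies(self, rng, tiny_gazetteer):
        import dataclasses

        gz = dataclasses.replace(
            tiny_gazetteer, postal_codes={"111 22": 0.9, "222 33": 0.1}
        )
        n = 10_000
        hits = sum(
            replace_postal_code("999 99", gz, rng)[0] == "111 22" for _ in range(n)
        )
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(hits / n - 0.9) < 3 * se

    def test_spaceless_original_renders_spaceless(self, tiny_gazetteer, rng):
        surrogate, _ = replace_postal_code("33344", tiny_gazetteer, rng)
        assert " " not in surrogate
        assert len(surrogate) == 5
        surrogate2, _ = replace_postal_code("333 44", tiny_gazetteer, rng)
        assert " " in surrogate2


class TestShiftDate:
    def test_forced_week_shift(self, rng):
        out, _ = shift_date("2019-03-05", PiiClass.FULL_DATE, POLICY, rng, fixed_delta=7)
        assert out == "2019-03-12"

    def test_forced_month_boundary(self, rng):
        out, _ = shift_date("2019-02-25", PiiClass.FULL_DATE, POLICY, rng, fixed_delta=7)
        assert out == "2019-03-04"

    def test_forced_year_boundary(self, rng):
        out, _ = shift_date("2019-12-28", PiiClass.FULL_DATE, POLICY, rng, fixed_delta=7)
        assert out == "2020-01-04"

    def test_day_month_year_dialect_preserves_padding(self, rng):
        out, _ = shift_date("05/03/2019", PiiClass.FULL_DATE, POLICY, rng, fixed_delta=7)
        assert out == "12/03/2019"
        out2, _ = shift_date("5/3/2019", PiiClass.FULL_DATE, POLICY, rng, fixed_delta=7)
        assert out2 == "12/3/2019"

    def test_seeded_shifts_stay_in_window_and_move(self, rng):
        original = datetime.date(2019, 6, 15)
        for _ in range(1000):
            out, _ = shift_date("2019-06-15", PiiClass.FULL_DATE, POLICY, rng)
            shifted = datetime.date.fromisoformat(out)
            delta = abs((shifted - original).days)
            assert 7 <= delta <= 14
            assert out != "2019-06-15"

    def test_partial_day_month_shifts_within_window(self, rng):
        anchor = datetime.date(2000, 6, 15)
        for _ in range(500):
            out, _ = shift_date("15/6", PiiClass.PARTIAL_DATE, POLICY, rng)
            d, m = (int(p) for p in out.split("/"))
            delta = abs((datetime.date(2000, m, d) - anchor).days)
            assert 7 <= delta <= 14

    def test_leap_day_partial_is_representable(self, rng):
        out, rule = shift_date("29/2", PiiClass.PARTIAL_DATE, POLICY, rng, fixed_delta=7)
        assert out == "7/3"
        assert "dm_partial" in rule

    def test_unparseable_passes_through_with_flag(self, rng):
        out, rule = shift_date("i fjol", PiiClass.PARTIAL_DATE, POLICY, rng)
        assert out == "i fjol"
        assert "passthrough" in rule


class TestPerturbAge:
    def test_forced_negative_delta(self, forced_rng_factory):
        rng = forced_rng_factory([3], random_value=0.9)  # magnitude 3, negative
        assert perturb_age("84", POLICY, rng)[0] == "81"

    def test_forced_positive_delta_on_year(self, forced_rng_factory):
        rng = forced_rng_factory([2], random_value=0.1)
        assert perturb_age("1943", POLICY, rng)[0] == "1945"

    def test_suffix_preserved(self, forced_rng_factory):
        rng = forced_rng_factory([3], random_value=0.9)
        assert perturb_age("84 år", POLICY, rng)[0] == "81 år"

    def test_draws_stay_in_window_and_never_zero(self, rng):
        for _ in range(10_000):
            out, _ = perturb_age("70", POLICY, rng)
            value = int(out)
            assert 65 <= value <= 75
            assert value != 70

    def test_never_negative(self, rng):
        for _ in range(500):
            assert int(perturb_age("1", POLICY, rng)[0]) >= 0

    def test_non_numeric_passthrough(self, rng):
        out, rule = perturb_age("ung", POLICY, rng)
        assert out == "ung" and "passthrough" in rule


class TestReplacePhone:
    def test_local_shape_preserved(self, tiny_gazetteer, rng):
        import re

        for _ in range(1000):
            out, _ = replace_phone("08-123 45 67", tiny_gazetteer, rng)
            assert re.fullmatch(r"\d{2}-\d{3} \d{2} \d{2}", out)
            assert out[:2] in tiny_gazetteer.phone_area_codes
            assert out != "08-123 45 67"

    def test_country_prefix_retained(self, tiny_gazetteer, rng):
        import re

        out, _ = replace_phone("+46 70 123 45 67", tiny_gazetteer, rng)
        assert out.startswith("+46 ")
        assert re.fullmatch(r"\+46 \d{2} \d{3} \d{2} \d{2}", out)

    def test_empty_input_passthrough(self, tiny_gazetteer, rng):
        out, rule = replace_phone("", tiny_gazetteer, rng)
        assert out == "" and "passthrough" in rule


class TestPseudonymizeDocument:
    def test_no_entities_is_identity(self, tiny_gazetteer):
        doc = AnnotatedDocument(doc_id="d", text="helt vanlig text")
        out, records = pseudonymize_document(
            doc, GoldDetector([doc]), tiny_gazetteer, POLICY
        )
        assert out.text == doc.text
        assert records == []

    def test_forced_composition(self, tiny_gazetteer):
        import dataclasses

        gz = dataclasses.replace(
            tiny_gazetteer, first_names={"Anna": "F", "Karin": "F"}
        )
        doc = AnnotatedDocument(
            doc_id="d", text="Anna är 84",
            spans=[
                EntitySpan(0, 4, PiiClass.FIRST_NAME, "Anna"),
                EntitySpan(8, 10, PiiClass.AGE, "84"),
            ],
        )
        out, records = pseudonymize_document(doc, GoldDetector([doc]), gz, POLICY)
        assert out.text.startswith("Karin är ")
        new_age = int(out.text.split()[-1])
        assert 79 <= new_age <= 89 and new_age != 84
        assert len(records) == 2
        assert out.spans[0].surface == "Karin"

    def test_text_outside_spans_byte_identical(self, gen_gazetteer):
        docs = generate_notes(
            NoteGeneratorConfig(n_docs=50, seed=3, target_density=0.08), gen_gazetteer
        )
        out_docs, _ = pseudonymize_corpus(
            docs, GoldDetector(docs), gen_gazetteer, POLICY
        )
        for orig, new in zip(docs, out_docs):
            frags_orig, cursor = [], 0
            for sp in orig.spans:
                frags_orig.append(orig.text[cursor : sp.start])
                cursor = sp.end
            frags_orig.append(orig.text[cursor:])
            frags_new, cursor = [], 0
            for sp in new.spans:
                frags_new.append(new.text[cursor : sp.start])
                cursor = sp.end
            frags_new.append(new.text[cursor:])
            assert frags_orig == frags_new

    def test_replaced_spans_do_not_keep_original_surface(self, gen_gazetteer):
        docs = generate_notes(
            NoteGeneratorConfig(n_docs=100, seed=4, target_density=0.08), gen_gazetteer
        )
        _, records = pseudonymize_corpus(docs, GoldDetector(docs), gen_gazetteer, POLICY)
        for rec in records:
            if "no-alternative" in rec.rule or "unchanged" in rec.rule or "passthrough" in rec.rule:
                continue
            assert rec.surrogate != rec.original

    def test_conservation_of_detected_spans(self, gen_gazetteer):
        """Every non-organization detected span yields exactly one record."""
        docs = generate_notes(
            NoteGeneratorConfig(n_docs=200, seed=5, target_density=0.05), gen_gazetteer
        )
        detector = GoldDetector(docs)
        out_docs, records = pseudonymize_corpus(docs, detector, gen_gazetteer, POLICY)
        detected = {c: 0 for c in PiiClass}
        for d in docs:
            for sp in detector.detect(d.text):
                detected[sp.pii_class] += 1
        logged = {c: 0 for c in PiiClass}
        for r in records:
            logged[r.pii_class] += 1
        for cls in PiiClass:
            expected = 0 if cls is PiiClass.ORGANIZATION else detected[cls]
            assert logged[cls] == expected

    def test_masked_organizations_are_logged(self, tiny_gazetteer):
        doc = AnnotatedDocument(
            doc_id="d", text="hos Vårdbolaget AB idag",
            spans=[EntitySpan(4, 18, PiiClass.ORGANIZATION, "Vårdbolaget AB")],
        )
        policy = SurrogatePolicy(master_seed=0, organization_mode="mask")
        out, records = pseudonymize_document(doc, GoldDetector([doc]), tiny_gazetteer, policy)
        assert out.text == "hos [ORGANIZATION] idag"
        assert len(records) == 1

    def test_referential_name_consistency(self, gen_gazetteer):
        name = next(iter(gen_gazetteer.first_names))
        text = f"{name} mår bra. {name} skrivs ut."
        doc = AnnotatedDocument(
            doc_id="d", text=text,
            spans=[
                EntitySpan(0, len(name), PiiClass.FIRST_NAME, name),
                EntitySpan(
                    len(name) + 10, 2 * len(name) + 10, PiiClass.FIRST_NAME, name
                ),
            ],
        )
        out, records = pseudonymize_document(
            doc, GoldDetector([doc]), gen_gazetteer, POLICY
        )
        assert records[0].surrogate == records[1].surrogate

    def test_document_consistent_dates_preserve_intervals(self, gen_gazetteer):
        text = "från 2019-03-05 till 2019-03-20"
        doc = AnnotatedDocument(
            doc_id="d", text=text,
            spans=[
                EntitySpan(5, 15, PiiClass.FULL_DATE, "2019-03-05"),
                EntitySpan(21, 31, PiiClass.FULL_DATE, "2019-03-20"),
            ],
        )
        policy = SurrogatePolicy(master_seed=3, document_consistent_dates=True)
        out, records = pseudonymize_document(
            doc, GoldDetector([doc]), gen_gazetteer, policy
        )
        d1 = datetime.date.fromisoformat(records[0].surrogate)
        d2 = datetime.date.fromisoformat(records[1].surrogate)
        assert (d2 - d1).days == 15

    def test_determinism_and_order_independence(self, gen_gazetteer):
        docs = generate_notes(
            NoteGeneratorConfig(n_docs=30, seed=6, target_density=0.08), gen_gazetteer
        )
        detector = GoldDetector(docs)
        a, ra = pseudonymize_corpus(docs, detector, gen_gazetteer, POLICY)
        b, rb = pseudonymize_corpus(docs, detector, gen_gazetteer, POLICY)
        assert [d.text for d in a] == [d.text for d in b]
        assert [(r.doc_id, r.surrogate) for r in ra] == [(r.doc_id, r.surrogate) for r in rb]
        shuffled, _ = pseudonymize_corpus(
            list(reversed(docs)), detector, gen_gazetteer, POLICY
        )
        by_id = {d.doc_id: d.text for d in shuffled}
        assert all(by_id[d.doc_id] == out.text for d, out in zip(docs, a))

    def test_second_pass_with_new_seed_re_replaces(self, gen_gazetteer):
        """Pseudonymization is not idempotent: a second pass rewrites again."""
        docs = generate_notes(
            NoteGeneratorConfig(n_docs=40, seed=7, target_density=0.08), gen_gazetteer
        )
        first, _ = pseudonymize_corpus(docs, GoldDetector(docs), gen_gazetteer, POLICY)
        second, _ = pseudonymize_corpus(
            first, GoldDetector(first), gen_gazetteer, SurrogatePolicy(master_seed=99)
        )
        changed = sum(a.text != b.text for a, b in zip(first, second))
        with_spans = sum(bool(d.spans) for d in first)
        assert with_spans > 10
        assert changed > with_spans // 2

    def test_policy_validation(self):
        from pseudoclin.schema import ValidationError

        with pytest.raises(ValidationError):
            SurrogatePolicy(date_shift_days=(0, 14))
        with pytest.raises(ValidationError):
            SurrogatePolicy(age_delta_years=(3, 2))
        with pytest.raises(ValidationError):
            SurrogatePolicy(organization_mode="drop")


class TestReplacementReport:
    def test_empty_log_zero_counts_with_total_words(self, gen_gazetteer):
        docs = generate_notes(
            NoteGeneratorConfig(n_docs=5, seed=1, target_density=0.0), gen_gazetteer
        )
        report = replacement_report([], docs)
        counts = dict(zip(report["pii_class"], report["count"]))
        assert counts["Total words"] > 0
        assert all(counts[c.value] == 0 for c in PiiClass)

    def test_report_matches_independent_groupby(self, gen_gazetteer):
        docs = generate_notes(
            NoteGeneratorConfig(n_docs=200, seed=8, target_density=0.05), gen_gazetteer
        )
        out_docs, records = pseudonymize_corpus(
            docs, GoldDetector(docs), gen_gazetteer, POLICY
        )
        report = replacement_report(records, out_docs)
        counts = dict(zip(report["pii_class"], report["count"]))
        import collections

        tally = collections.Counter(r.pii_class.value for r in records)
        for cls in PiiClass:
            assert counts[cls.value] == tally.get(cls.value, 0)

    def test_counts_add_over_merged_corpora(self, gen_gazetteer):
        a = generate_notes(
            NoteGeneratorConfig(n_docs=30, seed=2, target_density=0.05), gen_gazetteer
        )
        b = generate_notes(
            NoteGeneratorConfig(n_docs=20, seed=3, target_density=0.05), gen_gazetteer
        )
        _, ra = pseudonymize_corpus(a, GoldDetector(a), gen_gazetteer, POLICY)
        _, rb = pseudonymize_corpus(b, GoldDetector(b), gen_gazetteer, POLICY)
        rep_a = replacement_report(ra, a)
        rep_b = replacement_report(rb, b)
        rep_ab = replacement_report(ra + rb, a + b)
        merged = {
            k: va + vb
            for (k, va), vb in zip(
                zip(rep_a["pii_class"], rep_a["count"]), rep_b["count"]
            )
        }
        assert dict(zip(rep_ab["pii_class"], rep_ab["count"])) == merged
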