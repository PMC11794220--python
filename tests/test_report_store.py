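"""Data model, dictionaries and interchange round-trips."""

from datetime import date

import pytest
from pydantic import ValidationError

from icsr_signal import (
    DrugEntry,
    IcsrReport,
    ReactionEntry,
    classify_drug,
    default_drug_classes,
    default_hierarchy,
    expand_hlt,
    generate,
    null_config,
    read_reports,
    write_reports,
)
from icsr_signal.report_store import (
    IcsrParseError,
    IntegrityError,
    SchemaError,
    TermLookupError,
    normalize_ingredient,
    parse_icsr_date,
)

from conftest import make_report


class TestModelInvariants:
    def test_report_requires_drugs_and_reactions(self):
        with pytest.raises(ValidationError, match="drug"):
            IcsrReport(
                report_id="X",
                drugs=[],
                reactions=[ReactionEntry(pt="Rash")],
            )
        with pytest.raises(ValidationError, match="reaction"):
            IcsrReport(
                report_id="X",
                drugs=[DrugEntry(ingredient="nivolumab")],
                reactions=[],
            )

    @pytest.mark.parametrize("age", [-1, 121])
    def test_age_bounds(self, age):
        with pytest.raises(ValidationError):
            make_report("X", age=age)

    def test_drug_interval_ordering(self):
        with pytest.raises(ValidationError, match="after stop_date"):
            DrugEntry(
                ingredient="nivolumab",
                start_date="2021-05-01",
                stop_date="2021-04-01",
            )

    def test_partial_dates_imputed_to_mid_month(self):
        assert parse_icsr_date("2020-01") == (date(2020, 1, 15), True)
        assert parse_icsr_date("2020-01-07") == (date(2020, 1, 7), False)
        entry = DrugEntry(ingredient="nivolumab", start_date="2020-01")
        assert entry.start_date == date(2020, 1, 15)
        assert entry.date_imputed

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  Nivolumab ", "nivolumab"),
            ("Warfarin Sodium", "warfarin"),
            ("Imatinib mesylate", "imatinib"),
            ("mycophenolic  acid", "mycophenolic acid"),
        ],
    )
    def test_ingredient_normalization(self, raw, expected):
        assert normalize_ingredient(raw) == expected


class TestDictionaries:
    def test_classify_checkpoint_inhibitors(self):
        assert classify_drug("nivolumab") == "PD1i"
        assert classify_drug("avelumab") == "PDL1i"
        assert classify_drug("ipilimumab") == "CTLA4i"
        assert classify_drug("tacrolimus") is None

    def test_classes_pairwise_disjoint(self):
        dictionary = default_drug_classes()
        all_members = [ing for c in dictionary.classes.values() for ing in c]
        assert len(all_members) == len(set(all_members))
        # the receptor class has seven distinct antibodies
        assert len(dictionary.members("PD1i")) == 7

    def test_expand_transplant_rejection_hlt(self):
        pts = expand_hlt("Transplant Rejection")
        assert {
            "Kidney transplant rejection",
            "Liver transplant rejection",
            "Heart transplant rejection",
        } <= pts

    def test_expand_unknown_hlt_lists_known_terms(self):
        with pytest.raises(TermLookupError, match="Transplant Rejection"):
            expand_hlt("No such grouping")

    def test_hlt_expansion_covers_all_pts(self):
        hierarchy = default_hierarchy()
        union = set()
        for hlt in hierarchy.all_hlts:
            union |= expand_hlt(hlt, hierarchy)
        assert union == hierarchy.all_pts

    def test_dictionary_csv_round_trip(self, tmp_path):
        hierarchy = default_hierarchy()
        path = tmp_path / "hier.csv"
        hierarchy.to_csv(path)
        back = type(hierarchy).from_csv(path)
        assert back.all_pts == hierarchy.all_pts
        assert back.pts_of("Transplant Rejection") == hierarchy.pts_of(
            "Transplant Rejection"
        )

    def test_lookup_is_case_insensitive(self):
        hierarchy = default_hierarchy()
        assert hierarchy.pts_of("transplant rejection") == hierarchy.pts_of(
            "TRANSPLANT REJECTION"
        )


class TestInterchange:
    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_three_record_round_trip(self, tmp_path, fmt):
        reports = [
            make_report("A", start=date(2020, 1, 1), onset=date(2020, 1, 29)),
            make_report("B", ingredients=("ipilimumab", "tacrolimus"),
                        roles=["suspect", "concomitant"], outcome="fatal"),
            make_report("C", pts=("Diarrhoea",), sex="female"),
        ]
        path = tmp_path / f"x.{fmt}"
        write_reports(reports, path, format=fmt)
        back = read_reports(path, format=fmt)
        assert back == reports

    def test_null_optional_fields_preserved(self, tmp_path):
        report = IcsrReport(
            report_id="N",
            drugs=[DrugEntry(ingredient="nivolumab")],
            reactions=[ReactionEntry(pt="Rash")],
        )
        path = tmp_path / "n.jsonl"
        write_reports([report], path)
        (back,) = read_reports(path)
        assert back.patient_age is None
        assert back.receipt_date is None
        assert back.drugs[0].start_date is None
        assert back == report

    def test_empty_list_yields_header_only_csv(self, tmp_path):
        path = tmp_path / "e.csv"
        write_reports([], path, format="csv")
        assert path.read_text().startswith("report_id,")
        assert read_reports(path, format="csv") == []

    def test_missing_reactions_is_integrity_error_naming_record(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"report_id":"OK","drugs":[{"ingredient":"nivolumab"}],'
            '"reactions":[{"pt":"Rash"}]}\n'
            '{"report_id":"BAD","drugs":[{"ingredient":"nivolumab"}]}\n'
        )
        with pytest.raises(IcsrParseError, match="BAD") as exc_info:
            read_reports(path)
        assert exc_info.value.records[0].line == 2
        reports, malformed = read_reports(path, on_malformed="collect")
        assert [r.report_id for r in reports] == ["OK"]
        assert len(malformed) == 1

    def test_duplicate_report_id_raises(self, tmp_path):
        reports = [make_report("D"), make_report("D")]
        with pytest.raises(IntegrityError, match="duplicate"):
            write_reports(reports, tmp_path / "d.jsonl")
        path = tmp_path / "d2.jsonl"
        write_reports([make_report("D")], path)
        path.write_text(path.read_text() * 2)
        with pytest.raises(IntegrityError, match="duplicate"):
            read_reports(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("report_id,drugs\nA,[]\n")
        with pytest.raises(SchemaError, match="reactions"):
            read_reports(path, format="csv")

    def test_synthetic_file_round_trip_is_byte_identical(self, tmp_path):
        reports, _ = generate(null_config(n_reports=500, seed=7))
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_reports(reports, p1)
        write_reports(read_reports(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_generated_count_matches_parsed_count(self, tmp_path):
        reports, truth = generate(null_config(n_reports=1000, seed=3))
        path = tmp_path / "k.jsonl"
        write_reports(reports, path)
        assert len(read_reports(path)) == truth.n_reports == 1000
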