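"""Parsing, category aggregation, filtering and indicator encoding."""

import numpy as np
import pytest

from somward import ingest
from somward.records import (
    CategoryMap,
    RawDeathRecord,
    UnmappedCodeError,
    age_band,
    is_valid_icd10,
)

TINY_MAP = CategoryMap(
    rules=(
        ("I25", "atherosclerotic_heart_disease"),
        ("C34", "lung_cancer"),
        ("C", "other_cancer"),
        ("J44", "copd"),
    ),
    fallback_policy="other_bucket",
)


def _raw(record_id="r1", conditions=("I251",), underlying="I251", age=70, **kw):
    defaults = dict(
        record_id=record_id,
        data_year=2010,
        age_years=age,
        sex="female",
        race="white",
        education="secondary",
        marital="married",
        resident_status="local",
        place_of_death="home",
        manner="natural",
        underlying_cause=underlying,
        entity_conditions=tuple(conditions),
    )
    defaults.update(kw)
    return RawDeathRecord(**defaults)


CSV_HEADER = (
    "record_id,data_year,age_years,sex,race,education,marital,"
    "resident_status,place_of_death,manner,underlying_cause,conditions"
)


def _write_csv(tmp_path, rows, name="records.csv"):
    path = tmp_path / name
    path.write_text("\n".join([CSV_HEADER] + rows) + "\n")
    return path


class TestIcdValidation:
    @pytest.mark.parametrize("code", ["I25", "I251", "C50", "J449", "A401X"])
    def test_valid_shapes(self, code):
        assert is_valid_icd10(code)

    @pytest.mark.parametrize("code", ["1X9", "i25", "I2", "I251234", ""])
    def test_invalid_shapes(self, code):
        assert not is_valid_icd10(code)


class TestParseMcod:
    def test_parses_valid_rows_in_order(self, tmp_path):
        rows = [
            "r1,2010,70,female,white,secondary,married,local,home,natural,I251,I251 J449",
            "r2,2011,82,male,black,primary,widowed,local,hospital_inpatient,natural,C349,C349",
            "r3,2012,55,male,white,tertiary,divorced,nonlocal_us,home,accident,I251,",
        ]
        report = ingest.ParseReport()
        records = list(ingest.parse_mcod(_write_csv(tmp_path, rows), report=report))
        assert [r.record_id for r in records] == ["r1", "r2", "r3"]
        assert report.n_parsed == 3 and report.n_malformed == 0
        assert records[0].entity_conditions == ("I251", "J449")
        assert records[2].entity_conditions == ()

    def test_malformed_condition_code_skips_row(self, tmp_path):
        rows = [
            "r1,2010,70,female,white,secondary,married,local,home,natural,I251,1X9",
            "r2,2010,70,female,white,secondary,married,local,home,natural,I251,I251",
        ]
        report = ingest.ParseReport()
        records = list(ingest.parse_mcod(_write_csv(tmp_path, rows), report=report))
        assert [r.record_id for r in records] == ["r2"]
        assert report.n_malformed == 1
        assert report.errors[0][0] == 2  # header is line 1

    def test_empty_file_yields_nothing(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        report = ingest.ParseReport()
        assert list(ingest.parse_mcod(path, report=report)) == []
        assert report.n_parsed == 0 and report.n_malformed == 0

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("record_id,age_years\nr1,70\n")
        with pytest.raises(ValueError, match="required columns"):
            list(ingest.parse_mcod(path))

    def test_positional_condition_columns(self, tmp_path):
        schema = ingest.ColumnSchema(
            columns={f: f for f in (
                "record_id", "data_year", "age_years", "sex", "race", "education",
                "marital", "resident_status", "place_of_death", "manner",
                "underlying_cause",
            )},
            conditions_style="positional",
            conditions_prefix="cond",
        )
        path = tmp_path / "pos.csv"
        head = ("record_id,data_year,age_years,sex,race,education,marital,"
                "resident_status,place_of_death,manner,underlying_cause,cond1,cond2")
        path.write_text(
            head + "\nr1,2010,70,female,white,,married,local,home,natural,I251,I251,J449\n"
        )
        (rec,) = list(ingest.parse_mcod(path, schema))
        assert rec.entity_conditions == ("I251", "J449")
        assert rec.education is None


class TestCategoryMap:
    def test_prefix_rule_maps_all_extensions(self):
        assert TINY_MAP.lookup("I251") == "atherosclerotic_heart_disease"
        assert TINY_MAP.lookup("I25") == "atherosclerotic_heart_disease"

    def test_longest_prefix_wins(self):
        assert TINY_MAP.lookup("C349") == "lung_cancer"
        assert TINY_MAP.lookup("C509") == "other_cancer"

    def test_equal_prefixes_resolved_by_rule_order(self):
        cmap = CategoryMap(rules=(("C18", "colorectal"), ("C18", "gi")))
        assert cmap.lookup("C189") == "colorectal"

    def test_fallback_other_bucket(self):
        assert TINY_MAP.lookup("Z99") == "other"
        assert "other" in TINY_MAP.category_vocabulary

    def test_fallback_error_raises(self):
        strict = CategoryMap(rules=(("I25", "ahd"),), fallback_policy="error")
        with pytest.raises(UnmappedCodeError):
            strict.lookup("Z99")

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("prefix,label\nI25,ahd\nC,cancer\n")
        cmap = CategoryMap.from_csv(path)
        assert cmap.lookup("I2510") == "ahd"
        assert cmap.category_vocabulary == ("ahd", "cancer", "other")


class TestCodeRecord:
    def test_duplicate_categories_count_once(self):
        # I251 and I25 both map to the same category; C349 differs
        rec = ingest.code_record(_raw(conditions=("I251", "I25", "C349")), TINY_MAP)
        assert rec.categories == {"atherosclerotic_heart_disease", "lung_cancer"}
        assert rec.multimorbid == 1

    def test_single_category_not_multimorbid(self):
        rec = ingest.code_record(_raw(conditions=("I251", "I259")), TINY_MAP)
        assert rec.categories == {"atherosclerotic_heart_disease"}
        assert rec.multimorbid == 0

    def test_empty_conditions_unusable(self):
        rec = ingest.code_record(_raw(conditions=()), TINY_MAP)
        assert rec.categories == frozenset()
        assert rec.multimorbid == 0
        assert not rec.usable

    def test_underlying_mapped_separately_not_added(self):
        rec = ingest.code_record(
            _raw(conditions=("C349",), underlying="I251"), TINY_MAP
        )
        assert rec.underlying_category == "atherosclerotic_heart_disease"
        assert "atherosclerotic_heart_disease" not in rec.categories

    @pytest.mark.parametrize(
        "age,band", [(3, "<18"), (18, "18-40"), (40, "18-40"), (41, "41-64"),
                     (64, "41-64"), (65, "65-84"), (85, "85+"), (None, None)]
    )
    def test_age_bands(self, age, band):
        assert age_band(age) == band


class TestFilterAndMatrix:
    def test_filter_bookkeeping(self):
        coded = [
            ingest.code_record(_raw(record_id=f"r{i}", conditions=c), TINY_MAP)
            for i, c in enumerate([("I251",), (), ("C349", "J440"), ()])
        ]
        usable, omitted = ingest.filter_usable(coded)
        assert len(usable) == 2 and omitted == 2
        assert len(usable) + omitted == len(coded)

    def test_all_empty(self):
        coded = [ingest.code_record(_raw(conditions=()), TINY_MAP)]
        usable, omitted = ingest.filter_usable(coded)
        assert usable == [] and omitted == 1

    def test_indicator_rows_match_category_sets(self):
        vocab = ("atherosclerotic_heart_disease", "lung_cancer", "copd", "other")
        coded = [
            ingest.code_record(_raw(conditions=("I251",)), TINY_MAP),
            ingest.code_record(_raw(conditions=("I251", "J449")), TINY_MAP),
        ]
        X = ingest.build_indicator_matrix(coded, vocab)
        assert X.tolist() == [[1, 0, 0, 0], [1, 0, 1, 0]]
        assert X[1].sum() == 2 == len(coded[1].categories)

    def test_category_outside_vocab_raises(self):
        coded = [ingest.code_record(_raw(conditions=("Z991",)), TINY_MAP)]
        with pytest.raises(ValueError, match="other"):
            ingest.build_indicator_matrix(coded, vocab=("lung_cancer",))

    def test_multimorbid_equals_rowsum_threshold(self, small_population, demo_map):
        _, _, coded = small_population
        usable, _ = ingest.filter_usable(coded)
        X = ingest.build_indicator_matrix(usable, demo_map.category_vocabulary)
        mm = np.array([r.multimorbid for r in usable])
        assert np.array_equal(mm, (X.sum(axis=1) >= 2).astype(int))

    def test_coded_csv_round_trip(self, tmp_path, small_population):
        _, _, coded = small_population
        usable, _ = ingest.filter_usable(coded[:200])
        path = tmp_path / "coded.csv"
        ingest.write_coded_csv(usable, path)
        back = ingest.read_coded_csv(path)
        assert len(back) == len(usable)
        for a, b in zip(usable, back):
            assert a.categories == b.categories
            assert a.raw == b.raw
            assert a.multimorbid == b.multimorbid


class TestRoundTripInvariant:
    def test_parse_code_filter_conserves_counts(self, tmp_path):
        rows = [
            "r1,2010,70,female,white,,married,local,home,natural,I251,I251 J449",
            "r2,2010,70,female,white,,married,local,home,natural,I251,1X9",  # malformed
            "r3,2010,70,female,white,,married,local,home,natural,I251,",  # empty
            "r4,2010,70,female,white,,married,local,home,natural,C349,C349",
        ]
        report = ingest.ParseReport()
        parsed = list(ingest.parse_mcod(_write_csv(tmp_path, rows), report=report))
        coded = [ingest.code_record(r, TINY_MAP) for r in parsed]
        usable, omitted = ingest.filter_usable(coded)
        assert report.n_parsed + report.n_malformed == len(rows)
        assert len(usable) + omitted == report.n_parsed
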