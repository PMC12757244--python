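"""Report model, FAERS dialect reader, deduplication and classification."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import faerspv as f
from faerspv.faers_core import (
    CLASS_EXPOSED_CASE,
    CLASS_NOT_CLASSIFIABLE,
    CLASS_UNEXPOSED_CASE,
    CLASS_UNEXPOSED_NONCASE,
    CLASSES,
    load_synonym_map,
    standardize_drug_name,
)

from conftest import make_report


def drug(name, role="PS", **kw):
    return f.DrugEntry(name_raw=name, name_std=name, role=role, **kw)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


class TestDeduplicate:
    def test_most_recent_receipt_date_wins(self):
        versions = [
            make_report(5, 1, (2020, 1, 1)),
            make_report(4, 1, (2021, 6, 1)),
        ]
        survivors = f.deduplicate(versions)
        assert [r.primary_id for r in survivors] == [4]

    def test_higher_primary_id_breaks_date_ties(self):
        versions = [
            make_report(4, 1, (2021, 6, 1)),
            make_report(9, 1, (2021, 6, 1)),
        ]
        assert f.deduplicate(versions)[0].primary_id == 9

    def test_distinct_cases_pass_through(self):
        reports = [make_report(i, i, (2020, 1, i + 1)) for i in range(5)]
        assert f.deduplicate(reports) == sorted(
            reports, key=lambda r: r.case_id
        )

    def test_duplicate_primary_id_is_fatal(self):
        reports = [make_report(7, 1, (2020, 1, 1)),
                   make_report(7, 2, (2020, 1, 2))]
        with pytest.raises(ValueError, match="primary_id"):
            f.deduplicate(reports)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 8),  # case_id
                st.dates(dt.date(2015, 1, 1), dt.date(2024, 1, 1)),
            ),
            min_size=1,
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_brute_force_argmax_oracle(self, rows):
        reports = [
            make_report(pid, cid, date)
            for pid, (cid, date) in enumerate(rows)
        ]
        survivors = {r.primary_id for r in f.deduplicate(reports)}
        # oracle: group by case and take the (date, id) argmax directly
        expected = set()
        for cid in {r.case_id for r in reports}:
            group = [r for r in reports if r.case_id == cid]
            expected.add(
                max(group, key=lambda r: (r.fda_receipt_date, r.primary_id))
                .primary_id
            )
        assert survivors == expected

    def test_idempotent(self, synth_dataset):
        reports, _ = synth_dataset
        assert f.deduplicate(reports) == reports


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


class TestClassify:
    def test_ps_target_with_event_is_exposed_case(self, event):
        r = make_report(1, 1, (2020, 1, 1), drugs=[drug("denosumab")],
                        events=["Osteonecrosis of jaw"])
        assert f.classify_report(r, f.ExposureSpec("denosumab"), event) == \
            CLASS_EXPOSED_CASE

    def test_concomitant_role_does_not_satisfy_ps_requirement(self, event):
        r = make_report(1, 1, (2020, 1, 1), drugs=[drug("denosumab", "C")],
                        events=["Osteonecrosis of jaw"])
        assert f.classify_report(r, f.ExposureSpec("denosumab"), event) == \
            CLASS_UNEXPOSED_CASE
        spec_any = f.ExposureSpec("denosumab", required_role="any")
        assert f.classify_report(r, spec_any, event) == CLASS_EXPOSED_CASE

    def test_missing_co_drug_makes_report_unexposed(self, event):
        r = make_report(1, 1, (2020, 1, 1), drugs=[drug("denosumab")],
                        events=["Nausea"])
        spec = f.ExposureSpec("denosumab",
                              co_drugs=frozenset({"zoledronic acid"}))
        assert f.classify_report(r, spec, event) == CLASS_UNEXPOSED_NONCASE

    def test_missing_filter_field_is_not_classifiable(self, event):
        r = make_report(1, 1, (2020, 1, 1), drugs=[drug("denosumab")],
                        events=["Nausea"], sex=None)
        spec = f.ExposureSpec("denosumab", sex="male")
        assert f.classify_report(r, spec, event) == CLASS_NOT_CLASSIFIABLE
        # but a non-target report with missing sex is plain unexposed
        r2 = make_report(2, 2, (2020, 1, 1), drugs=[drug("aspirin")],
                         events=["Nausea"], sex=None)
        assert f.classify_report(r2, spec, event) == CLASS_UNEXPOSED_NONCASE

    def test_event_matching_ignores_case_and_whitespace(self):
        ev = f.EventLabel("Osteonecrosis of jaw")
        r = make_report(1, 1, (2020, 1, 1), drugs=[drug("denosumab")],
                        events=["  OSTEONECROSIS   OF JAW "])
        assert r.has_event(ev)

    @pytest.mark.parametrize("spec_kw", [
        {},
        {"sex": "male"},
        {"age_min": 65.0},
        {"regimen_filter": "q4w_120mg"},
        {"co_drugs": frozenset({"zoledronic acid"})},
    ])
    def test_classes_partition_dataset(self, synth_dataset, event, spec_kw):
        reports, _ = synth_dataset
        spec = f.ExposureSpec("denosumab", **spec_kw)
        counts = {c: 0 for c in CLASSES}
        for r in reports:
            counts[f.classify_report(r, spec, event)] += 1
        assert sum(counts.values()) == len(reports)


# ---------------------------------------------------------------------------
# regimen / age parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("text,expected", [
    ("120 MG, Q4W", "q4w_120mg"),
    ("120mg every 4 weeks", "q4w_120mg"),
    ("60 mg Q6M", "q6m_60mg"),
    ("60MG", "q6m_60mg"),
    ("70 mg weekly", "other"),
    ("60 mg then 120 mg", "other"),
    ("", None),
    (None, None),
])
def test_regimen_parsing(text, expected):
    assert f.parse_regimen(text) == expected


@pytest.mark.parametrize("age,unit,expected", [
    (70, "YR", 70.0),
    (7, "DEC", 70.0),
    (18, "MON", 1.5),
    (730.5, "DY", 2.0),
    (150, "YR", None),
    (-3, "YR", None),
    ("garbage", "YR", None),
    (70, "FOO", None),
])
def test_age_harmonization(age, unit, expected):
    got = f.harmonize_age(age, unit)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------


def _write(tmp_path, name, header, rows, sep="|"):
    p = tmp_path / f"{name}.txt"
    p.write_text("\n".join([sep.join(header)] +
                           [sep.join(map(str, r)) for r in rows]) + "\n")
    return p


class TestReader:
    def test_join_conservation(self, tmp_path):
        demo = _write(tmp_path, "demo",
                      ["primaryid", "caseid", "fda_dt"],
                      [(1, 1, "20200101"), (2, 2, "20200102"),
                       (3, 3, "20200103")])
        drug_p = _write(tmp_path, "drug",
                        ["primaryid", "drug_seq", "role_cod", "drugname"],
                        [(1, 1, "PS", "denosumab"), (1, 2, "C", "aspirin"),
                         (2, 1, "PS", "metformin"), (3, 1, "PS", "aspirin"),
                         (3, 2, "SS", "ibuprofen")])
        reports, load = f.read_faers_tables({"demo": demo, "drug": drug_p})
        assert len(reports) == 3
        assert sum(len(r.drugs) for r in reports) == 5
        assert load.total_orphans() == 0

    def test_orphan_child_rows_counted(self, tmp_path):
        demo = _write(tmp_path, "demo", ["primaryid", "caseid", "fda_dt"],
                      [(1, 1, "20200101")])
        reac = _write(tmp_path, "reac", ["primaryid", "pt"],
                      [(1, "Nausea"), (99, "Nausea")])
        reports, load = f.read_faers_tables({"demo": demo, "reac": reac})
        assert len(reports) == 1
        assert load.orphans == {"reac": 1}

    def test_dollar_dialect_autodetected(self, tmp_path):
        demo = _write(tmp_path, "demo",
                      ["primaryid", "caseid", "fda_dt", "sex"],
                      [(1, 1, "20200101", "F")], sep="$")
        reports, _ = f.read_faers_tables({"demo": demo})
        assert reports[0].sex == "female"

    def test_missing_demo_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            f.read_faers_tables({"drug": tmp_path / "drug.txt"})

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        demo = _write(tmp_path, "demo", ["primaryid", "caseid", "fda_dt"],
                      [(1, 1, "20200101"), ("oops", 2, "20200101"),
                       (3, 3, "2020")])
        reports, load = f.read_faers_tables({"demo": demo})
        assert len(reports) == 1
        assert load.malformed == {"demo": 2}

    def test_synonym_map_standardizes_names(self, tmp_path):
        smap_path = tmp_path / "syn.txt"
        smap_path.write_text("PROLIA|denosumab\nXGEVA\tdenosumab\n")
        smap = load_synonym_map(smap_path)
        assert standardize_drug_name("  prolia ", smap) == "denosumab"
        assert standardize_drug_name("Xgeva", smap) == "denosumab"
        assert standardize_drug_name("aspirin", smap) == "aspirin"
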