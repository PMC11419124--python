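import math

import numpy as np
import pytest

from affinity_forge.curation import (
    CurationConfig,
    UnclearUnitsError,
    collapse_within_document,
    filter_extremes,
    remove_author_overlap,
    remove_cited_duplicates,
    remove_dummy_targets,
    run_cascade,
    standardize_activity,
)
from conftest import record, records_from_frame
from oracles import brute_force_dedup_stages


class TestStandardizeActivity:
    @pytest.mark.parametrize(
        "value,units,rtype,mtype,p",
        [
            (1.0, "nM", "Ki", "pKi", 9.0),
            (1000.0, "nM", "IC50", "pIC50", 6.0),
            (1.0, "uM", "IC50", "pIC50", 6.0),
            (1.0, "µM", "Kd", "pKd", 6.0),  # micro sign U+00B5
            (1.0, "μM", "Kd", "pKd", 6.0),  # Greek mu U+03BC
            (1.0, "M", "Kd", "pKd", 0.0),
            (1.0, "fM", "Ki", "pKi", 15.0),
            (10.0, "mM", "Ki", "pKi", 2.0),
            (1.0, "NM", "Ki", "pKi", 9.0),  # case-insensitive
        ],
    )
    def test_conversion_to_p_scale(self, value, units, rtype, mtype, p):
        got_mtype, got_p = standardize_activity(value, units, rtype)
        assert got_mtype == mtype
        assert got_p == pytest.approx(p, abs=1e-12)

    def test_unclear_units_flagged(self):
        with pytest.raises(UnclearUnitsError, match="mg/mL"):
            standardize_activity(5.0, "mg/mL", "Ki")

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            standardize_activity(-1.0, "nM", "Ki")
        with pytest.raises(ValueError):
            standardize_activity(0.0, "nM", "Ki")
        with pytest.raises(ValueError, match="EC50"):
            standardize_activity(1.0, "nM", "EC50")


class TestDummyTargets:
    def test_default_dummy_removed(self):
        records = [record(rid=f"R{i}", target="CHEMBL1") for i in range(4)]
        records.append(record(rid="R5", target="CHEMBL612545"))
        assert len(remove_dummy_targets(records)) == 4

    def test_empty_dummy_set_is_identity(self):
        records = [record(rid=f"R{i}") for i in range(3)]
        assert remove_dummy_targets(records, dummy_ids=()) == records

    def test_all_dummy_yields_empty(self):
        records = [record(rid=f"R{i}", target="CHEMBL612545") for i in range(5)]
        assert remove_dummy_targets(records) == []


class TestFilterExtremes:
    def test_boundaries_are_strict_as_printed(self):
        # 11 mM (p ≈ 1.96) removed; exactly 10 mM (p = 2) and 1 fM (p = 15) kept
        eleven_mm = record(rid="a", pvalue=-math.log10(11e-3))
        ten_mm = record(rid="b", pvalue=2.0)
        one_fm = record(rid="c", pvalue=15.0)
        one_pm = record(rid="d", pvalue=12.0)
        too_tight = record(rid="e", pvalue=15.000001)
        kept = filter_extremes([eleven_mm, ten_mm, one_fm, one_pm, too_tight])
        assert [r.record_id for r in kept] == ["b", "c", "d"]


class TestWithinDocumentCollapse:
    def test_highest_p_value_survives(self):
        low = record(rid="lo", pvalue=6.1)
        high = record(rid="hi", pvalue=7.3, index=1)
        kept = collapse_within_document([low, high])
        assert [r.record_id for r in kept] == ["hi"]

    def test_singleton_group_unchanged(self):
        only = record(rid="solo", pvalue=5.0)
        assert collapse_within_document([only]) == [only]

    def test_tie_keeps_exactly_one_deterministically(self):
        a = record(rid="a", pvalue=7.0, index=0)
        b = record(rid="b", pvalue=7.0, index=1)
        kept = collapse_within_document([a, b])
        assert [r.record_id for r in kept] == ["a"]

    def test_different_documents_not_collapsed(self):
        a = record(rid="a", doc="DOC1", pvalue=6.0)
        b = record(rid="b", doc="DOC2", pvalue=7.0, index=1)
        assert len(collapse_within_document([a, b])) == 2


class TestCitationDedup:
    def test_identical_value_keeps_earliest_year(self):
        a = record(rid="a", doc="A", year=2010, pvalue=7.30)
        b = record(rid="b", doc="B", year=2015, pvalue=7.30, index=1)
        kept = remove_cited_duplicates([a, b])
        assert [r.record_id for r in kept] == ["a"]

    def test_nearby_but_distinct_values_both_kept(self):
        a = record(rid="a", doc="A", year=2010, pvalue=7.30)
        b = record(rid="b", doc="B", year=2015, pvalue=7.31, index=1)
        assert len(remove_cited_duplicates([a, b])) == 2

    def test_three_document_chain_keeps_original(self):
        docs = [("A", 2010), ("B", 2012), ("C", 2015)]
        records = [
            record(rid=d, doc=d, year=y, pvalue=8.2, index=i)
            for i, (d, y) in enumerate(docs)
        ]
        kept = remove_cited_duplicates(records)
        assert [r.record_id for r in kept] == ["A"]

    def test_missing_year_never_kept_as_original(self):
        dated = record(rid="dated", doc="A", year=2018, pvalue=6.5)
        undated = record(rid="undated", doc="B", year=None, pvalue=6.5, index=1)
        kept = remove_cited_duplicates([dated, undated])
        assert [r.record_id for r in kept] == ["dated"]


class TestAuthorOverlap:
    def test_shared_author_collapses_to_earliest(self):
        a = record(rid="a", doc="A", year=2015, authors=("x x", "y y"), pvalue=6.0)
        b = record(rid="b", doc="B", year=2018, authors=("y y", "z z"), pvalue=7.0, index=1)
        kept = remove_author_overlap([a, b])
        assert [r.record_id for r in kept] == ["a"]

    def test_author_normalization_case_and_whitespace(self):
        a = record(rid="a", doc="A", year=2015, authors=("Smith  J",), pvalue=6.0)
        b = record(rid="b", doc="B", year=2018, authors=("smith j",), pvalue=7.0, index=1)
        assert len(remove_author_overlap([a, b])) == 1

    def test_disjoint_author_sets_both_kept(self):
        a = record(rid="a", doc="A", authors=("x x",), pvalue=6.0)
        b = record(rid="b", doc="B", authors=("z z",), pvalue=7.0, index=1)
        assert len(remove_author_overlap([a, b])) == 2

    def test_transitive_chain_is_one_component(self):
        a = record(rid="a", doc="A", year=2010, authors=("p p", "q q"), pvalue=6.0)
        b = record(rid="b", doc="B", year=2012, authors=("q q", "r r"), pvalue=7.0, index=1)
        c = record(rid="c", doc="C", year=2014, authors=("r r", "s s"), pvalue=8.0, index=2)
        kept = remove_author_overlap([a, b, c])
        assert [r.record_id for r in kept] == ["a"]

    def test_empty_author_list_forms_own_component(self):
        anon1 = record(rid="a", doc="A", authors=(), pvalue=6.0)
        anon2 = record(rid="b", doc="B", authors=(), pvalue=7.0, index=1)
        assert len(remove_author_overlap([anon1, anon2])) == 2


class TestRunCascade:
    def test_empty_input_reports_all_zeros(self):
        measurements, report = run_cascade([])
        assert measurements == []
        assert report.counts() == [(0, 0)] * 5

    def test_fixture_ground_truth_reproduced(self, curation_fixture):
        _, frame, truth = curation_fixture
        _, report = run_cascade(records_from_frame(frame))
        assert report.counts() == [
            (d["records_in"], d["records_out"]) for d in truth.stage_counts
        ]
        assert sorted(report.surviving_ids) == truth.surviving_ids

    def test_clean_fixture_passes_through(self):
        from affinity_forge.fixtures import FixtureSpec, generate_curation_fixture

        spec = FixtureSpec(
            n_records=40, seed=5, n_dummy_targets=0, n_extreme_high=0, n_extreme_low=0,
            n_unclear_units=0, n_within_doc_duplicate_groups=0, n_citation_chains=0,
            n_author_overlap_components=0,
        )
        frame, _ = generate_curation_fixture(spec)
        _, report = run_cascade(records_from_frame(frame))
        assert all(s.records_in == s.records_out for s in report.stages)

    def test_counts_monotone_and_chained(self, curation_fixture):
        _, frame, _ = curation_fixture
        _, report = run_cascade(records_from_frame(frame))
        for stage in report.stages:
            assert stage.records_out <= stage.records_in
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert prev.records_out == nxt.records_in

    def test_idempotence_on_surviving_records(self, curation_fixture):
        _, frame, _ = curation_fixture
        records = records_from_frame(frame)
        _, report = run_cascade(records)
        survivors = [r for r in records if r.record_id in set(report.surviving_ids)]
        _, rerun = run_cascade(survivors)
        assert all(s.records_in == s.records_out for s in rerun.stages)
        assert sorted(rerun.surviving_ids) == sorted(report.surviving_ids)

    def test_row_permutation_never_changes_counts(self, curation_fixture):
        _, frame, _ = curation_fixture
        _, base = run_cascade(records_from_frame(frame))
        rng = np.random.default_rng(0)
        shuffled = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
        _, permuted = run_cascade(records_from_frame(shuffled))
        assert permuted.counts() == base.counts()

    def test_dedup_stages_match_brute_force_oracle(self):
        from affinity_forge.fixtures import FixtureSpec, generate_curation_fixture

        spec = FixtureSpec(
            n_records=45, seed=13, n_dummy_targets=0, n_extreme_high=0, n_extreme_low=0,
            n_unclear_units=0, n_within_doc_duplicate_groups=5, n_citation_chains=5,
            n_author_overlap_components=5, group_size=3,
        )
        frame, _ = generate_curation_fixture(spec)
        records = records_from_frame(frame)
        _, report = run_cascade(records)

        from affinity_forge.curation import standardize_activity
        from dataclasses import replace

        standardized = []
        for r in records:
            mtype, p = standardize_activity(r.value, r.units, r.rtype)
            standardized.append(replace(r, mtype=mtype, pvalue=p))
        oracle_ids = sorted(r.record_id for r in brute_force_dedup_stages(standardized))
        assert sorted(report.surviving_ids) == oracle_ids

    def test_drop_reasons_are_labelled(self):
        records = [
            record(rid="dummy", target="CHEMBL612545"),
            record(rid="odd", units="mg/mL", index=1),
            record(rid="extreme", value=11.0, units="mM", index=2),
            record(rid="ok", index=3),
        ]
        _, report = run_cascade(records, CurationConfig())
        reasons = {k: v for s in report.stages for k, v in s.drop_reasons.items()}
        assert reasons == {"dummy_target": 1, "unclear_units": 1, "extreme_value": 1}
        assert report.surviving_ids == ["ok"]
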