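import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termscout.corpus_model import Corpus, RelatednessEdge, VideoRecord
from termscout.expansion_eval import dedupe_against_core
from termscout.network_eval import (
    DegreeRecord,
    NetworkEvalError,
    degree_metrics,
    exclusion_filter,
    precision_at,
    summarize,
    threshold_curve,
)
from termscout.synthetic_corpus import GeneratorConfig, generate

from reference_counts import (
    N_RETAINED,
    TABLE_CURVE_EXPECTED,
    TABLE_SUMMARY,
    degree_fixture,
)


def _coded_sample(n_non_english=28, n_duplicate=8, n_missing=1, n_total=150):
    videos = [VideoRecord("core0", set_label="core", title="colonoscopy")]
    i = 0
    for _ in range(n_non_english):
        videos.append(VideoRecord(f"x{i}", set_label="neighbor:t", language="es",
                                  relevance="irrelevant"))
        i += 1
    for _ in range(n_duplicate):
        videos.append(VideoRecord(f"x{i}", set_label="neighbor:t", language="en",
                                  relevance="irrelevant", exclusion="duplicate_of_core"))
        i += 1
    for _ in range(n_missing):
        videos.append(VideoRecord(f"x{i}", set_label="neighbor:t", language="en",
                                  relevance="irrelevant", exclusion="missing_metadata"))
        i += 1
    for _ in range(n_total - n_non_english - n_duplicate - n_missing):
        videos.append(VideoRecord(f"x{i}", set_label="neighbor:t", language="en",
                                  relevance="relevant"))
        i += 1
    return Corpus(videos=videos, focal_term="colonoscopy")


class TestExclusionFilter:
    def test_reference_arithmetic(self):
        corpus = _coded_sample()
        retained, tally = exclusion_filter(corpus)
        assert len(retained) == N_RETAINED == 113
        assert tally["non_english"] == 28
        assert tally["duplicate_of_core"] == 8
        assert tally["missing_metadata"] == 1

    def test_no_exclusions_identity(self):
        corpus = _coded_sample(0, 0, 0)
        retained, tally = exclusion_filter(corpus)
        assert len(retained) == 150
        assert not tally

    def test_all_excluded_warns_not_errors(self, caplog):
        videos = [VideoRecord("c", set_label="core")] + [
            VideoRecord(f"n{i}", set_label="neighbor:t", language="fr") for i in range(3)
        ]
        retained, tally = exclusion_filter(Corpus(videos=videos))
        assert retained == []
        assert tally["non_english"] == 3

    def test_und_trusted_by_default(self):
        videos = [VideoRecord("n0", set_label="neighbor:t", language="und")]
        retained, _ = exclusion_filter(Corpus(videos=videos))
        assert len(retained) == 1
        retained, tally = exclusion_filter(
            Corpus(videos=videos), treat_und_as_non_english=True
        )
        assert retained == []
        assert tally["non_english"] == 1

    def test_en_variants_kept(self):
        videos = [VideoRecord("n0", set_label="neighbor:t", language="en-GB")]
        retained, _ = exclusion_filter(Corpus(videos=videos))
        assert len(retained) == 1


class TestDegreeMetrics:
    def test_no_edges_all_zero(self):
        recs = degree_metrics([], {"c1"}, {"n1", "n2"})
        assert all(r.total_degree == 0 for r in recs)
        assert len(recs) == 2

    def test_hand_count(self):
        edges = [RelatednessEdge("core1", "new1"), RelatednessEdge("new1", "core2")]
        [rec] = degree_metrics(edges, {"core1", "core2"}, {"new1"})
        assert (rec.indegree, rec.outdegree, rec.total_degree) == (1, 1, 2)

    def test_total_is_sum(self):
        rng = random.Random(0)
        core = {f"c{i}" for i in range(10)}
        new = {f"n{i}" for i in range(10)}
        edges = [
            RelatednessEdge(rng.choice(sorted(core | new)), rng.choice(sorted(core | new)))
            for _ in range(200)
        ]
        edges = [e for e in edges if e.source_id != e.target_id]
        for rec in degree_metrics(edges, core, new):
            assert rec.total_degree == rec.indegree + rec.outdegree

    def test_duplicate_edges_count_once(self):
        edges = [RelatednessEdge("c", "n")] * 5
        [rec] = degree_metrics(edges, {"c"}, {"n"})
        assert rec.total_degree == 1

    def test_non_core_edges_ignored(self):
        edges = [RelatednessEdge("n1", "n2"), RelatednessEdge("ext", "n1")]
        recs = degree_metrics(edges, {"c"}, {"n1", "n2"})
        assert all(r.total_degree == 0 for r in recs)

    def test_overlap_rejected(self):
        with pytest.raises(NetworkEvalError):
            degree_metrics([], {"a", "b"}, {"b", "c"})


class TestThresholdCurve:
    def test_reference_curve_cells(self):
        records, relevance = degree_fixture()
        curve = threshold_curve(records, relevance)
        assert curve.total_relevant == 37
        assert len(curve.rows) == len(TABLE_CURVE_EXPECTED)
        for row in curve.rows:
            exp = TABLE_CURVE_EXPECTED[row.degree]
            got = (row.cum_videos, row.cum_relevant, row.precision_pct,
                   row.recall_pct, row.f1_pct)
            assert got == exp, f"degree {row.degree}: {got} != {exp}"

    def test_single_degree_all_relevant(self):
        recs = [DegreeRecord(f"v{i}", 0, 0) for i in range(10)]
        curve = threshold_curve(recs, {r.video_id: True for r in recs})
        [row] = curve.rows
        assert (row.precision_pct, row.recall_pct, row.f1_pct) == (100, 100.0, 100.0)

    def test_toy_enumeration_oracle(self):
        # degrees {2: 1 video 1 rel, 1: 2 videos 1 rel, 0: 2 videos 0 rel}
        recs = [DegreeRecord("a", 2, 0), DegreeRecord("b", 1, 0),
                DegreeRecord("c", 1, 0), DegreeRecord("d", 0, 0), DegreeRecord("e", 0, 0)]
        rel = {"a": True, "b": True, "c": False, "d": False, "e": False}
        curve = threshold_curve(recs, rel)
        at1 = precision_at(curve, 1)
        assert (at1["n"], at1["n_relevant"]) == (3, 2)
        assert at1["precision"] == pytest.approx(2 / 3)
        assert at1["recall"] == pytest.approx(1.0)
        assert at1["f1_pct"] == 80.0

    def test_zero_relevant_rejected(self):
        recs = [DegreeRecord("a", 1, 0)]
        with pytest.raises(NetworkEvalError):
            threshold_curve(recs, {"a": False})

    def test_missing_relevance_rejected(self):
        with pytest.raises(NetworkEvalError):
            threshold_curve([DegreeRecord("a", 1, 0)], {})

    def test_conservation_and_monotonicity(self):
        records, relevance = degree_fixture()
        curve = threshold_curve(records, relevance)
        assert sum(r.n_relevant for r in curve.rows) == curve.total_relevant
        cum_v = [r.cum_videos for r in curve.rows]
        cum_r = [r.cum_relevant for r in curve.rows]
        rec = [r.cum_recall for r in curve.rows]
        assert cum_v == sorted(cum_v)
        assert cum_r == sorted(cum_r)
        assert rec == sorted(rec)
        assert curve.rows[-1].cum_recall == pytest.approx(1.0)
        for r in curve.rows:
            lo, hi = sorted((r.cum_precision, r.cum_recall))
            assert lo - 1e-12 <= r.cum_f1 <= hi + 1e-12

    def test_loosest_row_equals_base_rate(self):
        records, relevance = degree_fixture()
        curve = threshold_curve(records, relevance)
        last = curve.rows[-1]
        assert last.cum_precision == pytest.approx(37 / 113)
        assert last.cum_recall == pytest.approx(1.0)

    def test_invariant_to_record_order(self):
        records, relevance = degree_fixture()
        shuffled = records[:]
        random.Random(5).shuffle(shuffled)
        assert threshold_curve(records, relevance).rows == threshold_curve(shuffled, relevance).rows

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.booleans()), min_size=1, max_size=40
        ).filter(lambda rows: any(rel for _, rel in rows))
    )
    def test_curve_invariants_property(self, rows):
        recs = [DegreeRecord(f"v{i}", deg, 0) for i, (deg, _) in enumerate(rows)]
        rel = {f"v{i}": r for i, (_, r) in enumerate(rows)}
        curve = threshold_curve(recs, rel)
        degs = [r.degree for r in curve.rows]
        assert degs == sorted(degs, reverse=True)
        assert curve.rows[-1].cum_recall == pytest.approx(1.0)
        assert curve.rows[-1].cum_videos == len(rows)
        assert sum(r.n_relevant for r in curve.rows) == curve.total_relevant
        for r in curve.rows:
            assert 0.0 <= r.cum_precision <= 1.0
            assert 0.0 <= r.cum_recall <= 1.0
            lo, hi = sorted((r.cum_precision, r.cum_recall))
            assert lo - 1e-12 <= r.cum_f1 <= hi + 1e-12


class TestPrecisionAt:
    def test_reference_degree3(self):
        records, relevance = degree_fixture()
        stats = precision_at(threshold_curve(records, relevance), 3)
        assert (stats["n"], stats["n_relevant"]) == (32, 28)
        assert stats["precision_pct"] == 88

    def test_degree0_full_recall(self):
        records, relevance = degree_fixture()
        stats = precision_at(threshold_curve(records, relevance), 0)
        assert stats["n"] == 113
        assert stats["recall_pct"] == 100.0

    def test_above_degree7_all_100(self):
        records, relevance = degree_fixture()
        curve = threshold_curve(records, relevance)
        pcts = {r.precision_pct for r in curve.rows if r.degree > 7}
        assert pcts == {100}

    def test_unobserved_threshold_resolves_down(self):
        # degree 8 unobserved in the reference table: resolves to degree 9 row
        records, relevance = degree_fixture()
        stats = precision_at(threshold_curve(records, relevance), 8)
        assert stats["degree"] == 9
        assert stats["n"] == 23

    def test_above_max_rejected(self):
        records, relevance = degree_fixture()
        with pytest.raises(NetworkEvalError):
            precision_at(threshold_curve(records, relevance), 1000)


class TestSummarize:
    @pytest.mark.parametrize("term", sorted(TABLE_SUMMARY))
    def test_reference_summary_ratios(self, term):
        n_coded, n_rel, n_b, n_ab, exp_p, exp_r = TABLE_SUMMARY[term]
        records, relevance = [], {}
        i = 0

        def add(n, degree, rel):
            nonlocal i
            for _ in range(n):
                vid = f"s{i}"
                i += 1
                records.append(DegreeRecord(vid, degree, 0))
                relevance[vid] = rel

        add(n_ab, 1, True)              # relevant with degree >= 1
        add(n_b - n_ab, 1, False)       # irrelevant with degree >= 1
        add(n_rel - n_ab, 0, True)      # relevant, unconnected
        add(n_coded - n_rel - (n_b - n_ab), 0, False)
        row = summarize(term, n_coded, records, relevance)
        assert row.precision_pct == exp_p
        assert row.recall_pct == exp_r

    def test_degenerate_rejected(self):
        with pytest.raises(NetworkEvalError):
            summarize("t", 1, [DegreeRecord("a", 0, 0)], {"a": True})


class TestSyntheticPrecisionGain:
    def test_degree_filter_beats_base_rate(self):
        wins = 0
        for seed in range(10):
            cfg = GeneratorConfig(
                seed=seed, n_core=40, n_expansion_per_term=25,
                p_relevant=0.4, p_edge_rel=0.3, p_edge_irr=0.01,
            )
            corpus = dedupe_against_core(generate(cfg))
            retained, _ = exclusion_filter(corpus)
            relevance = {v.video_id: v.relevance == "relevant" for v in retained}
            records = degree_metrics(corpus.edges, corpus.core_ids, set(relevance))
            curve = threshold_curve(records, relevance)
            at1 = precision_at(curve, 1)
            at0 = precision_at(curve, 0)
            wins += at1["precision"] > at0["precision"]
        assert wins >= 9
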