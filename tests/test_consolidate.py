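"""Merging, filtering, categorization and the full refinement pipeline."""

import pytest

from txrefine.annotation_io import AnnotationSet
from txrefine.consolidate import (
    CategorizedSets,
    RefineConfig,
    SampleAnnotation,
    SupportRecord,
    categorize_vs_reference,
    filter_new_genes,
    filter_supported,
    merge_samples,
    refine_annotation,
    remove_fusions,
    sample_specificity,
)

from .conftest import make_set, make_tx


def sample(sid, *txs, sex="male", strain="ps94"):
    return SampleAnnotation(sid, sex, strain, make_set(*txs))


FOUR_SAMPLES = (
    ("s1", "male", "ps94"),
    ("s2", "female", "ps94"),
    ("s3", "male", "ps88"),
    ("s4", "female", "ps88"),
)


class TestMerge:
    def test_identical_chain_merges_across_samples(self):
        t1 = make_tx("tA", [(0, 100), (200, 300)], cov=3.0)
        t2 = make_tx("tA", [(0, 100), (200, 300)], cov=7.0)
        records = merge_samples([sample("s1", t1), sample("s2", t2)])
        assert len(records) == 1
        assert records[0].supporting_samples == {"s1", "s2"}
        assert records[0].max_coverage == 7.0

    def test_single_sample_transcript_kept_separate(self):
        records = merge_samples(
            [sample("s1", make_tx("tA", [(0, 100), (200, 300)])),
             sample("s2")]
        )
        assert len(records) == 1
        assert records[0].supporting_samples == {"s1"}

    def test_merged_termini_take_widest_boundaries(self):
        t1 = make_tx("tA", [(10, 100), (200, 290)])
        t2 = make_tx("tA", [(0, 100), (200, 300)])
        (rec,) = merge_samples([sample("s1", t1), sample("s2", t2)])
        assert rec.transcript.start == 0 and rec.transcript.end == 300
        # the junction chain is untouched
        assert [e.bounds for e in rec.transcript.exons] == [(0, 100), (200, 300)]

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample_id"):
            merge_samples([sample("s1"), sample("s1")])


class TestFilter:
    def make_record(self, n_samples, cov):
        t = make_tx("t", [(0, 100)])
        return SupportRecord(t, frozenset(f"s{i}" for i in range(n_samples)), cov)

    def test_two_samples_good_coverage_kept(self):
        assert filter_supported([self.make_record(2, 5.0)]) != []

    def test_single_sample_removed_despite_coverage(self):
        assert filter_supported([self.make_record(1, 100.0)]) == []

    def test_coverage_exactly_at_threshold_removed(self):
        # the coverage rule is strictly greater-than
        assert filter_supported([self.make_record(2, 2.0)]) == []
        assert filter_supported([self.make_record(2, 2.01)]) != []

    def test_monotone_in_both_thresholds(self):
        records = [
            self.make_record(n, c)
            for n in (1, 2, 3)
            for c in (1.0, 2.0, 2.5, 8.0)
        ]
        previous = len(records)
        for ms in (0, 1, 2, 3, 4):
            kept = len(filter_supported(records, min_samples=ms))
            assert kept <= previous
            previous = kept
        previous = len(records)
        for mc in (0.0, 1.0, 2.0, 3.0, 10.0):
            kept = len(filter_supported(records, min_coverage=mc))
            assert kept <= previous
            previous = kept


class TestCategorize:
    REF = make_set(
        make_tx("r1", [(0, 100), (900, 1000)], gene="gA"),
        make_tx("r2", [(5000, 5100), (5200, 5300)], gene="gB"),
    )

    @staticmethod
    def record(tid, exons, strand="+"):
        t = make_tx(tid, exons, strand=strand)
        return SupportRecord(t, frozenset({"s1", "s2"}), 10.0)

    def test_equal_routes_to_extended(self):
        sets = categorize_vs_reference(
            [self.record("q", [(0, 100), (900, 1100)])], self.REF
        )
        assert [r.transcript.transcript_id for r in sets.extended_isoforms] == ["q"]

    def test_overlapping_u_transcripts_form_one_new_gene(self):
        sets = categorize_vs_reference(
            [
                self.record("u1", [(20000, 20500)]),
                self.record("u2", [(20300, 20800)]),
            ],
            self.REF,
        )
        assert len(sets.intergenic_new) == 2
        assert len(sets.new_genes) == 1

    def test_run_on_excluded_from_new_genes(self):
        sets = categorize_vs_reference(
            [self.record("p1", [(1500, 1700)])], self.REF
        )
        assert [r.transcript.transcript_id for r in sets.run_on] == ["p1"]
        assert sets.new_genes == []

    def test_category_sets_are_disjoint(self):
        records = [
            self.record("q", [(0, 100), (900, 1100)]),
            self.record("j1", [(0, 100), (900, 950), (970, 1000)]),
            self.record("u1", [(20000, 20500)]),
            self.record("i1", [(400, 500)]),
            self.record("p1", [(1500, 1700)]),
        ]
        sets = categorize_vs_reference(records, self.REF)
        all_ids = [
            r.transcript.transcript_id
            for group in (
                sets.extended_isoforms, sets.new_isoforms, sets.intronic_new,
                sets.intergenic_new, sets.run_on,
            )
            for r in group
        ]
        assert sorted(all_ids) == sorted(set(all_ids)) == sorted(
            r.transcript.transcript_id for r in records
        )


class TestCleanup:
    REF = make_set(
        make_tx("r1", [(0, 100), (300, 400)], gene="gA"),
        make_tx("r2", [(5000, 5100), (5300, 5400)], gene="gB"),
    )

    def test_fusion_removed_from_isoform_sets(self):
        fusion = SupportRecord(
            make_tx("fus", [(0, 100), (300, 400), (5000, 5100)]),
            frozenset({"s1", "s2"}), 9.0,
        )
        inside = SupportRecord(
            make_tx("ok", [(0, 100), (300, 450)]),
            frozenset({"s1", "s2"}), 9.0,
        )
        sets = categorize_vs_reference([fusion, inside], self.REF)
        sets = remove_fusions(sets, self.REF)
        survivors = {
            r.transcript.transcript_id
            for r in sets.extended_isoforms + sets.new_isoforms
        }
        assert survivors == {"ok"}
        assert sets.removed_fusions == ["fus"]

    def test_u_transcript_bridging_genes_untouched_by_fusion_filter(self):
        bridger = SupportRecord(
            make_tx("u_bridge", [(2000, 2200)]), frozenset({"s1", "s2"}), 9.0
        )
        sets = categorize_vs_reference([bridger], self.REF)
        before = [r.transcript.transcript_id for r in sets.intergenic_new]
        sets = remove_fusions(sets, self.REF)
        assert [r.transcript.transcript_id for r in sets.intergenic_new] == before

    def test_new_gene_filtering_direct_indirect_and_isolated(self):
        kept = SupportRecord(
            make_tx("far", [(20000, 20400)]), frozenset({"s1", "s2"}), 9.0
        )
        direct = SupportRecord(
            make_tx("direct", [(90, 150)], strand="-"),
            frozenset({"s1", "s2"}), 9.0,
        )
        indirect = SupportRecord(
            make_tx("indirect", [(1000, 1400)]), frozenset({"s1", "s2"}), 9.0
        )
        # chain of two single-sample transcripts connects 'indirect' to gA
        chain = [
            make_tx("x1", [(80, 600)]),       # overlaps reference exons
            make_tx("x2", [(550, 1100)]),     # overlaps x1 and 'indirect'
        ]
        sets = CategorizedSets()
        sets.intergenic_new = [kept, indirect]
        sets.intronic_new = []
        from txrefine.transcript_algebra import cluster_genes

        sets.intergenic_new.append(direct)
        sets.new_genes = cluster_genes(
            [r.transcript for r in sets.new_gene_records]
        )
        sets = filter_new_genes(sets, self.REF, chain)
        survivors = {r.transcript.transcript_id for r in sets.new_gene_records}
        assert survivors == {"far"}
        assert set(sets.removed_new_gene_transcripts) == {"direct", "indirect"}


class TestSpecificity:
    def records(self, *sample_sets):
        return [
            SupportRecord(make_tx(f"t{i}", [(0, 100)]), frozenset(ss), 10.0)
            for i, ss in enumerate(sample_sets)
        ]

    def samples(self):
        return [
            SampleAnnotation(sid, sex, strain, AnnotationSet())
            for sid, sex, strain in FOUR_SAMPLES
        ]

    def test_male_specific(self):
        rep = sample_specificity(self.records({"s1", "s3"}), self.samples())
        assert rep["male_specific"] == 1.0
        assert rep["female_specific"] == 0.0

    def test_all_samples_not_specific(self):
        rep = sample_specificity(
            self.records({"s1", "s2", "s3", "s4"}), self.samples()
        )
        assert rep["male_specific"] == rep["female_specific"] == 0.0
        assert rep["strain_specific"] == rep["discordant_pair"] == 0.0

    def test_discordant_pair_baseline(self):
        # ps94 male + ps88 female: different sex and different strain
        rep = sample_specificity(self.records({"s1", "s4"}), self.samples())
        assert rep["discordant_pair"] == 1.0
        assert rep["male_specific"] == rep["female_specific"] == 0.0


class TestRefinePipeline:
    def test_fixed_point_on_reference_like_samples(self):
        ref = make_set(
            make_tx("r1", [(0, 100), (300, 400)], gene="gA"),
            make_tx("r2", [(5000, 5100), (5300, 5400)], gene="gB"),
        )
        samples = []
        for sid, sex, strain in FOUR_SAMPLES:
            txs = [
                make_tx(f"obs_{t.transcript_id}",
                        [e.bounds for e in t.exons],
                        strand=t.strand, cov=10.0, fpkm=5.0)
                for t in ref
            ]
            samples.append(SampleAnnotation(sid, sex, strain, make_set(*txs)))
        result = refine_annotation(samples, ref, RefineConfig())
        assert result.stage_counts["new_isoforms"] == 0
        assert result.stage_counts["new_genes"] == 0
        assert result.stage_counts["extended_isoforms"] == 2
        assert (result.boundary_extensions[["ext5", "ext3"]] == 0).all().all()

    def test_boundary_extension_measured_from_gene_span(self):
        ref = make_set(make_tx("r1", [(1000, 1100), (1300, 1400)], gene="gA"))
        samples = []
        for sid, sex, strain in FOUR_SAMPLES[:2]:
            t = make_tx("obs", [(700, 1100), (1300, 1700)], cov=10.0)
            samples.append(SampleAnnotation(sid, sex, strain, make_set(t)))
        result = refine_annotation(samples, ref, RefineConfig())
        row = result.boundary_extensions.iloc[0]
        assert row["gene_id"] == "gA"
        assert row["ext5"] == 300 and row["ext3"] == 300

    def test_planted_truth_roundup(self, cohort, refined):
        # spot check: every planted single-sample noise transcript is
        # absent from the final annotation
        noise = {
            r.feature_id
            for r in cohort.truth.by_category("single_sample_noise")
        }
        assert noise
        assert not noise & set(refined.provenance["transcript_id"])
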