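import numpy as np
import pytest

import promforest as pf
from promforest.dataset import (
    DatasetError,
    SamplingError,
    load_dataset_tsv,
    save_dataset_tsv,
)


def tss(contig, pos, strand):
    return pf.TSSRecord(pf.GenomicInterval(contig, pos, pos + 1, strand))


class TestPromoterInterval:
    def test_plus_strand_upstream_window(self):
        iv = pf.promoter_interval_from_tss(tss("c1", 1000, "+"), 40)
        assert iv.key == ("c1", 960, 1000, "+")

    def test_minus_strand_mirror(self):
        iv = pf.promoter_interval_from_tss(tss("c1", 1000, "-"), 40)
        assert iv.key == ("c1", 1001, 1041, "-")

    def test_boundary_violations_dropped(self, caplog):
        assert pf.promoter_interval_from_tss(tss("c1", 10, "+"), 40) is None
        assert (
            pf.promoter_interval_from_tss(tss("c1", 80, "-"), 40, contig_length=100)
            is None
        )


def test_deduplicate_keeps_first_occurrence_order():
    a = pf.GenomicInterval("c1", 0, 40, "+")
    b = pf.GenomicInterval("c1", 50, 90, "-")
    assert pf.deduplicate_intervals([a, a, b]) == [a, b]
    assert pf.deduplicate_intervals([]) == []
    distinct = [pf.GenomicInterval("c1", i, i + 40, "+") for i in range(0, 1000, 10)]
    assert pf.deduplicate_intervals(distinct) == distinct


class TestNegativeSampling:
    def test_zero_draws(self, benchmark):
        assert pf.sample_negative_intervals(benchmark.genome, 0, seed=1) == []

    def test_no_overlap_with_excluded(self, benchmark):
        """5000 draws on 1 Mbp avoid 100 excluded promoters (all-pairs check)."""
        exclude = benchmark.truth.promoters[:100]
        negs = pf.sample_negative_intervals(
            benchmark.genome, 5000, exclude=exclude, seed=11
        )
        assert len(negs) == 5000
        collisions = sum(
            1
            for n in negs
            for e in exclude
            if n.contig == e.contig and min(n.end, e.end) - max(n.start, e.start) > 0
        )
        assert collisions == 0

    def test_deterministic(self, benchmark):
        a = pf.sample_negative_intervals(benchmark.genome, 50, seed=5)
        b = pf.sample_negative_intervals(benchmark.genome, 50, seed=5)
        assert a == b

    def test_budget_exhaustion(self):
        genome = pf.GenomeSequence({"c1": "ACGT" * 30})
        exclude = [pf.GenomicInterval("c1", 0, 120, "+")]
        with pytest.raises(SamplingError):
            pf.sample_negative_intervals(
                genome, 5, exclude=exclude, seed=0, max_draw_factor=10
            )


class TestBuildDataset:
    def test_counts_at_1_to_10(self, small_fixture):
        _, genome, tss_records, _ = small_fixture
        ds = pf.build_dataset(genome, tss_records, neg_per_pos=10, seed=2)
        assert (ds.n_pos, ds.n_neg) == (60, 600)
        assert ds.ratio_meta == (1, 10)

    def test_balanced_ratio(self, small_fixture):
        _, genome, tss_records, _ = small_fixture
        ds = pf.build_dataset(genome, tss_records, neg_per_pos=1, seed=2)
        assert ds.n_neg == ds.n_pos

    def test_duplicate_tss_collapse(self, small_fixture):
        _, genome, tss_records, _ = small_fixture
        ds = pf.build_dataset(
            genome, tss_records + tss_records[:20], neg_per_pos=1, seed=2
        )
        assert ds.n_pos == 60

    def test_positives_match_strand_aware_extraction(self, small_fixture):
        """Every positive equals fetch_sequence(promoter_interval_from_tss)."""
        _, genome, tss_records, _ = small_fixture
        ds = pf.build_dataset(genome, tss_records, neg_per_pos=1, seed=4)
        expected = {
            pf.fetch_sequence(genome, pf.promoter_interval_from_tss(t))
            for t in tss_records
        }
        got = {r.sequence for r in ds.records if r.label == 1}
        assert got == expected

    def test_negatives_avoid_positives(self, small_fixture):
        _, genome, tss_records, _ = small_fixture
        ds = pf.build_dataset(genome, tss_records, neg_per_pos=10, seed=9)
        pos = [r.origin for r in ds.records if r.label == 1]
        neg = [r.origin for r in ds.records if r.label == 0]
        collisions = sum(
            1
            for n in neg
            for p in pos
            if n.contig == p.contig and min(n.end, p.end) - max(n.start, p.start) > 0
        )
        assert collisions == 0

    def test_empty_tss_rejected(self, benchmark):
        with pytest.raises(DatasetError):
            pf.build_dataset(benchmark.genome, [], seed=0)


class TestSplit:
    def test_stratified_counts(self, benchmark):
        # exact arithmetic case: 1100 records at 1:10 -> 25 + 250 test rows
        sub = pf.LabeledSequenceSet(
            [r for r in benchmark.train_set.records if r.label == 1][:100]
            + [r for r in benchmark.train_set.records if r.label == 0][:1000]
        )
        _, test = pf.split_train_test(sub, 0.25, seed=0)
        assert (test.n_pos, test.n_neg) == (25, 250)
        # the full 250/2500 set preserves the 1:10 ratio within rounding
        train, test = pf.split_train_test(benchmark.train_set, 0.25, seed=0)
        assert (train.n_pos + test.n_pos, train.n_neg + test.n_neg) == (250, 2500)
        assert test.n_neg / test.n_pos == pytest.approx(10, rel=0.05)

    def test_disjoint_union(self, benchmark):
        train, test = pf.split_train_test(benchmark.train_set, 0.25, seed=0)
        all_records = sorted(
            (r.origin.key for r in train.records + test.records)
        )
        assert all_records == sorted(r.origin.key for r in benchmark.train_set.records)

    def test_deterministic(self, benchmark):
        a = pf.split_train_test(benchmark.train_set, 0.25, seed=7)
        b = pf.split_train_test(benchmark.train_set, 0.25, seed=7)
        assert [r.origin.key for r in a[0].records] == [
            r.origin.key for r in b[0].records
        ]

    def test_tiny_balanced_split(self, benchmark):
        four = pf.LabeledSequenceSet(
            [r for r in benchmark.train_set.records if r.label == 1][:2]
            + [r for r in benchmark.train_set.records if r.label == 0][:2]
        )
        tr, te = pf.split_train_test(four, 0.5, seed=0)
        assert (tr.n_pos, tr.n_neg) == (1, 1) and (te.n_pos, te.n_neg) == (1, 1)

    def test_singleton_class_rejected(self, benchmark):
        bad = pf.LabeledSequenceSet(
            [r for r in benchmark.train_set.records if r.label == 1][:1]
            + [r for r in benchmark.train_set.records if r.label == 0][:5]
        )
        with pytest.raises(DatasetError):
            pf.split_train_test(bad, 0.5, seed=0)


def test_tsv_round_trip(tmp_path, small_fixture):
    _, genome, tss_records, _ = small_fixture
    ds = pf.build_dataset(genome, tss_records, neg_per_pos=1, seed=3)
    path = tmp_path / "ds.tsv"
    save_dataset_tsv(ds, path)
    back = load_dataset_tsv(path)
    assert [(r.sequence, r.label, r.origin.key) for r in back.records] == [
        (r.sequence, r.label, r.origin.key) for r in ds.records
    ]
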