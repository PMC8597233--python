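import numpy as np
import pytest

import promforest as pf
from promforest.evaluate import MetricError, matthews_corrcoef_safe
from promforest.genome_io import GenomicInterval
from promforest.scanner import PredictionRecord
from oracles import cluster_tp_oracle, overlap_labels_oracle, pr_roc_areas_oracle


def iv(start, end, strand="+", contig="c1"):
    return GenomicInterval(contig, start, end, strand)


def preds_at(spans, probs, strand="+"):
    return [
        PredictionRecord(iv(s, e, strand), p) for (s, e), p in zip(spans, probs)
    ]


class TestOverlapLabelling:
    TRUTH = pf.GroundTruth([iv(100, 140)])

    def test_overlap_above_10_percent(self):
        assert pf.label_by_overlap([iv(96, 136)], self.TRUTH).tolist() == [1]

    def test_overlap_below_threshold(self):
        # 3 bp shared < ceil(0.1 * 40) = 4
        assert pf.label_by_overlap([iv(63, 103)], self.TRUTH).tolist() == [0]

    def test_strand_aware(self):
        assert pf.label_by_overlap([iv(96, 136, "-")], self.TRUTH).tolist() == [0]

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            truth = pf.GroundTruth(
                [
                    iv(s, s + 40, rng.choice(["+", "-"]))
                    for s in rng.integers(0, 5000, size=rng.integers(1, 40))
                ]
            )
            windows = [
                iv(s, s + 40, rng.choice(["+", "-"]))
                for s in rng.integers(0, 5000, size=300)
            ]
            got = pf.label_by_overlap(windows, truth).tolist()
            assert got == overlap_labels_oracle(windows, truth.promoters)


class TestClusterLabelling:
    def test_within_100nt_is_tp(self):
        truth = pf.GroundTruth([iv(1000, 1040)])
        recs = preds_at([(1090, 1130)], [0.9])
        assert pf.label_by_cluster(recs, truth).tolist() == [True]

    def test_beyond_100nt_is_fp(self):
        truth = pf.GroundTruth([iv(1000, 1040)])
        recs = preds_at([(1190, 1230)], [0.9])
        assert pf.label_by_cluster(recs, truth).tolist() == [False]

    def test_k_caps_tps_per_truth(self):
        """7 predictions all within 20 nt of one truth: exactly 5 TPs."""
        truth = pf.GroundTruth([iv(1000, 1040)])
        spans = [(1000 + 3 * i, 1040 + 3 * i) for i in range(7)]
        recs = preds_at(spans, [0.5] * 7)
        flags = pf.label_by_cluster(recs, truth, k=5)
        assert flags.sum() == 5
        tp_idx = set(np.flatnonzero(flags))
        assert tp_idx == cluster_tp_oracle(
            [r.window for r in recs], truth.promoters, k=5
        )

    def test_strand_blind(self):
        truth = pf.GroundTruth([iv(1000, 1040, "+")])
        recs = preds_at([(1050, 1090)], [0.9], strand="-")
        assert pf.label_by_cluster(recs, truth).tolist() == [True]

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            truth = pf.GroundTruth(
                [iv(s, s + 40) for s in rng.integers(0, 4000, size=rng.integers(1, 20))]
            )
            spans = [(s, s + 40) for s in rng.integers(0, 4000, size=200)]
            recs = preds_at(spans, rng.random(200))
            got = set(np.flatnonzero(pf.label_by_cluster(recs, truth)))
            assert got == cluster_tp_oracle([r.window for r in recs], truth.promoters)


class TestPrRoc:
    def test_perfect(self):
        r = pf.pr_roc([1, 0], [0.9, 0.1])
        assert (r.auprc, r.auroc) == (1.0, 1.0)

    def test_inverted(self):
        assert pf.pr_roc([1, 0], [0.1, 0.9]).auroc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            pf.pr_roc([1, 1], [0.2, 0.4])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            r = pf.pr_roc(labels.tolist(), scores.tolist())
            auprc, auroc = pr_roc_areas_oracle(labels.tolist(), scores.tolist())
            assert r.auprc == pytest.approx(auprc)
            assert r.auroc == pytest.approx(auroc)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(5)
        n = 100_000
        labels = (rng.random(n) < 0.1).astype(int)
        scores = rng.random(n)
        r = pf.pr_roc(labels, scores)
        assert r.auprc == pytest.approx(0.1, abs=0.02)
        assert r.auroc == pytest.approx(0.5, abs=0.02)


class TestGenomeWide:
    def _perfect_setup(self):
        truths = [iv(1000 * i + 500, 1000 * i + 540) for i in range(20)]
        preds = [PredictionRecord(t, 1.0) for t in truths]
        preds += preds_at(
            [(1000 * i + 100, 1000 * i + 140) for i in range(20)], [0.0] * 20
        )
        return preds, pf.GroundTruth(truths)

    def test_perfect_predictions_score_one_in_both_modes(self):
        preds, truth = self._perfect_setup()
        assert pf.evaluate_genome_wide(preds, truth, "OVERLAP").auprc == 1.0
        assert pf.evaluate_genome_wide(preds, truth, "CLUSTER").auprc == pytest.approx(1.0)

    def test_cluster_at_least_overlap_on_synthetic_scan(self, small_scan, small_fixture):
        """Near-miss predictions are credited by the cluster scheme only."""
        _, _, _, truth = small_fixture
        ov = pf.evaluate_genome_wide(small_scan, truth, "OVERLAP")
        cl = pf.evaluate_genome_wide(small_scan, truth, "CLUSTER")
        assert cl.auprc >= ov.auprc

    def test_empty_truth_rejected(self):
        preds, _ = self._perfect_setup()
        with pytest.raises(MetricError):
            pf.evaluate_genome_wide(preds, pf.GroundTruth([]), "OVERLAP")


class TestBalanced:
    def test_mcc_degenerate_convention(self):
        assert matthews_corrcoef_safe(np.array([1, 0]), np.array([1, 1])) == 0.0

    def test_separable_model_is_perfect(self, small_model, small_fixture):
        _, genome, tss_records, _ = small_fixture
        ds = pf.build_dataset(genome, tss_records, neg_per_pos=1, seed=77)
        report = pf.evaluate_balanced(small_model, ds)
        # trained on these positives: near-perfect separation expected
        assert report.result.auroc > 0.95
        assert report.accuracy > 0.8

    def test_random_scores_give_half_accuracy(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=20_000)
        y_hat = rng.integers(0, 2, size=20_000)
        acc = float(np.mean(y == y_hat))
        assert acc == pytest.approx(0.5, abs=0.02)
        assert matthews_corrcoef_safe(y, y_hat) == pytest.approx(0.0, abs=0.02)


def test_random_baseline_auprc_is_prevalence():
    assert pf.random_baseline_auprc(1, 4) == 0.25
    with pytest.raises(ValueError):
        pf.random_baseline_auprc(5, 4)
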