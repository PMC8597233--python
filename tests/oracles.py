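"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: overlap labelling and
cluster matching are all-pairs Python loops, PR/ROC areas come from
exhaustive threshold enumeration, and 4-mer frequencies from a plain
dictionary count.
"""

import math
from collections import Counter


def overlap_labels_oracle(windows, truth_intervals, min_frac=0.1):
    """All-pairs overlap labelling (same contig + strand, >= ceil(frac*len) bp)."""
    labels = []
    for w in windows:
        need = math.ceil(min_frac * (w.end - w.start))
        hit = any(
            t.contig == w.contig
            and t.strand == w.strand
            and min(t.end, w.end) - max(t.start, w.start) >= need
            for t in truth_intervals
        )
        labels.append(int(hit))
    return labels


def cluster_tp_oracle(pred_intervals, truth_intervals, max_dist=100, k=5):
    """Indices of predictions that are TPs under k-nearest-within-cutoff."""
    tp = set()
    for t in truth_intervals:
        cands = []
        for i, p in enumerate(pred_intervals):
            if p.contig != t.contig:
                continue
            gap = max(p.start - t.end, t.start - p.end, 0)
            cands.append((gap, p.start, i))
        cands.sort()
        for gap, _, i in cands[:k]:
            if gap < max_dist:
                tp.add(i)
    return tp


def pr_roc_areas_oracle(labels, scores):
    """(AUPRC, AUROC) by exhaustive enumeration of distinct thresholds.

    AUPRC uses step-wise (right-constant precision) integration; AUROC is
    the Mann-Whitney statistic (trapezoid-equivalent, ties counted 1/2).
    """
    pairs = sorted(zip(scores, labels), reverse=True)
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    # AUPRC
    auprc = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            tp += pairs[j][1]
            fp += 1 - pairs[j][1]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        auprc += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    # AUROC via rank comparison
    wins = 0.0
    for sp, lp in zip(scores, labels):
        if lp != 1:
            continue
        for sn, ln in zip(scores, labels):
            if ln != 0:
                continue
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    auroc = wins / (n_pos * n_neg)
    return auprc, auroc


def tetra_freqs_oracle(seq):
    """4-mer frequency dict via plain counting; N-containing windows dropped."""
    counts = Counter()
    for i in range(len(seq) - 3):
        kmer = seq[i : i + 4]
        if "N" not in kmer:
            counts[kmer] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()} if total else {}
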