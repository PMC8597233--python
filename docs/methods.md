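# Methods

## Coordinate model

All coordinates are 0-based half-open with an explicit strand (BED
semantics). A TSS is a length-1 interval. The promoter window of a TSS
base at position *p* is `[p−40, p)` on the plus strand and
`[p+1, p+41)` on the minus strand; fetched 5′→3′ on its own strand, the
window covers TSS-relative positions −40…−1 in either case. Windows
that would leave their contig are dropped (not clipped) with a logged
warning — the classifiers require exactly 40 nt. Genomes are treated as
linear; windows never wrap origins or span contigs. Softmasked FASTA is
uppercased on read, since both encodings are case-free.

Two position-labelling conventions coexist in this domain and differ by
one: the dataset contract above (−40…−1, sequence index *i* ↔ position
*i*−40) and the −39…0 labelling conventionally used for importance
profiles, which this package adopts for reported feature names
(`pos-39:A` … `pos0:T`, label = index − 39). Motif placement and the
motif-recovery tests work in sequence indices, which are unambiguous:
the default planted motif starts at index 28 of the 40-mer.

## Dataset construction

Duplicate promoter intervals (identical contig, start, end, strand) are
collapsed to the first occurrence. Negatives are sampled by rejection:
starts uniform over valid positions with contigs weighted by length,
strand uniform, and any candidate sharing ≥1 bp of genomic coordinate
with a positive (strand-blind — the conservative reading) is rejected;
the budget is 1000 draws per requested negative, after which a resource
error suggests reducing *n*. Balanced validation sets apply the same
exclusion, so no validation negative is a mislabelled promoter.
Sequences containing N are retained; the encoders define N handling
(all-zero one-hot block; N-containing 4-mer windows dropped from
numerator and denominator alike). Stratified 75/25 splitting preserves
the class ratio within rounding.

## Models

Forests use Gini impurity, probability = fraction of tree votes, and
data-derived balanced class weights `w_c = N/(2·N_c)` (a 1:10 set gives
{0: 0.55, 1: 5.5}); fixed published weight pairs floating around for
this task are inconsistent with any standard formula at 1:10 and are
deliberately not hard-coded. Grid-search CV is stratified k-fold over
`max_features × n_estimators`; the selection metric is mean fold AUPRC
with ties broken by mean AUROC, then by the smaller forest (cheaper
model wins when indistinguishable). The `full` profile (9-cell grid,
10 folds, 1000–3000 trees) is faithful to the method's published search
space; the `fast` profile (3 `max_features` rules × 100 trees, 3 folds)
keeps the same selection logic at test scale. Models serialise via
joblib with a format-version field and a sha256 fingerprint of the
training matrix, so accidental encoder/model mismatches are detectable.

## Scanning

Step-1 scanning is the faithful default; the CLI exposes `--step` with
a logged warning because sparser sampling measurably lowers
exact-locus recall. Minus-strand windows are scored on the reverse
complement of the forward slice. Batched encoding keeps memory bounded
by the batch size; batched and unbatched execution produce identical
outputs (tested). Output order is (contig, start, strand).

## Evaluation

*Overlap mode*: a window is positive iff it shares at least
`ceil(0.1 × window_length)` bp (4 bp for 40-nt windows) with a truth
interval on the same contig and strand — the `-s -f 0.1` intersect
semantics, with the fraction measured against the predicted window.
The PR curve then sweeps all distinct scores; AUPRC uses step-wise
(right-constant precision) integration and AUROC the trapezoid rule.

*Cluster mode*: for each truth interval, its 5 nearest prediction
windows by gap distance (overlapping or book-ended intervals count as
distance 0; ties broken toward the leftmost start) lying strictly
within 100 nt are true positives; matching is strand-blind. Because the
matching depends on which predictions survive a threshold, the curve is
rebuilt by re-running the matcher at each of a 200-quantile score grid
(configurable) rather than at every distinct score — exact re-matching
at millions of thresholds would be quadratic. Recall is matched truths
over all truths; the ROC false-positive denominator is all windows
minus the truth count.

*Balanced mode*: PR/ROC over predicted probabilities plus MCC and
accuracy at a fixed 0.5 threshold; a degenerate confusion table yields
MCC 0 by the 0/0 → 0 convention.

PR/ROC integration is delegated to scikit-learn's
`precision_recall_curve` / `average_precision_score` / `roc_auc_score`,
which implement exactly these rules; the test suite cross-checks them
against an exhaustive threshold-enumeration oracle, and both labelling
schemes against all-pairs brute-force oracles.

## Importance

Impurity importance is the per-tree normalised mean decrease in Gini,
averaged over trees (renormalised to sum to 1) with the across-tree
standard deviation. Permutation importance is the mean decrease in
accuracy (threshold 0.5) over 5 within-column shuffles of a held-out
evaluation set (the 25% split by default — importances on training data
overstate memorised features). One-hot rankings reshape into a 40 × 4
position-by-nucleotide profile.

## Synthetic data

The simulator emulates the data regime the method targets: an i.i.d.
background genome of configurable GC content (real bacterial genomes
span roughly 30–72% GC; default 0.5) with N planted promoters. Each
promoter carries the `TATAAT` hexamer at TSS-relative −12…−7 —
the canonical Pribnow-box placement ~10 bp upstream — with each motif
base independently re-randomised at rate 0.15, so classifiers cannot be
trivially perfect and PR curves have shape. TSS positions are jittered
within equal-length chunks (one promoter per chunk, ≥60 bp from chunk
edges), which guarantees non-overlap deterministically; strands
alternate +/− so both strand code paths are always exercised. The
canonical benchmark is 1 Mbp / 500 promoters / seed 42, TSS alternately
assigned to a 250-TSS training half (1:10 set) and a 250-TSS validation
half (1:1 set), with negatives of either half excluded from overlap
with *all* planted promoters.

What the simulator deliberately omits: positional base composition
biases, the −35 element and spacer-length variation, operon structure,
repeat families, and sequencing-derived TSS noise. Passing tests on
synthetic data therefore demonstrate that the pipeline's machinery
(extraction arithmetic, strand handling, encodings, CV selection,
scanning, both evaluation schemes, importance aggregation) is correct
and that the forests can recover a planted upstream motif — not that
real-genome accuracies will match the synthetic ones, which are easier
(a single motif family against an i.i.d. background).

## Problem sizes and numerical choices

Tests and the acceptance script run the `fast` training profile on the
1 Mbp benchmark and scan at step 10 (~2×10⁵ windows), sizes chosen so
the whole suite completes in minutes on one CPU while leaving every
code path identical to a full-scale run. The published full-scale runs
this mirrors scanned ~7 Mbp genomes at step 1 (~1.4×10⁷ windows).
4-mer frequency vectors sum to 1 within 1e−9 whenever a valid window
exists; an all-N sequence yields the zero vector. Window-count
arithmetic is `L − 40 + 1` per contig per strand, exactly.

## Known limitations

Cluster-mode AUPRC depends mildly on the threshold-grid density (200
quantiles by default); exact per-score re-matching is available by
raising `n_thresholds`. The gap distance counts book-ended intervals as
0 rather than 1, a half-open-coordinate convention that can differ by
one base from other interval toolkits. Probabilities are raw vote
fractions — no calibration is attempted. Scanning is single-threaded by
design; genome-scale step-1 scans are feasible but slow in pure Python
batching.
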