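"""Build labelled promoter / non-promoter sequence sets from TSS coordinates.

A promoter is operationalised as the 40 bp immediately upstream of a TSS,
read 5'->3' toward the TSS on its own strand.  Negatives are random
genomic windows of the same length, drawn uniformly over both strands and
all contigs (weighted by length) and rejected if they share a single base
of genomic coordinate with any positive, strand-blind.  Training sets use
a 1:10 positive:negative ratio to mimic the scarcity of promoters in a
whole genome; validation sets are balanced 1:1.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.model_selection import train_test_split

from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    TSSRecord,
    fetch_sequence,
)

logger = logging.getLogger(__name__)

PROMOTER_WIDTH = 40


class DatasetError(ValueError):
    """Dataset construction could not produce a valid labelled set."""


class SamplingError(RuntimeError):
    """Rejection sampling of negatives exhausted its retry budget."""


class SequenceRecord(NamedTuple):
    sequence: str
    label: int
    origin: GenomicInterval


@dataclass
class LabeledSequenceSet:
    """Fixed-width sequences with binary promoter labels and provenance."""

    records: list[SequenceRecord]
    ratio_meta: tuple[int, int] | None = None  # declared positive:negative

    def __post_init__(self) -> None:
        for r in self.records:
            if len(r.sequence) != PROMOTER_WIDTH:
                raise DatasetError(
                    f"sequence at {r.origin} has length {len(r.sequence)}, "
                    f"expected {PROMOTER_WIDTH}"
                )
            if r.label not in (0, 1):
                raise DatasetError(f"label must be 0 or 1, got {r.label}")
        if self.ratio_meta is not None and self.n_pos == 0:
            raise DatasetError("declared ratio but no positive records")

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def n_pos(self) -> int:
        return sum(r.label == 1 for r in self.records)

    @property
    def n_neg(self) -> int:
        return len(self.records) - self.n_pos

    def fingerprint(self) -> str:
        """Order-independent sha256 over (sequence, label) pairs."""
        h = hashlib.sha256()
        for seq, label in sorted((r.sequence, r.label) for r in self.records):
            h.update(f"{seq}\t{label}\n".encode())
        return h.hexdigest()


def promoter_interval_from_tss(
    tss: TSSRecord,
    width: int = PROMOTER_WIDTH,
    contig_length: int | None = None,
) -> GenomicInterval | None:
    """Interval of the `width` bp upstream of a TSS on its own strand.

    For a plus-strand TSS base at p this is [p-width, p)+; for a
    minus-strand TSS it is [p+1, p+1+width)-.  Either way the fetched
    sequence reads 5'->3' toward the TSS, covering TSS-relative positions
    -width..-1.  Returns None (with a logged warning) when the interval
    would leave the contig.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    p = tss.site.start
    if tss.site.strand == "+":
        start, end = p - width, p
    else:
        start, end = p + 1, p + 1 + width
    if start < 0 or (contig_length is not None and end > contig_length):
        logger.warning("dropping TSS %s: promoter window leaves the contig", tss.site)
        return None
    return GenomicInterval(tss.site.contig, start, end, tss.site.strand)


def deduplicate_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse exact (contig, start, end, strand) duplicates, keeping the
    first occurrence and the original order."""
    seen: set[tuple] = set()
    out: list[GenomicInterval] = []
    for iv in ivs:
        if iv.key not in seen:
            seen.add(iv.key)
            out.append(iv)
    return out


def _exclusion_trees(exclude: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in exclude:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    return trees


def sample_negative_intervals(
    genome: GenomeSequence,
    n: int,
    length: int = PROMOTER_WIDTH,
    exclude: Sequence[GenomicInterval] = (),
    seed: int = 0,
    max_draw_factor: int = 1000,
) -> list[GenomicInterval]:
    """Draw n random windows sharing no base with any excluded interval.

    Starts are uniform over valid positions with contigs weighted by
    length; strand is uniform over {+,-}.  Overlap against `exclude` is
    tested on genomic coordinates regardless of strand.  Deterministic
    for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    contig_ids = [c for c in genome.contigs if genome.contig_length(c) >= length]
    if not contig_ids:
        raise SamplingError(f"no contig can hold a {length}-bp window")
    n_starts = np.array([genome.contig_length(c) - length + 1 for c in contig_ids])
    weights = n_starts / n_starts.sum()
    trees = _exclusion_trees(exclude)

    out: list[GenomicInterval] = []
    draws = 0
    budget = max_draw_factor * n
    while len(out) < n:
        batch = min(max(n - len(out), 64), budget - draws)
        if batch <= 0:
            raise SamplingError(
                f"drew {draws} candidates but accepted only {len(out)}/{n}; "
                "the exclusion set may be too dense — try a smaller n"
            )
        cidx = rng.choice(len(contig_ids), size=batch, p=weights)
        starts = rng.integers(0, n_starts[cidx])
        strands = rng.choice(np.array(["+", "-"]), size=batch)
        draws += batch
        for ci, s, st in zip(cidx, starts, strands):
            if len(out) == n:
                break
            contig = contig_ids[ci]
            tree = trees.get(contig)
            if tree is not None and tree.overlaps(int(s), int(s) + length):
                continue
            out.append(GenomicInterval(contig, int(s), int(s) + length, str(st)))
    return out


def build_dataset(
    genome: GenomeSequence,
    tss: Sequence[TSSRecord],
    neg_per_pos: int = 10,
    seed: int = 0,
    width: int = PROMOTER_WIDTH,
    extra_exclude: Sequence[GenomicInterval] = (),
) -> LabeledSequenceSet:
    """Assemble a labelled set from TSS records at a given class ratio.

    Positives are the deduplicated in-bounds promoter windows; negatives
    are ``neg_per_pos`` random windows per positive, excluded from any
    coordinate overlap with the positives (and with ``extra_exclude``,
    e.g. the promoters of a held-out set).  Records are shuffled
    deterministically with the seed.
    """
    if not tss:
        raise DatasetError("no TSS records supplied")
    candidates = [
        promoter_interval_from_tss(t, width, genome.contig_length(t.site.contig))
        for t in tss
    ]
    pos_ivs = deduplicate_intervals(iv for iv in candidates if iv is not None)
    if not pos_ivs:
        raise DatasetError("every TSS was dropped at a contig boundary")

    seq_train, seq_shuffle = np.random.SeedSequence(seed).spawn(2)
    neg_ivs = sample_negative_intervals(
        genome,
        n=neg_per_pos * len(pos_ivs),
        length=width,
        exclude=list(pos_ivs) + list(extra_exclude),
        seed=seq_train.generate_state(1)[0] % (2**31),
    )
    records = [SequenceRecord(fetch_sequence(genome, iv), 1, iv) for iv in pos_ivs]
    records += [SequenceRecord(fetch_sequence(genome, iv), 0, iv) for iv in neg_ivs]
    order = np.random.default_rng(seq_shuffle.generate_state(1)[0]).permutation(
        len(records)
    )
    return LabeledSequenceSet(
        [records[i] for i in order], ratio_meta=(1, neg_per_pos)
    )


def split_train_test(
    ds: LabeledSequenceSet,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[LabeledSequenceSet, LabeledSequenceSet]:
    """Stratified split preserving the class ratio in both parts."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    labels = ds.labels
    if min(np.bincount(labels, minlength=2)) < 2:
        raise DatasetError("stratified split needs >= 2 records of each class")
    idx = np.arange(len(ds.records))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    mk = lambda ids: LabeledSequenceSet(
        [ds.records[i] for i in sorted(ids)], ratio_meta=ds.ratio_meta
    )
    return mk(train_idx), mk(test_idx)


# --- TSV serialisation ------------------------------------------------------

_TSV_COLUMNS = ["sequence", "label", "origin", "strand"]


def save_dataset_tsv(ds: LabeledSequenceSet, path: str | Path) -> None:
    """Write a 4-column TSV: sequence, label, origin (contig:start-end), strand."""
    df = pd.DataFrame(
        {
            "sequence": [r.sequence for r in ds.records],
            "label": [r.label for r in ds.records],
            "origin": [
                f"{r.origin.contig}:{r.origin.start}-{r.origin.end}"
                for r in ds.records
            ],
            "strand": [r.origin.strand for r in ds.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_dataset_tsv(path: str | Path) -> LabeledSequenceSet:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "strand": str})
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing TSV column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        contig, span = row.origin.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        records.append(
            SequenceRecord(
                row.sequence,
                int(row.label),
                GenomicInterval(contig, start, end, row.strand),
            )
        )
    return LabeledSequenceSet(records)
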