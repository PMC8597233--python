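"""Genome-wide promoter scoring with a 40-nt sliding window on both strands.

Each contig of length L yields floor((L - window) / step) + 1 windows per
strand; a minus-strand window at [s, s+40) is scored on the reverse
complement of the forward slice.  Encoding and prediction are batched so
the full set of encoded windows is never resident at once.  The default
step of 1 nt matches the method's design; larger steps trade recall for
speed.
"""

from __future__ import annotations

import logging
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .encoders import encode_sequences, reverse_complement
from .genome_io import GenomeSequence, GenomicInterval
from .model import TrainedModel, predict_proba_features

logger = logging.getLogger(__name__)

WINDOW_SIZE = 40


class PredictionRecord(NamedTuple):
    """A scored scan window."""

    window: GenomicInterval
    probability: float


def window_starts(contig_length: int, window: int = WINDOW_SIZE, step: int = 1) -> range:
    if contig_length < window:
        return range(0)
    return range(0, contig_length - window + 1, step)


def sliding_windows(
    genome: GenomeSequence, window: int = WINDOW_SIZE, step: int = 1
) -> Iterator[GenomicInterval]:
    """Stream scan windows: per contig, all plus-strand then all minus-strand."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    for contig, seq in genome.contigs.items():
        starts = window_starts(len(seq), window, step)
        if len(starts) == 0:
            logger.warning(
                "contig %r (%d bp) is shorter than the %d-nt window; skipped",
                contig, len(seq), window,
            )
            continue
        for strand in ("+", "-"):
            for s in starts:
                yield GenomicInterval(contig, s, s + window, strand)


def count_windows(genome: GenomeSequence, window: int = WINDOW_SIZE, step: int = 1) -> int:
    """Total window count over both strands (exact arithmetic)."""
    per_strand = sum(
        len(window_starts(len(seq), window, step)) for seq in genome.contigs.values()
    )
    return 2 * per_strand


def scan_genome(
    model: TrainedModel,
    genome: GenomeSequence,
    step: int = 1,
    batch_size: int = 8192,
) -> list[PredictionRecord]:
    """Score every window on both strands; output sorted by (contig, start, strand).

    Windows are encoded and scored in batches of ``batch_size`` so memory
    stays bounded by the batch, not the genome.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    records: list[PredictionRecord] = []
    for contig, seq in genome.contigs.items():
        starts = list(window_starts(len(seq), WINDOW_SIZE, step))
        if not starts:
            logger.warning(
                "contig %r (%d bp) is shorter than the %d-nt window; skipped",
                contig, len(seq), WINDOW_SIZE,
            )
            continue
        contig_records: list[PredictionRecord] = []
        for strand in ("+", "-"):
            for i in range(0, len(starts), batch_size):
                chunk = starts[i : i + batch_size]
                seqs = [seq[s : s + WINDOW_SIZE] for s in chunk]
                if strand == "-":
                    seqs = [reverse_complement(x) for x in seqs]
                X = encode_sequences(seqs, model.encoder_tag)
                probs = predict_proba_features(model, X)
                contig_records.extend(
                    PredictionRecord(
                        GenomicInterval(contig, s, s + WINDOW_SIZE, strand),
                        float(p),
                    )
                    for s, p in zip(chunk, probs)
                )
        contig_records.sort(key=lambda r: (r.window.start, r.window.strand))
        records.extend(contig_records)
    return records


def threshold_predictions(
    records: Sequence[PredictionRecord], tau: float
) -> list[PredictionRecord]:
    """Keep records with probability >= tau, order preserved."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    return [r for r in records if r.probability >= tau]
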