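"""Synthetic bacterial genomes with planted promoters and known truth.

The generator emulates the data regime the classifier is built for: an
i.i.d. background genome of configurable GC content carrying N
non-overlapping promoters, each a 40-nt window upstream of a nominal TSS
with a degenerate Pribnow-box-like motif (default TATAAT) starting 12 bp
upstream of the TSS (TSS-relative positions -12..-7, sequence indices
28..33 of the 40-mer).  Promoter strands alternate +/- so both strand
code paths are exercised, and each motif base is independently
randomised with a configurable mutation rate so classifiers cannot be
trivially perfect.

The canonical benchmark bundle is a 1 Mbp genome at GC 0.5 with 500
promoters (mutation rate 0.15, seed 42), split into 250 training TSS
(1:10 positive:negative training set) and 250 validation TSS (balanced
1:1 set).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .dataset import (
    LabeledSequenceSet,
    build_dataset,
    promoter_interval_from_tss,
)
from .evaluate import GroundTruth
from .genome_io import GenomeSequence, GenomicInterval, TSSRecord, write_bed

BASES = "ACGT"
_CODES = {b: i for i, b in enumerate(BASES)}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT codes

PROMOTER_WIDTH = 40
#: margin kept free around a TSS so the promoter window and some flank fit
_EDGE_MARGIN = 60


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic genome with planted promoters."""

    genome_length: int = 1_000_000
    gc_content: float = 0.5
    n_promoters: int = 500
    motif: str = "TATAAT"
    motif_offset: int = -12  # motif start relative to the TSS (occupies -12..-7)
    motif_mutation_rate: float = 0.15
    seed: int = 42
    contig: str = "synthetic_1"

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_promoters * 200 >= self.genome_length:
            raise ValueError(
                "placement infeasible: need n_promoters * 200 < genome_length"
            )
        if not (0.0 <= self.motif_mutation_rate <= 1.0):
            raise ValueError("motif_mutation_rate must be in [0, 1]")
        i0 = self.motif_offset + PROMOTER_WIDTH
        if i0 < 0 or i0 + len(self.motif) > PROMOTER_WIDTH:
            raise ValueError("motif does not fit inside the 40-nt promoter window")


def generate_genome(
    spec: SyntheticSpec,
) -> tuple[GenomeSequence, list[TSSRecord], GroundTruth]:
    """Sample a genome, TSS map, and matching truth intervals.

    Background bases are i.i.d. with the requested GC; promoter i sits in
    chunk i of the genome (chunks of length L/N), guaranteeing
    non-overlap, with strand alternating +, -, +, ...  Deterministic per
    seed: the same spec always yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=spec.genome_length, p=p).astype(np.int8)

    motif_codes = np.array([_CODES[b] for b in spec.motif], dtype=np.int8)
    chunk = spec.genome_length // spec.n_promoters
    tss_records: list[TSSRecord] = []
    truth: list[GenomicInterval] = []
    for i in range(spec.n_promoters):
        pos = chunk * i + int(rng.integers(_EDGE_MARGIN, chunk - _EDGE_MARGIN))
        strand = "+" if i % 2 == 0 else "-"
        planted = motif_codes.copy()
        mutate = rng.random(len(planted)) < spec.motif_mutation_rate
        planted[mutate] = rng.integers(0, 4, size=int(mutate.sum()))
        if strand == "+":
            g0 = pos + spec.motif_offset  # sequence index i <-> genomic pos-40+i
            codes[g0 : g0 + len(planted)] = planted
        else:
            # promoter [pos+1, pos+41)-: sequence index i <-> genomic pos+40-i,
            # so the motif appears as its reverse complement on the forward strand
            g0 = pos - spec.motif_offset - len(planted) + 1
            codes[g0 : g0 + len(planted)] = _COMP[planted[::-1]]
        site = GenomicInterval(spec.contig, pos, pos + 1, strand)
        tss_records.append(TSSRecord(site, source_label="synthetic"))
        truth.append(promoter_interval_from_tss(tss_records[-1], PROMOTER_WIDTH))

    seq = "".join(BASES[c] for c in codes)
    genome = GenomeSequence({spec.contig: seq})
    return genome, tss_records, GroundTruth(truth)


@dataclass
class BenchmarkBundle:
    """The canonical synthetic benchmark used across tests and examples."""

    spec: SyntheticSpec
    genome: GenomeSequence
    tss: list[TSSRecord]
    truth: GroundTruth
    train_tss: list[TSSRecord]
    val_tss: list[TSSRecord]
    train_set: LabeledSequenceSet  # 1:10 positive:negative
    val_set: LabeledSequenceSet  # 1:1 balanced


def make_benchmark(spec: SyntheticSpec) -> BenchmarkBundle:
    """Generate the genome and build the 1:10 train / 1:1 validation sets.

    TSS alternate between the halves (even index -> train, odd -> val) so
    both halves mix strands; negatives of either set are excluded from
    overlap with *all* planted promoters.
    """
    genome, tss, truth = generate_genome(spec)
    train_tss = tss[0::2]
    val_tss = tss[1::2]
    child = np.random.SeedSequence(spec.seed).spawn(2)
    train_set = build_dataset(
        genome,
        train_tss,
        neg_per_pos=10,
        seed=int(child[0].generate_state(1)[0] % (2**31)),
        extra_exclude=truth.promoters,
    )
    val_set = build_dataset(
        genome,
        val_tss,
        neg_per_pos=1,
        seed=int(child[1].generate_state(1)[0] % (2**31)),
        extra_exclude=truth.promoters,
    )
    return BenchmarkBundle(
        spec=spec,
        genome=genome,
        tss=tss,
        truth=truth,
        train_tss=train_tss,
        val_tss=val_tss,
        train_set=train_set,
        val_set=val_set,
    )


@lru_cache(maxsize=1)
def default_benchmark() -> BenchmarkBundle:
    """1 Mbp, GC 0.5, 500 promoters, motif mutation 0.15, seed 42."""
    return make_benchmark(SyntheticSpec())


def write_fixture(
    spec: SyntheticSpec, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write FASTA + TSS BED + truth BED for a spec; returns the paths."""
    genome, tss, truth = generate_genome(spec)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fasta")
    with open(fasta, "w") as fh:
        for contig, seq in genome.contigs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    tss_bed = Path(f"{prefix}.tss.bed")
    write_bed(
        [t.site for t in tss], [0.0] * len(tss), tss_bed
    )
    truth_bed = Path(f"{prefix}.promoters.bed")
    write_bed(truth.promoters, [0.0] * len(truth.promoters), truth_bed)
    return fasta, tss_bed, truth_bed
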