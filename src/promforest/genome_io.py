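"""Genome and interval I/O: FASTA reading, BED6 round-tripping, and the
coordinate model (0-based half-open, strand-aware) used throughout.

A TSS is carried as a length-1 interval; promoters, scan windows and
predictions are all :class:`GenomicInterval` instances.  BED coordinates
follow the BEDTools convention (0-based half-open), and the BED score
column carries prediction probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .encoders import VALID_ALPHABET, reverse_complement

STRANDS = ("+", "-")


class ParseError(ValueError):
    """A FASTA/BED file violates the expected format."""


class CoordinateError(ValueError):
    """An interval falls outside its contig or names an unknown contig."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic span: 0-based inclusive start, exclusive end."""

    contig: str
    start: int
    end: int
    strand: str
    name: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ParseError(f"invalid strand {self.strand!r}; expected '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Coordinate identity (ignores name/score) used for deduplication."""
        return (self.contig, self.start, self.end, self.strand)

    def __str__(self) -> str:  # e.g. "c1:960-1000(+)"
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: a single genomic base plus provenance."""

    site: GenomicInterval
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.site.length != 1:
            raise CoordinateError("a TSS must be a length-1 interval")


@dataclass
class GenomeSequence:
    """One or more contigs of uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ParseError("genome has no contigs")
        for cid, seq in self.contigs.items():
            if not seq:
                raise ParseError(f"contig {cid!r} is empty")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise ParseError(
                    f"contig {cid!r} contains invalid character(s) {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_length(self, contig: str) -> int:
        try:
            return len(self.contigs[contig])
        except KeyError:
            raise CoordinateError(f"unknown contig {contig!r}") from None


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (possibly softmasked) FASTA file into a GenomeSequence.

    Lowercase bases are folded to uppercase; contig order is preserved.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found (empty or malformed file)")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise ParseError(f"{path}: duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: contig {rec.id!r} contains invalid character(s) {sorted(bad)}"
            )
        if not seq:
            raise ParseError(f"{path}: contig {rec.id!r} has an empty sequence")
        contigs[rec.id] = seq
    return GenomeSequence(contigs)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED6 file (chrom, start, end, name, score, strand).

    Strand is required; the score column is retained on each interval
    (predictions store their probability there).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 6 BED columns "
                    f"(chrom, start, end, name, score, strand), got {len(fields)}"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer start/end") from None
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid span [{start}, {end})"
                )
            if strand not in STRANDS:
                raise ParseError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            try:
                score: float | None = float(score_s)
            except ValueError:
                score = None
            intervals.append(
                GenomicInterval(chrom, start, end, strand, name=name, score=score)
            )
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    scores: Sequence[float] | None,
    path: str | Path,
) -> None:
    """Write BED6; scores (probabilities in [0,1]) go in column 5 with six
    decimals so the file round-trips losslessly through :func:`read_bed`."""
    if scores is None:
        scores = [iv.score if iv.score is not None else 0.0 for iv in intervals]
    if len(scores) != len(intervals):
        raise ValueError(
            f"{len(intervals)} intervals but {len(scores)} scores"
        )
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score {s} outside [0, 1]")
    with open(path, "w") as fh:
        for iv, s in zip(intervals, scores):
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{s:.6f}\t{iv.strand}\n"
            )


def fetch_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Extract the 5'->3' sequence of an interval.

    Plus-strand intervals return the forward slice; minus-strand intervals
    return its reverse complement.
    """
    length = genome.contig_length(iv.contig)
    if iv.end > length:
        raise CoordinateError(
            f"interval {iv} extends past contig end ({length} bp)"
        )
    seq = genome.contigs[iv.contig][iv.start : iv.end]
    return seq if iv.strand == "+" else reverse_complement(seq)
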