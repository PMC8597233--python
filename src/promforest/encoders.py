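"""Sequence encodings consumed by the random-forest classifiers.

Two feature spaces are supported:

* **HOT** — positional one-hot encoding of a fixed-length 40-nt sequence.
  Each base maps to a 4-bit indicator in channel order A, G, C, T
  (A=1000, G=0100, C=0010, T=0001); an ambiguous N leaves its block all
  zero.  The vector is position-major, 40 x 4 = 160 features.

* **TETRA** — tetra-nucleotide (4-mer) frequencies.  Overlapping 4-mers
  are counted with step 1 and divided by the number of valid 4-mers;
  windows containing N are excluded from numerator and denominator.
  Features are the 256 4-mers in lexicographic order (A < C < G < T).

The encoders are strand-agnostic: callers decide which strand's sequence
is passed in (the scanner reverse-complements minus-strand windows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import LabeledSequenceSet

SEQUENCE_LENGTH = 40

#: one-hot channel order fixed by the A=1000 ... T=0001 convention
HOT_CHANNELS = "AGCT"
N_HOT_FEATURES = SEQUENCE_LENGTH * 4

#: lexicographic base order for the 4-mer feature index
TETRA_BASES = "ACGT"
N_TETRA_FEATURES = 4 ** 4

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level lookup tables: base -> channel / lexicographic code, 255 = N/other
_HOT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(HOT_CHANNELS):
    _HOT_CODE[ord(_b)] = _i
_LEX_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(TETRA_BASES):
    _LEX_CODE[ord(_b)] = _i


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T, N}."""


class ShapeError(ValueError):
    """Sequence length incompatible with the requested encoding."""


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise AlphabetError(
            f"invalid nucleotide(s) {sorted(bad)}; expected only A/C/G/T/N"
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N)."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a 40-nt sequence as a 160-dim binary vector.

    Position-major: features 4*i .. 4*i+3 are the A,G,C,T indicators of
    base i.  N yields an all-zero block.
    """
    if len(seq) != SEQUENCE_LENGTH:
        raise ShapeError(
            f"one-hot encoding requires length {SEQUENCE_LENGTH}, got {len(seq)}"
        )
    _check_alphabet(seq)
    return _one_hot_from_codes(
        _HOT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][None, :]
    )[0]


def _one_hot_from_codes(codes: np.ndarray) -> np.ndarray:
    """(n, 40) channel codes (255 = N) -> (n, 160) float one-hot matrix."""
    hot = codes[:, :, None] == np.arange(4, dtype=np.uint8)[None, None, :]
    return hot.reshape(codes.shape[0], -1).astype(np.float64)


def one_hot_encode_batch(seqs: Sequence[str]) -> np.ndarray:
    """Vectorised one-hot encoding of equal-length 40-nt sequences."""
    if len(seqs) == 0:
        return np.empty((0, N_HOT_FEATURES))
    joined = "".join(seqs)
    if len(joined) != SEQUENCE_LENGTH * len(seqs):
        raise ShapeError(f"all sequences must have length {SEQUENCE_LENGTH}")
    raw = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    codes = _HOT_CODE[raw].reshape(len(seqs), SEQUENCE_LENGTH)
    if np.any((codes == 255) & ~np.isin(raw.reshape(codes.shape), [ord("N")])):
        raise AlphabetError("invalid nucleotide in batch; expected A/C/G/T/N")
    return _one_hot_from_codes(codes)


def one_hot_decode(vec: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero blocks decode to N."""
    vec = np.asarray(vec)
    if vec.shape != (N_HOT_FEATURES,):
        raise ShapeError(f"expected shape ({N_HOT_FEATURES},), got {vec.shape}")
    blocks = vec.reshape(SEQUENCE_LENGTH, 4)
    out = []
    for block in blocks:
        hits = np.flatnonzero(block)
        if hits.size == 0:
            out.append("N")
        elif hits.size == 1:
            out.append(HOT_CHANNELS[hits[0]])
        else:
            raise ValueError("one-hot block with more than one bit set")
    return "".join(out)


def tetra_freq_encode(seq: str, k: int = 4) -> np.ndarray:
    """Overlapping k-mer (default 4) frequency vector of a sequence.

    Counts of each 4-mer divided by the number of valid 4-mers in the
    sequence; 4-mers containing N are dropped from both numerator and
    denominator (an N-free 40-mer has denominator 37).
    """
    if k != 4:
        raise ValueError("only k=4 (tetra-nucleotide) frequencies are supported")
    if len(seq) < k:
        raise ShapeError(f"need length >= {k} for {k}-mer frequencies, got {len(seq)}")
    _check_alphabet(seq)
    codes = _LEX_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    n_win = len(seq) - k + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~np.any(win == 255, axis=1)
    freqs = np.zeros(N_TETRA_FEATURES)
    if valid.any():
        idx = win[valid] @ (4 ** np.arange(k - 1, -1, -1))
        np.add.at(freqs, idx, 1.0)
        freqs /= valid.sum()
    return freqs


def hot_feature_names() -> list[str]:
    """Names ``pos-39:A`` ... ``pos0:T`` — positions labelled -39..0 TSS-relative."""
    return [
        f"pos{i - (SEQUENCE_LENGTH - 1)}:{base}"
        for i in range(SEQUENCE_LENGTH)
        for base in HOT_CHANNELS
    ]


def tetra_feature_names() -> list[str]:
    """The 256 4-mers in lexicographic order AAAA ... TTTT."""
    names = []
    for a in TETRA_BASES:
        for b in TETRA_BASES:
            for c in TETRA_BASES:
                for d in TETRA_BASES:
                    names.append(a + b + c + d)
    return names


@dataclass
class FeatureMatrix:
    """Encoded rows aligned with a labelled sequence set."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    encoder_tag: str

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ShapeError("feature matrix and label vector row counts differ")
        if self.X.shape[1] != len(self.feature_names) and self.X.shape[0] > 0:
            raise ShapeError("feature name count does not match matrix width")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def _normalise_tag(encoder: str) -> str:
    tag = encoder.upper()
    if tag not in ("HOT", "TETRA"):
        raise ValueError(f"unknown encoder {encoder!r}; expected 'HOT' or 'TETRA'")
    return tag


def encode_sequences(seqs: Sequence[str], encoder: str) -> np.ndarray:
    """Encode sequences into a feature matrix by encoder tag."""
    tag = _normalise_tag(encoder)
    if tag == "HOT":
        return one_hot_encode_batch(list(seqs))
    rows = np.empty((len(seqs), N_TETRA_FEATURES))
    for i, s in enumerate(seqs):
        try:
            rows[i] = tetra_freq_encode(s)
        except (AlphabetError, ShapeError) as exc:
            raise type(exc)(f"record {i}: {exc}") from exc
    return rows


def encode_set(ds: "LabeledSequenceSet", encoder: str) -> FeatureMatrix:
    """Encode every record of a labelled sequence set into a FeatureMatrix."""
    tag = _normalise_tag(encoder)
    names = hot_feature_names() if tag == "HOT" else tetra_feature_names()
    seqs = [r.sequence for r in ds.records]
    y = np.array([r.label for r in ds.records], dtype=np.int64)
    if not seqs:
        width = N_HOT_FEATURES if tag == "HOT" else N_TETRA_FEATURES
        return FeatureMatrix(np.empty((0, width)), y, names, tag)
    try:
        X = encode_sequences(seqs, tag)
    except (AlphabetError, ShapeError):
        # re-raise with the offending record index for debuggability
        for i, s in enumerate(seqs):
            try:
                encode_sequences([s], tag)
            except (AlphabetError, ShapeError) as exc:
                raise type(exc)(f"record {i}: {exc}") from exc
        raise
    return FeatureMatrix(X, y, names, tag)
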