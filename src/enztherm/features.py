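"""Numeric sequence representations and pairwise sequence identity.

Encoders follow the scikit-learn transformer protocol (``fit`` on training
sequences only, ``transform`` on any sequences), so they drop into pipelines
and so that per-fold fitting inside cross-validation is natural. Supported
schemes:

``ngram``
    Overlapping n-gram counts, n in 1..4; n=1 is the bag-of-words residue
    composition. The vocabulary is fitted on training sequences only
    (lexicographic order); query n-grams unseen in training are dropped.
``onehot``
    Positional one-hot encoding padded to a fixed maximum length
    (20 columns per position).
``blosum45`` / ``blosum62``
    Per-position substitution-score rows over a shared multiple sequence
    alignment: each aligned position contributes the 20 BLOSUM scores of the
    residue observed there; gaps contribute zeros. The alignment is either
    supplied (aligned FASTA from any standard MSA tool) or built by a naive
    star alignment against the longest training sequence.
``embedding_table``
    Precomputed fixed-length vectors (e.g. protein language-model embeddings)
    looked up by sequence id; never computed in-process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, ValidationError
from .records import CANONICAL_RESIDUES, SequenceSet

logger = logging.getLogger(__name__)

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureMatrix:
    """A dense feature matrix with row ids and named columns."""

    row_ids: list[str]
    values: np.ndarray
    feature_names: list[str]
    scheme: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-dimensional")
        if self.values.shape[0] != len(self.row_ids):
            raise ValidationError("row count does not match row_ids")
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError("column count does not match feature_names")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_names)


@dataclass
class EncoderConfig:
    """A fitted encoder description (scheme plus its fitted state)."""

    scheme: str
    n: int | None = None
    max_len: int | None = None
    vocabulary: list[str] = field(default_factory=list)
    alignment_required: bool = False


@dataclass
class AlignmentSet:
    """Equal-length aligned sequences keyed by id; gap character '-'."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) > 1:
            raise ValidationError("aligned sequences have unequal lengths")

    @property
    def length(self) -> int:
        return len(next(iter(self.entries.values()))) if self.entries else 0

    def __getitem__(self, sid: str) -> str:
        return self.entries[sid]

    def degapped(self) -> dict[str, str]:
        return {sid: s.replace("-", "") for sid, s in self.entries.items()}


# ---------------------------------------------------------------------------
# pairwise identity

# Match-maximizing global alignment. The infinitesimal gap penalty keeps the
# match count maximal while preferring the most compact (fewest-gap) optimal
# alignment, which pins down the alignment-length denominator.
_GAP_EPS = 1e-6


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -_GAP_EPS
    aligner.extend_gap_score = -_GAP_EPS
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Alignment maximizes the number of matching residues (match=1, mismatch=0,
    gap=0); identity = matches / alignment length. Symmetric, and 1.0 exactly
    iff the sequences are identical.
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    if a == b:
        return 1.0
    alignment = _make_aligner().align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def max_identity_to_set(query: str, training: SequenceSet | Iterable[str]) -> float:
    """Highest pairwise identity between ``query`` and any training sequence."""
    seqs = training.sequences() if isinstance(training, SequenceSet) else list(training)
    if not seqs:
        raise ValidationError("training set is empty")
    return max(pairwise_identity(query, s) for s in seqs)


def align_to_reference(sequence: str, reference: str) -> str:
    """Project ``sequence`` onto the reference's coordinates.

    Each reference position receives the residue aligned to it ('-' for a
    gap); residues inserted relative to the reference are dropped (with a
    warning), so the result always has ``len(reference)`` columns.
    """
    if sequence == reference:
        return sequence
    alignment = _make_aligner().align(reference, sequence)[0]
    ref_row, seq_row = str(alignment[0]), str(alignment[1])
    out = []
    dropped = 0
    for ref_ch, seq_ch in zip(ref_row, seq_row):
        if ref_ch == "-":
            dropped += seq_ch != "-"
            continue
        out.append(seq_ch)
    if dropped:
        logger.warning(
            "star alignment dropped %d residue(s) inserted relative to the reference",
            dropped,
        )
    return "".join(out)


def star_align(sequences: SequenceSet, reference_id: str | None = None) -> AlignmentSet:
    """Naive star alignment: align every sequence to the longest one pairwise.

    A testing fallback, not a progressive MSA; insertions relative to the
    reference are dropped. Prefer supplying an aligned FASTA from a real
    MSA tool.
    """
    if len(sequences) == 0:
        raise ValidationError("cannot align an empty sequence set")
    if reference_id is None:
        reference_id = max(sequences.ids, key=lambda sid: len(sequences[sid]))
    reference = sequences[reference_id]
    return AlignmentSet(
        {sid: align_to_reference(seq, reference) for sid, seq in sequences.items()}
    )


def load_alignment(path: str | Path) -> AlignmentSet:
    """Load an aligned FASTA (equal-length rows, '-' gaps)."""
    from Bio import SeqIO

    entries: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in entries:
            raise ValidationError(f"duplicate id {entry.id!r} in alignment")
        entries[entry.id] = str(entry.seq).upper()
    if not entries:
        raise ValidationError(f"no sequences in alignment file {path}")
    return AlignmentSet(entries)


# ---------------------------------------------------------------------------
# encoders (sklearn transformers over lists of sequence strings)


class NGramEncoder(TransformerMixin, BaseEstimator):
    """Overlapping n-gram count encoding; n=1 is bag-of-words composition.

    The vocabulary is the lexicographically sorted set of n-grams observed in
    the training sequences. Query n-grams outside the vocabulary contribute
    nothing (logged at debug level).
    """

    def __init__(self, n: int = 1):
        self.n = n

    def fit(self, X: Sequence[str], y: object = None) -> "NGramEncoder":
        if not 1 <= self.n <= 4:
            raise ConfigError(f"n must be in 1..4, got {self.n}")
        vocab: set[str] = set()
        for seq in X:
            if len(seq) < self.n:
                raise ValidationError(
                    f"sequence {seq!r} is shorter than n={self.n}"
                )
            vocab.update(seq[i : i + self.n] for i in range(len(seq) - self.n + 1))
        self.vocabulary_ = sorted(vocab)
        self._index_ = {g: i for i, g in enumerate(self.vocabulary_)}
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        index = self._index_
        out = np.zeros((len(X), len(self.vocabulary_)), dtype=float)
        unknown = 0
        for row, seq in enumerate(X):
            for i in range(len(seq) - self.n + 1):
                col = index.get(seq[i : i + self.n])
                if col is None:
                    unknown += 1
                else:
                    out[row, col] += 1.0
        if unknown:
            logger.debug("%d n-gram(s) outside the fitted vocabulary ignored", unknown)
        return out

    def get_feature_names_out(self, input_features: object = None) -> np.ndarray:
        return np.asarray(self.vocabulary_, dtype=object)

    def config(self) -> EncoderConfig:
        return EncoderConfig(scheme="ngram", n=self.n, vocabulary=list(self.vocabulary_))


class OneHotEncoder(TransformerMixin, BaseEstimator):
    """Positional one-hot encoding padded to ``max_len`` (20 cols/position)."""

    def __init__(self, max_len: int | None = None):
        self.max_len = max_len

    def fit(self, X: Sequence[str], y: object = None) -> "OneHotEncoder":
        longest = max((len(s) for s in X), default=0)
        if self.max_len is None:
            self.max_len_ = longest
        else:
            if self.max_len < longest:
                raise ConfigError(
                    f"max_len={self.max_len} shorter than longest training "
                    f"sequence ({longest})"
                )
            self.max_len_ = self.max_len
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(X), 20 * self.max_len_), dtype=float)
        for row, seq in enumerate(X):
            if len(seq) > self.max_len_:
                raise ValidationError(
                    f"sequence of length {len(seq)} exceeds max_len={self.max_len_}"
                )
            for pos, aa in enumerate(seq):
                out[row, 20 * pos + _RESIDUE_INDEX[aa]] = 1.0
        return out

    def get_feature_names_out(self, input_features: object = None) -> np.ndarray:
        return np.asarray(
            [
                f"pos{p + 1}_{aa}"
                for p in range(self.max_len_)
                for aa in CANONICAL_RESIDUES
            ],
            dtype=object,
        )


class BlosumEncoder(TransformerMixin, BaseEstimator):
    """BLOSUM substitution-score encoding over a shared alignment frame.

    With a precomputed ``alignment`` (an :class:`AlignmentSet` keyed by the
    raw sequence string), sequences are looked up directly. Otherwise ``fit``
    records the longest training sequence as the alignment reference and
    ``transform`` projects each sequence onto it via a pairwise global
    alignment (the star-alignment fallback).
    """

    def __init__(self, matrix_name: str = "BLOSUM62", alignment: AlignmentSet | None = None):
        self.matrix_name = matrix_name
        self.alignment = alignment

    def _matrix(self):
        name = self.matrix_name.upper()
        if name not in ("BLOSUM45", "BLOSUM62"):
            raise ConfigError(f"unknown substitution matrix {self.matrix_name!r}")
        return substitution_matrices.load(name)

    def fit(self, X: Sequence[str], y: object = None) -> "BlosumEncoder":
        matrix = self._matrix()
        self._rows_ = {
            aa: np.array([matrix[aa, bb] for bb in CANONICAL_RESIDUES], dtype=float)
            for aa in CANONICAL_RESIDUES
        }
        if self.alignment is not None:
            self._by_sequence_ = {
                raw: aligned
                for (sid, aligned), raw in zip(
                    self.alignment.entries.items(), self.alignment.degapped().values()
                )
            }
            self.n_positions_ = self.alignment.length
            self.reference_ = None
        else:
            self._by_sequence_ = {}
            self.reference_ = max(X, key=len) if len(X) else ""
            self.n_positions_ = len(self.reference_)
        return self

    def _aligned(self, seq: str) -> str:
        if seq in self._by_sequence_:
            return self._by_sequence_[seq]
        if self.reference_ is None:
            raise ValidationError(
                "sequence not present in the supplied alignment and no "
                "star-alignment reference is available"
            )
        return align_to_reference(seq, self.reference_)

    def transform(self, X: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(X), 20 * self.n_positions_), dtype=float)
        for row, seq in enumerate(X):
            aligned = self._aligned(seq)
            for pos, aa in enumerate(aligned):
                if aa == "-":
                    continue  # gaps encode as zero vectors
                if aa not in self._rows_:
                    raise ValidationError(f"non-canonical residue {aa!r} in alignment")
                out[row, 20 * pos : 20 * (pos + 1)] = self._rows_[aa]
        return out

    def get_feature_names_out(self, input_features: object = None) -> np.ndarray:
        return np.asarray(
            [
                f"col{p + 1}_{aa}"
                for p in range(self.n_positions_)
                for aa in CANONICAL_RESIDUES
            ],
            dtype=object,
        )


class EmbeddingTableEncoder(TransformerMixin, BaseEstimator):
    """Lookup of precomputed fixed-length vectors keyed by sequence id.

    An injection point for external representations (e.g. protein
    language-model embeddings computed offline); transform input is a list of
    sequence ids, not sequences.
    """

    keyed_by = "id"

    def __init__(self, table: "FeatureMatrix | Mapping[str, Sequence[float]]" = ()):
        self.table = table

    def fit(self, X: Sequence[str] = (), y: object = None) -> "EmbeddingTableEncoder":
        if isinstance(self.table, FeatureMatrix):
            self._vectors_ = {
                sid: self.table.values[i] for i, sid in enumerate(self.table.row_ids)
            }
            self.n_dims_ = self.table.shape[1]
        else:
            self._vectors_ = {k: np.asarray(v, dtype=float) for k, v in dict(self.table).items()}
            lengths = {v.shape[0] for v in self._vectors_.values()}
            if len(lengths) > 1:
                raise ValidationError("embedding vectors have ragged lengths")
            self.n_dims_ = lengths.pop() if lengths else 0
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        missing = [sid for sid in X if sid not in self._vectors_]
        if missing:
            raise ValidationError(f"ids absent from embedding table: {missing}")
        if not len(X):
            return np.zeros((0, self.n_dims_))
        return np.vstack([self._vectors_[sid] for sid in X])

    def get_feature_names_out(self, input_features: object = None) -> np.ndarray:
        return np.asarray([f"emb{i}" for i in range(self.n_dims_)], dtype=object)


def load_embedding_table(path: str | Path) -> FeatureMatrix:
    """Load a TSV embedding table: first column id, remaining columns floats."""
    df = pd.read_csv(path, sep="\t", header=None)
    ids = df.iloc[:, 0].astype(str).tolist()
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric embedding values: {exc}") from None
    if df.iloc[:, 1:].isna().any().any():
        raise ValidationError("ragged or missing embedding values")
    return FeatureMatrix(
        row_ids=ids,
        values=values,
        feature_names=[f"emb{i}" for i in range(values.shape[1])],
        scheme="embedding_table",
    )


# ---------------------------------------------------------------------------
# functional wrappers (thin, over the transformers)


def fit_ngram_encoder(train_sequences: SequenceSet, n: int) -> EncoderConfig:
    return NGramEncoder(n=n).fit(train_sequences.sequences()).config()


def encode_ngram(sequences: SequenceSet, config: EncoderConfig) -> FeatureMatrix:
    encoder = NGramEncoder(n=config.n or 1)
    encoder.vocabulary_ = list(config.vocabulary)
    encoder._index_ = {g: i for i, g in enumerate(encoder.vocabulary_)}
    values = encoder.transform(sequences.sequences())
    return FeatureMatrix(sequences.ids, values, list(config.vocabulary), "ngram")


def encode_onehot(sequences: SequenceSet, max_len: int) -> FeatureMatrix:
    encoder = OneHotEncoder(max_len=max_len)
    encoder.max_len_ = max_len
    values = encoder.transform(sequences.sequences())
    return FeatureMatrix(
        sequences.ids, values, list(encoder.get_feature_names_out()), "onehot"
    )


def encode_blosum(alignment: AlignmentSet, matrix_name: str = "BLOSUM62") -> FeatureMatrix:
    encoder = BlosumEncoder(matrix_name=matrix_name, alignment=alignment)
    encoder.fit([])
    ids = list(alignment.entries)
    values = np.zeros((len(ids), 20 * alignment.length))
    for row, sid in enumerate(ids):
        aligned = alignment[sid]
        for pos, aa in enumerate(aligned):
            if aa == "-":
                continue
            if aa not in encoder._rows_:
                raise ValidationError(f"non-canonical residue {aa!r} in alignment")
            values[row, 20 * pos : 20 * (pos + 1)] = encoder._rows_[aa]
    return FeatureMatrix(
        ids, values, list(encoder.get_feature_names_out()), encoder.matrix_name.lower()
    )


def concat_temperature(
    features: FeatureMatrix, temperatures: Sequence[float], mode: str = "absolute_C"
) -> FeatureMatrix:
    """Append a trailing temperature column (absolute or relative degrees C)."""
    if mode not in ("absolute_C", "relative_C"):
        raise ConfigError(f"unknown temperature mode {mode!r}")
    temps = np.asarray(temperatures, dtype=float)
    if temps.shape[0] != features.shape[0]:
        raise ValidationError(
            f"temperature count {temps.shape[0]} does not match row count "
            f"{features.shape[0]}"
        )
    values = np.hstack([features.values, temps.reshape(-1, 1)])
    return FeatureMatrix(
        list(features.row_ids),
        values,
        list(features.feature_names) + ["temperature"],
        features.scheme,
    )
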