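"""Activity-table and sequence I/O.

The canonical unit of data is the :class:`ActivityRecord`: one measured (or
curve-estimated) catalytic efficiency ``kcat/Km`` for one enzyme sequence at one
assay temperature. kcat/Km is stored on the linear scale (mM^-1 s^-1) at I/O
time; all log10 transforms happen downstream so provenance stays auditable.

Replicate measurements — the same (sequence_id, temperature) appearing twice —
are retained as distinct records; downstream maximum-selection handles them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .exceptions import ConsistencyError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical one-letter codes.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Canonical activity-table columns, in file order.
ACTIVITY_COLUMNS = (
    "sequence_id",
    "sequence",
    "temperature_C",
    "kcat_km_mM_s",
    "is_wild_type",
    "is_estimated",
    "source",
)
_REQUIRED_COLUMNS = ACTIVITY_COLUMNS[:4]


@dataclass(frozen=True)
class ActivityRecord:
    """One kcat/Km measurement at one temperature for one sequence.

    Attributes
    ----------
    sequence_id : opaque string key; maps to exactly one sequence string.
    sequence : amino-acid string over the canonical 20-letter alphabet.
    temperature_C : assay temperature in degrees Celsius.
    kcat_km : catalytic efficiency in mM^-1 s^-1, linear scale, > 0.
    is_wild_type : True for wild-type enzymes, False for mutants.
    is_estimated : True if derived from an activity-temperature curve rather
        than directly reported.
    source : free-text provenance.
    """

    sequence_id: str
    sequence: str
    temperature_C: float
    kcat_km: float
    is_wild_type: bool = True
    is_estimated: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.sequence_id!r}: empty sequence")
        if not (self.kcat_km > 0) or not math.isfinite(self.kcat_km):
            raise ValidationError(
                f"record {self.sequence_id!r}: kcat_km must be a positive finite "
                f"number, got {self.kcat_km!r}"
            )
        if not math.isfinite(self.temperature_C):
            raise ValidationError(
                f"record {self.sequence_id!r}: non-finite temperature"
            )
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise ValidationError(
                f"record {self.sequence_id!r}: non-canonical residues {sorted(bad)}"
            )


class SequenceSet:
    """Ordered, duplicate-free mapping sequence_id -> amino-acid sequence."""

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        self._entries: dict[str, str] = {}
        items = entries.items() if isinstance(entries, Mapping) else entries
        for sid, seq in items:
            self.add(sid, seq)

    def add(self, sequence_id: str, sequence: str) -> None:
        if sequence_id in self._entries:
            raise ConsistencyError(f"duplicate sequence id {sequence_id!r}")
        if not sequence:
            raise ValidationError(f"sequence {sequence_id!r} is empty")
        self._entries[sequence_id] = sequence

    @property
    def ids(self) -> list[str]:
        return list(self._entries)

    def __getitem__(self, sequence_id: str) -> str:
        return self._entries[sequence_id]

    def __contains__(self, sequence_id: object) -> bool:
        return sequence_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._entries.items()

    def sequences(self) -> list[str]:
        return list(self._entries.values())

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        return SequenceSet((sid, self._entries[sid]) for sid in ids)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SequenceSet) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"SequenceSet({len(self)} sequences)"


def normalize_residues(sequence: str, policy: str = "strict") -> str:
    """Uppercase a sequence and resolve non-canonical characters.

    ``strict`` raises on any character outside the 20 canonical residues,
    naming the offending character and its 1-based position.
    ``drop_nonstandard`` removes such characters and logs a warning.
    """
    if policy not in ("strict", "drop_nonstandard"):
        raise ValidationError(f"unknown normalization policy {policy!r}")
    upper = sequence.upper()
    if policy == "strict":
        for pos, ch in enumerate(upper, start=1):
            if ch not in _CANONICAL_SET:
                raise ValidationError(
                    f"non-canonical residue {ch!r} at position {pos}"
                )
        return upper
    kept = [ch for ch in upper if ch in _CANONICAL_SET]
    dropped = len(upper) - len(kept)
    if dropped:
        logger.warning("dropped %d non-canonical residue(s) from sequence", dropped)
    return "".join(kept)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "t", "1", "yes", "wt", "wild_type"):
        return True
    if text in ("false", "f", "0", "no", "mutant"):
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean")


def read_activity_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    residue_policy: str = "strict",
) -> list[ActivityRecord]:
    """Read an activity table (CSV/TSV) into validated records.

    Parameters
    ----------
    path : file with one header row; delimiter sniffed unless ``delimiter``
        is given.
    schema : optional map from canonical column names (``sequence_id``,
        ``sequence``, ``temperature_C``, ``kcat_km_mM_s``, ``is_wild_type``,
        ``is_estimated``, ``source``) to the file's column names, for
        adapting foreign tables.
    residue_policy : passed to :func:`normalize_residues`.

    Rows are preserved in file order; duplicate (sequence_id, temperature)
    rows are kept as distinct records. Row-level problems raise
    :class:`ValidationError` citing the 1-based data-row index.
    """
    path = Path(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    colmap = {name: name for name in ACTIVITY_COLUMNS}
    if schema:
        colmap.update(schema)
    for canonical in _REQUIRED_COLUMNS:
        if colmap[canonical] not in df.columns:
            raise SchemaError(
                f"missing required column {colmap[canonical]!r} (for {canonical})"
            )

    records: list[ActivityRecord] = []
    seq_by_id: dict[str, str] = {}
    for row_index, row in enumerate(df.itertuples(index=False), start=1):
        row_dict = dict(zip(df.columns, row))

        def get(canonical: str, default: object = None) -> object:
            col = colmap[canonical]
            if col in df.columns:
                value = row_dict[col]
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    return default
                return value
            return default

        raw_kcat = get("kcat_km_mM_s")
        try:
            kcat = float(raw_kcat)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {row_index}: non-numeric kcat_km value {raw_kcat!r}"
            ) from None
        if not kcat > 0:
            raise ValidationError(
                f"row {row_index}: kcat_km must be positive, got {raw_kcat!r}"
            )
        try:
            temperature = float(get("temperature_C"))  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {row_index}: non-numeric temperature "
                f"{get('temperature_C')!r}"
            ) from None

        sid = str(get("sequence_id"))
        try:
            sequence = normalize_residues(str(get("sequence")), residue_policy)
        except ValidationError as exc:
            raise ValidationError(f"row {row_index}: {exc}") from None
        if sid in seq_by_id and seq_by_id[sid] != sequence:
            raise ConsistencyError(
                f"row {row_index}: sequence_id {sid!r} maps to two different "
                "sequence strings"
            )
        seq_by_id[sid] = sequence

        records.append(
            ActivityRecord(
                sequence_id=sid,
                sequence=sequence,
                temperature_C=temperature,
                kcat_km=kcat,
                is_wild_type=_parse_bool(get("is_wild_type", True)),
                is_estimated=_parse_bool(get("is_estimated", False)),
                source=str(get("source", "") or ""),
            )
        )
    return records


def write_activity_table(
    records: Iterable[ActivityRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records in the canonical column order at full float precision."""
    rows = [
        {
            "sequence_id": r.sequence_id,
            "sequence": r.sequence,
            "temperature_C": r.temperature_C,
            "kcat_km_mM_s": r.kcat_km,
            "is_wild_type": r.is_wild_type,
            "is_estimated": r.is_estimated,
            "source": r.source,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS))
    # repr-based float rendering round-trips exactly
    df.to_csv(path, sep=delimiter, index=False, float_format=None)


def load_sequences(path: str | Path, residue_policy: str = "strict") -> SequenceSet:
    """Load a FASTA file into a :class:`SequenceSet`.

    The sequence_id is the first whitespace-delimited token of each header;
    residues are uppercased. Duplicate ids and empty entries are errors.
    """
    sequences = SequenceSet()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_residues(str(entry.seq), residue_policy)
        if not seq:
            raise ValidationError(f"FASTA entry {entry.id!r} has an empty sequence")
        sequences.add(entry.id, seq)
    return sequences


def sequences_from_records(records: Iterable[ActivityRecord]) -> SequenceSet:
    """Collect the unique (id, sequence) pairs of a record list, in first-seen order."""
    sequences = SequenceSet()
    for record in records:
        if record.sequence_id in sequences:
            if sequences[record.sequence_id] != record.sequence:
                raise ConsistencyError(
                    f"sequence_id {record.sequence_id!r} maps to two different "
                    "sequence strings"
                )
        else:
            sequences.add(record.sequence_id, record.sequence)
    return sequences
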