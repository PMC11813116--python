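"""Reading and writing of the external representations the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython's SeqIO; this module adds
alphabet validation, id bookkeeping and the pairing logic, and defines the
plain-text tabular conventions used throughout (TSV, UTF-8, ``NA`` for
missing values).

Internally every sequence is stored in the DNA alphabet; RNA input (mature
miRNAs are catalogued with U) is converted U→T at this boundary and back on
output, so downstream alignment code works over a single comparison alphabet.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "ReadPair",
    "CountMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_count_matrix",
    "write_count_matrix",
    "write_table",
    "read_table",
    "read_taxonomy_table",
    "revcomp",
    "rna_to_dna",
    "dna_to_rna",
]

_DNA_CHARS = frozenset("ACGT")
_RNA_CHARS = frozenset("ACGU")
_PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class FormatError(ValueError):
    """Raised for malformed or invalid external input."""


class Alphabet(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"
    PROTEIN = "PROTEIN"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence in a declared alphabet.

    ``id`` is the first whitespace-delimited token of the header; the full
    header is retained as ``description``.
    """

    id: str
    sequence: str
    alphabet: Alphabet = Alphabet.DNA
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        allowed = {
            Alphabet.DNA: _DNA_CHARS,
            Alphabet.RNA: _RNA_CHARS,
            Alphabet.PROTEIN: _PROTEIN_CHARS,
        }[self.alphabet]
        bad = set(self.sequence) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.alphabet.value} alphabet"
            )

    def as_dna(self) -> "SequenceRecord":
        if self.alphabet is Alphabet.DNA:
            return self
        return SequenceRecord(
            self.id, rna_to_dna(self.sequence), Alphabet.DNA, self.description
        )

    def as_rna(self) -> "SequenceRecord":
        if self.alphabet is Alphabet.RNA:
            return self
        return SequenceRecord(
            self.id, dna_to_rna(self.sequence), Alphabet.RNA, self.description
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """A paired-end metagenomic read; both mates share one id."""

    id: str
    mate1: SequenceRecord
    mate2: SequenceRecord
    sample_id: str = ""

    def __post_init__(self) -> None:
        for mate in (self.mate1, self.mate2):
            if mate.alphabet is not Alphabet.DNA:
                raise FormatError(f"read pair {self.id!r}: mates must be DNA")


@dataclass
class CountMatrix:
    """A samples × features matrix of nonnegative integer counts."""

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise FormatError("non-integer cell in count matrix")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def totals(self) -> pd.Series:
        return self.to_frame().sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.DNA) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records, order preserved.

    U↔T is *not* applied here: the record keeps the characters of the file
    and must therefore be valid in ``alphabet``. Use ``as_dna``/``as_rna``
    for conversion.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: sequence line before first header")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                rec.id, str(rec.seq).upper(), alphabet, rec.description
            )
        )
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n{rec.sequence}\n")


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path, sample_id: str = ""
) -> list[ReadPair]:
    """Pair R1/R2 FASTQ files positionally into ReadPairs.

    Quality strings are validated (length must match the sequence) but not
    retained. Mate ids may carry /1 and /2 suffixes; the shared pair id is
    the R1 id with any such suffix stripped.
    """

    def _records(path):
        try:
            yield from SeqIO.parse(str(path), "fastq")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc

    pairs: list[ReadPair] = []
    it1, it2 = _records(path_r1), _records(path_r2)
    for rec1 in it1:
        rec2 = next(it2, None)
        if rec2 is None:
            raise FormatError(
                f"{path_r2} has fewer records than {path_r1} (pairing error)"
            )
        pair_id = rec1.id.removesuffix("/1")
        pairs.append(
            ReadPair(
                pair_id,
                SequenceRecord(rec1.id, str(rec1.seq).upper(), Alphabet.DNA),
                SequenceRecord(rec2.id, str(rec2.seq).upper(), Alphabet.DNA),
                sample_id,
            )
        )
    if next(it2, None) is not None:
        raise FormatError(
            f"{path_r1} has fewer records than {path_r2} (pairing error)"
        )
    return pairs


def write_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path, pairs: Iterable[ReadPair]
) -> None:
    """Write pairs as two synchronized FASTQ files (constant quality I)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.id}/1\n{pair.mate1.sequence}\n+\n"
                     f"{'I' * len(pair.mate1.sequence)}\n")
            f2.write(f"@{pair.id}/2\n{pair.mate2.sequence}\n+\n"
                     f"{'I' * len(pair.mate2.sequence)}\n")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix: first column sample id, header of feature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.astype(np.int64)
    except ValueError as exc:
        bad = None
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    int(cell)
                except (TypeError, ValueError):
                    bad = (df.index[i], df.columns[j], cell)
                    break
            if bad:
                break
        if bad:
            raise FormatError(
                f"{path}: non-integer cell {bad[2]!r} at row {bad[0]!r}, "
                f"column {bad[1]!r}"
            ) from exc
        raise
    try:
        return CountMatrix.from_frame(values)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_matrix(path: str | Path, matrix: CountMatrix) -> None:
    df = matrix.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_table(path: str | Path, table: pd.DataFrame, index: bool = False) -> None:
    """Write any result table as TSV, UTF-8, missing values as NA."""
    table.to_csv(path, sep="\t", na_rep="NA", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy node table: node_id, parent_id, rank, name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"node_id", "parent_id", "rank", "name"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing taxonomy columns {sorted(missing)}")
    return df
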