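"""File formats and cut-up preprocessing.

The binner consumes assembled contigs (FASTA) plus a per-contig,
per-sample mean-coverage table (TSV with a header row).  It emits a
two-column contig-to-bin TSV.  Ground-truth species labels for
evaluation use the same two-column TSV shape.

Long assembled contigs are conventionally cut into ~10 kb fragments
before binning to dilute local assembly errors; :func:`cut_up_contigs`
implements that preprocessing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    CoverageMismatchError,
    DuplicateIdError,
    EmptyInputError,
    IllegalCharacterError,
    NegativeCoverageError,
    NonNumericCoverageError,
)

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class ContigRecord:
    """A single named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ContigSet:
    """An ordered collection of contigs; the order defines the row index
    used by every downstream matrix."""

    records: list[ContigRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise DuplicateIdError(f"duplicate contig id: {dup!r}")
        for r in self.records:
            if not r.id:
                raise EmptyInputError("contig with empty id")
            if r.length < 1:
                raise EmptyInputError(f"contig {r.id!r} has empty sequence")

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=np.int64)

    def subset(self, indices) -> "ContigSet":
        return ContigSet([self.records[i] for i in indices])

    def __len__(self) -> int:
        return self.N

    def __iter__(self) -> Iterator[ContigRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ContigRecord:
        return self.records[i]


@dataclass
class CoverageMatrix:
    """N x M matrix of mean read depth per contig (rows) per sample (cols)."""

    values: np.ndarray
    sample_ids: list[str]
    contig_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("coverage values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.contig_ids) or m != len(self.sample_ids):
            raise ValueError("coverage shape does not match id lists")
        if np.any(self.values < 0):
            raise NegativeCoverageError("negative coverage value")

    @property
    def M(self) -> int:
        return self.values.shape[1]


@dataclass
class BinningResult:
    """Final contig-to-bin assignment; labels are dense integers in [0, C)."""

    contig_ids: list[str]
    bin_labels: list[int]
    num_bins: int

    def __post_init__(self) -> None:
        if len(self.contig_ids) != len(self.bin_labels):
            raise ValueError("ids and labels differ in length")
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise DuplicateIdError("duplicate contig id in binning result")
        for lab in self.bin_labels:
            if not (0 <= int(lab) < self.num_bins):
                raise ValueError(f"bin label {lab} outside [0, {self.num_bins})")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.contig_ids, (int(b) for b in self.bin_labels)))


def read_fasta(path) -> ContigSet:
    """Read contigs from a FASTA file.

    Sequences are uppercased; any character outside {A,C,G,T,N} is
    rejected.  Record order in the file is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ContigRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise IllegalCharacterError(
                f"contig {rec.id!r} contains illegal characters {bad}"
            )
        records.append(ContigRecord(id=rec.id, sequence=seq))
    if not records:
        raise EmptyInputError(f"empty input: no FASTA records in {path}")
    return ContigSet(records)


def write_fasta(contigs: ContigSet, path, width: int = 80) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in contigs:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_coverage_table(path, contigs: ContigSet) -> CoverageMatrix:
    """Read a TSV coverage table and align its rows to the contig order.

    Expected layout: header ``contig_id<TAB>sample1<TAB>...`` and one row
    per contig.  The set of contig ids must match the FASTA exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise EmptyInputError(f"coverage table {path} has no sample columns")
    id_col = df.columns[0]
    table_ids = set(df[id_col])
    fasta_ids = set(contigs.ids)
    if table_ids != fasta_ids:
        missing = sorted(fasta_ids - table_ids)[:5]
        extra = sorted(table_ids - fasta_ids)[:5]
        raise CoverageMismatchError(
            f"coverage/contig mismatch (missing from table: {missing}, "
            f"unknown in table: {extra})"
        )
    if df[id_col].duplicated().any():
        raise DuplicateIdError("duplicate contig id in coverage table")
    sample_ids = [str(c) for c in df.columns[1:]]
    body = df.set_index(id_col).loc[contigs.ids, :]
    try:
        values = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise NonNumericCoverageError(f"non-numeric coverage value: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise NonNumericCoverageError("non-finite coverage value")
    if np.any(values < 0):
        raise NegativeCoverageError("negative coverage in table")
    return CoverageMatrix(values=values, sample_ids=sample_ids, contig_ids=list(contigs.ids))


def write_coverage_table(coverage: CoverageMatrix, path) -> None:
    df = pd.DataFrame(coverage.values, columns=coverage.sample_ids)
    df.insert(0, "contig_id", coverage.contig_ids)
    df.to_csv(path, sep="\t", index=False)


def cut_up_contigs(contigs: ContigSet, chunk_len: int = 10_000) -> ContigSet:
    """Split long contigs into consecutive non-overlapping ~chunk_len pieces.

    A contig of length >= 2*chunk_len is cut into floor(L / chunk_len)
    fragments; the final remainder (< chunk_len) is merged into the last
    fragment, so every fragment of a split contig has length in
    [chunk_len, 2*chunk_len).  Shorter contigs pass through intact and
    keep their original id.  Fragment ids are ``<parent>.<index>`` with a
    0-based index.  Total emitted bases equal total input bases.
    """
    if chunk_len < 1:
        raise ValueError("chunk_len must be >= 1")
    out: list[ContigRecord] = []
    for rec in contigs:
        L = rec.length
        if L < 2 * chunk_len:
            out.append(rec)
            continue
        n_frag = L // chunk_len
        for i in range(n_frag):
            start = i * chunk_len
            end = (i + 1) * chunk_len if i < n_frag - 1 else L
            out.append(ContigRecord(id=f"{rec.id}.{i}", sequence=rec.sequence[start:end]))
    return ContigSet(out)


def write_binning(result: BinningResult, path) -> None:
    """Write a contig-to-bin TSV (header ``contig_id<TAB>bin_id``)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("contig_id\tbin_id\n")
        for cid, lab in zip(result.contig_ids, result.bin_labels):
            fh.write(f"{cid}\t{int(lab)}\n")


def read_binning(path) -> BinningResult:
    """Read a contig-to-bin TSV written by :func:`write_binning`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "bin_id": int})
    labels = [int(x) for x in df["bin_id"]]
    num_bins = (max(labels) + 1) if labels else 0
    return BinningResult(
        contig_ids=[str(x) for x in df["contig_id"]],
        bin_labels=labels,
        num_bins=num_bins,
    )


def read_truth(path) -> dict[str, str]:
    """Read a two-column TSV mapping contig id to species label."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise EmptyInputError(f"truth table {path} needs two columns")
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        raise DuplicateIdError("duplicate contig id in truth table")
    return dict(zip(ids, df.iloc[:, 1]))


def write_truth(truth: Mapping[str, str], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("contig_id\tspecies_label\n")
        for cid, lab in truth.items():
            fh.write(f"{cid}\t{lab}\n")
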