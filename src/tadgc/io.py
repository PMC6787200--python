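"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (multi-record), BED3/4/6, sparse contact triplets (TSV) and
gene x tissue TPM expression tables (TSV). One coordinate convention is
enforced at this boundary: everything downstream sees 0-based half-open
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval

__all__ = [
    "FormatError",
    "BedRecord",
    "ExpressionTable",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_contacts",
    "read_expression",
    "write_expression",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered ``{name: sequence}`` map.

    Sequences are uppercased; N and IUPAC ambiguity codes are preserved.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: expected FASTA header '>' on line 1")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records parsed")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


@dataclass(frozen=True)
class BedRecord:
    """One BED line: an interval plus any extra columns, kept verbatim."""

    interval: GenomicInterval
    fields: tuple[str, ...] = ()

    @property
    def label(self) -> str | None:
        """First extra column (BED name/label), if present."""
        return self.fields[0] if self.fields else None


def read_bed(
    path: str | Path,
    min_columns: int = 3,
    one_based: bool = False,
) -> list[BedRecord]:
    """Read a BED file as 0-based half-open intervals.

    ``one_based=True`` converts 1-based inclusive input at this boundary
    (start is decremented); the rest of the package never re-interprets
    coordinates. Extra columns beyond the third are returned as strings.
    """
    path = Path(path)
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < max(3, min_columns):
                raise FormatError(
                    f"{path}:{lineno}: expected >= {max(3, min_columns)} "
                    f"tab-separated columns, got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate: {exc}"
                ) from exc
            if one_based:
                start -= 1
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"[{start}, {end})"
                )
            strand = "."
            extras = tuple(parts[3:])
            if len(parts) >= 6 and parts[5] in ("+", "-", "."):
                strand = parts[5]
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(BedRecord(iv, extras))
    return records


def write_bed(records: Sequence[BedRecord], path: str | Path) -> None:
    """Write BED records; round-trips canonical 3-column input byte-identically."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), *rec.fields]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Contacts (sparse triplets)


def read_contacts(
    path: str | Path,
    bin_size: int,
    chrom_sizes: Mapping[str, int],
):
    """Read a sparse triplet contact file into a symmetric ContactMatrix.

    Two row layouts are accepted:

    * ``binA binB count`` -- global bin indices, and
    * ``chromA posA chromB posB count`` -- positions binned by ``bin_size``.

    Entries given in both triangles are summed; the matrix is symmetrized.
    """
    from .hubs import ContactMatrix  # local import avoids a module cycle

    cm = ContactMatrix.empty(bin_size, chrom_sizes)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) == 3:
                    i, j = int(parts[0]), int(parts[1])
                    count = float(parts[2])
                elif len(parts) == 5:
                    i = cm.bin_index(parts[0], int(parts[1]))
                    j = cm.bin_index(parts[2], int(parts[3]))
                    count = float(parts[4])
                else:
                    raise FormatError(
                        f"{path}:{lineno}: expected 3 or 5 columns, got {len(parts)}"
                    )
            except FormatError:
                raise
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            if not (0 <= i < cm.n_bins and 0 <= j < cm.n_bins):
                raise FormatError(
                    f"{path}:{lineno}: bin index out of range "
                    f"({i}, {j}) with {cm.n_bins} bins"
                )
            rows.append(i)
            cols.append(j)
            vals.append(count)
    return cm.with_triplets(np.array(rows, dtype=int), np.array(cols, dtype=int), np.array(vals))


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionTable:
    """Gene x tissue TPM matrix.

    ``df`` has gene ids as the index and tissue names as columns; all
    values are non-negative TPM. The emulated reference layout has 27
    tissues, but any number >= 2 is accepted.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise FormatError("duplicate gene ids in expression table")
        if self.df.columns.duplicated().any():
            raise FormatError("duplicate tissue names in expression table")
        if (self.df.values < 0).any():
            raise FormatError("negative TPM values in expression table")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def tpm(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def n_tissues(self) -> int:
        return self.df.shape[1]


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a TSV expression table: first column gene id, header = tissues."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expression table needs >= 2 tissue columns")
    df.index = df.index.astype(str)
    return ExpressionTable(df.astype(float))


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index_label="gene_id")
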