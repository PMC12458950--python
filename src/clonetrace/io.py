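"""Readers and writers for the plain-text formats the pipeline exchanges.

Reads arrive as FASTQ (optionally gzipped, with the cell tag and UMI encoded
in the read name) or as a tagged TSV table; an optional SAM/BAM path pulls
CB/UB-style tags via pysam. Tables (tag counts, assignments, fates,
diversity, scores) are tab-separated with fixed headers.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
from Bio import SeqIO

from .extract import ReadRecord

__all__ = [
    "DEFAULT_NAME_REGEX",
    "read_fastq",
    "read_read_table",
    "read_sam",
    "read_reads",
    "write_fastq",
    "write_read_table",
    "read_matrix_tsv",
    "write_tsv",
    "read_point_table",
]

# Read names like "READID_ACGTACGTACGTACGT_ACGTACGTACGT" (id_cell_umi).
DEFAULT_NAME_REGEX = r"^(?P<id>.+)_(?P<cell>[ACGTN]+)_(?P<umi>[ACGTN]+)$"


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(
    path: str | Path, name_regex: str = DEFAULT_NAME_REGEX
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from FASTQ/FASTQ.gz.

    ``name_regex`` extracts the cell tag and UMI from the read name via the
    named groups ``cell`` and ``umi`` (and optionally ``id``); a read whose
    name does not match carries no cell tag.
    """
    pattern = re.compile(name_regex)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            m = pattern.match(rec.id)
            if m:
                gd = m.groupdict()
                yield ReadRecord(
                    read_id=gd.get("id") or rec.id,
                    sequence=str(rec.seq).upper(),
                    cell_tag=gd.get("cell"),
                    umi=gd.get("umi"),
                )
            else:
                yield ReadRecord(read_id=rec.id, sequence=str(rec.seq).upper())


def write_fastq(reads, path: str | Path) -> None:
    """Write reads as FASTQ, encoding cell tag and UMI into the read name."""
    with open(path, "w") as fh:
        for r in reads:
            name = r.read_id
            if r.cell_tag is not None and r.umi is not None:
                name = f"{r.read_id}_{r.cell_tag}_{r.umi}"
            fh.write(f"@{name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_read_table(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a TSV with columns read_id, cell_tag, umi, sequence."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"read_id", "sequence"}
    if not required.issubset(df.columns):
        raise ValueError("read table needs at least read_id and sequence columns")
    for row in df.itertuples(index=False):
        cell = getattr(row, "cell_tag", "") or None
        umi = getattr(row, "umi", "") or None
        yield ReadRecord(
            read_id=row.read_id, sequence=row.sequence.upper(), cell_tag=cell, umi=umi
        )


def write_read_table(reads, path: str | Path) -> None:
    rows = [
        (r.read_id, r.cell_tag or "", r.umi or "", r.sequence) for r in reads
    ]
    pd.DataFrame(rows, columns=["read_id", "cell_tag", "umi", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_sam(
    path: str | Path, cell_tag: str = "CB", umi_tag: str = "UB"
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from SAM/BAM, taking cell/UMI from alignment tags."""
    import pysam  # optional dependency, isolated here

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.query_sequence is None:
                continue
            cb = aln.get_tag(cell_tag) if aln.has_tag(cell_tag) else None
            ub = aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else None
            yield ReadRecord(
                read_id=aln.query_name,
                sequence=aln.query_sequence.upper(),
                cell_tag=cb,
                umi=ub,
            )


def read_reads(path: str | Path, fmt: Optional[str] = None) -> Iterator[ReadRecord]:
    """Dispatch on format: fastq / fastq.gz, tsv, sam/bam (by extension if fmt=None)."""
    path = Path(path)
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz")):
            fmt = "fastq"
        elif name.endswith((".sam", ".bam")):
            fmt = "sam"
        else:
            fmt = "tsv"
    if fmt == "fastq":
        return read_fastq(path)
    if fmt == "sam":
        return read_sam(path)
    if fmt == "tsv":
        return read_read_table(path)
    raise ValueError(f"unknown read format {fmt!r}")


def read_matrix_tsv(path: str | Path, cells_in: str = "rows") -> pd.DataFrame:
    """Dense labelled matrix from TSV; ``cells_in`` is "rows" or "columns"."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if cells_in == "columns":
        df = df.T
    elif cells_in != "rows":
        raise ValueError("cells_in must be 'rows' or 'columns'")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_point_table(path: str | Path) -> pd.DataFrame:
    """Point/spot table with columns x, y and optionally channel/value."""
    df = pd.read_csv(path, sep="\t")
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError("point table needs x and y columns")
    return df
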