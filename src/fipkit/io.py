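"""Readers and writers for the standard formats the pipeline touches.

FASTQ (optionally gzipped), MTX triplet matrices with genes/barcodes
sidecar TSVs (the layout droplet quantifiers emit), BED intervals,
bedGraph coverage, TSS annotation TSVs, and barcode whitelist TSVs.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_whitelist",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_tss_table",
]


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) records from a FASTQ file."""
    with _open_text(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (title, sequence, quality) records; returns the count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for title, seq, qual in records:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_whitelist(path: str | Path) -> dict[str, str]:
    """Read a round1 whitelist TSV of (index name, barcode sequence)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "sequence"], dtype=str)
    return dict(zip(df["name"], df["sequence"].str.upper()))


def read_mtx_dir(path: str | Path) -> tuple[scipy.sparse.csr_matrix, list[str], list[str]]:
    """Read a matrix directory (matrix.mtx, genes.tsv, barcodes.tsv).

    Returns (counts genes x cells, gene names, barcodes).
    """
    path = Path(path)
    counts = scipy.io.mmread(path / "matrix.mtx").tocsr()
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match {len(genes)} genes x {len(cells)} barcodes"
        )
    return counts, genes, cells


def write_mtx_dir(
    path: str | Path,
    counts: scipy.sparse.spmatrix,
    genes: list[str],
    cells: list[str],
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.coo_matrix(counts))
    pd.Series(genes).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(cells).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into columns chrom/start/end (+ name if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names) :])
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(path: str | Path, df: pd.DataFrame) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS annotation TSV with columns chrom, position, strand, gene."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "strand", "gene"}
    if not required.issubset(df.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    return df


def bedgraph_to_arrays(
    df: pd.DataFrame, chrom_sizes: dict[str, int]
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-base arrays keyed by chromosome."""
    tracks = {chrom: np.zeros(size) for chrom, size in chrom_sizes.items()}
    for chrom, grp in df.groupby("chrom"):
        if chrom not in tracks:
            raise KeyError(f"chromosome {chrom!r} absent from chrom_sizes")
        arr = tracks[chrom]
        for start, end, value in grp[["start", "end", "value"]].itertuples(index=False):
            arr[start:end] += value
    return tracks
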