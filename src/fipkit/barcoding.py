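"""Two-round barcode handling.

A library carries two barcodes per transcript: a well-specific round1
preindex added by indexed Tn5 tagmentation before encapsulation, and the
conventional droplet (round2) barcode added inside the emulsion.  Reads
are first demultiplexed by the round1 index with no mismatches allowed;
each per-index read set is then quantified by a standard droplet
quantifier, and the resulting per-index gene x barcode matrices are
merged into one matrix whose cells are composite barcodes
"ROUND2-ROUND1".  QC filtering and binomial count thinning (for
depth-sensitivity curves) operate on the merged matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

__all__ = [
    "BarcodeScheme",
    "ReadTriplet",
    "DemuxStats",
    "CountMatrix",
    "demultiplex",
    "merge_matrices",
    "qc_filter",
    "thin_counts",
    "genes_per_cell_curve",
]

UNASSIGNED = "unassigned"

#: default mitochondrial gene-name prefixes (human and mouse conventions)
MITO_PREFIXES = ("MT-", "mt-")


@dataclass(frozen=True)
class BarcodeScheme:
    """Whitelists and read-layout offsets for the two barcode rounds.

    ``round1_location`` names which read of the triplet carries the
    round1 index ("R1", "R2" or "I1") and at which 0-based offset.  The
    default layout places the index at the first bases of R2, the
    cDNA-side read tagged by the Tn5 adapter.  All whitelist entries
    must share one length; assignment is exact-match only.
    """

    round1_whitelist: Mapping[str, str]  # index name -> barcode sequence
    round1_read: str = "R2"
    round1_offset: int = 0
    umi_length: int = 10
    round2_length: int = 16
    round2_whitelist_size: int | None = None

    def __post_init__(self) -> None:
        seqs = list(self.round1_whitelist.values())
        if not seqs:
            raise ValueError("round1 whitelist is empty")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("round1 whitelist entries must share one length")
        if len(set(seqs)) != len(seqs):
            raise ValueError("round1 whitelist entries must be unique")
        if self.round1_read not in {"R1", "R2", "I1"}:
            raise ValueError("round1_read must be one of R1, R2, I1")
        if self.round1_offset < 0:
            raise ValueError("round1_offset must be non-negative")

    @property
    def round1_length(self) -> int:
        return len(next(iter(self.round1_whitelist.values())))


@dataclass(frozen=True)
class ReadTriplet:
    """One sequencing record: R1 (barcode+UMI read), R2 (cDNA), optional I1."""

    name: str
    r1: tuple[str, str]  # (sequence, quality)
    r2: tuple[str, str]
    i1: tuple[str, str] | None = None

    def read(self, which: str) -> tuple[str, str] | None:
        return {"R1": self.r1, "R2": self.r2, "I1": self.i1}[which]


@dataclass
class DemuxStats:
    per_index: dict[str, int]
    unassigned: int = 0
    malformed: int = 0

    @property
    def total(self) -> int:
        return sum(self.per_index.values()) + self.unassigned + self.malformed

    @property
    def assigned_fraction(self) -> float:
        return sum(self.per_index.values()) / self.total if self.total else float("nan")


def demultiplex(
    reads: Iterable[ReadTriplet],
    scheme: BarcodeScheme,
) -> tuple[dict[str, list[ReadTriplet]], DemuxStats]:
    """Split reads by round1 index with exact whitelist matching.

    A read is assigned to an index only when the bases at the configured
    location equal a whitelist entry exactly; any mismatch sends it to
    the ``unassigned`` bin.  The round1 bases are trimmed from the
    assigned read.  Reads too short to contain the index are counted as
    malformed.  Returns (per-index read lists, stats); read conservation
    holds: assigned + unassigned + malformed = input.
    """
    lookup = {seq: name for name, seq in scheme.round1_whitelist.items()}
    lo, hi = scheme.round1_offset, scheme.round1_offset + scheme.round1_length
    out: dict[str, list[ReadTriplet]] = {name: [] for name in scheme.round1_whitelist}
    out[UNASSIGNED] = []
    stats = DemuxStats(per_index={name: 0 for name in scheme.round1_whitelist})

    for read in reads:
        carrier = read.read(scheme.round1_read)
        if carrier is None or len(carrier[0]) < hi:
            stats.malformed += 1
            continue
        name = lookup.get(carrier[0][lo:hi])
        if name is None:
            out[UNASSIGNED].append(read)
            stats.unassigned += 1
            continue
        seq, qual = carrier
        trimmed = (seq[: lo] + seq[hi:], qual[: lo] + qual[hi:])
        fields = {"R1": read.r1, "R2": read.r2, "I1": read.i1}
        fields[scheme.round1_read] = trimmed
        out[name].append(ReadTriplet(name=read.name, r1=fields["R1"], r2=fields["R2"], i1=fields["I1"]))
        stats.per_index[name] += 1
    return out, stats


@dataclass
class CountMatrix:
    """A sparse gene x cell count matrix with composite-barcode cells."""

    counts: scipy.sparse.csr_matrix  # genes x cells
    genes: list[str]
    cells: list[str]

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape does not match gene/cell name lengths")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_totals(self, prefixes: Sequence[str] = MITO_PREFIXES) -> np.ndarray:
        mask = np.array([g.startswith(tuple(prefixes)) for g in self.genes])
        if not mask.any():
            return np.zeros(self.n_cells)
        return np.asarray(self.counts[mask].sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            genes=list(self.genes),
            cells=[c for c, k in zip(self.cells, keep) if k] if keep.dtype == bool
            else [self.cells[i] for i in keep],
        )


def composite_barcode(round2: str, round1: str) -> str:
    """Form the composite cell barcode "ROUND2-ROUND1"."""
    return f"{round2}-{round1}"


def merge_matrices(
    inputs: Sequence[tuple[str, scipy.sparse.spmatrix, Sequence[str], Sequence[str]]],
) -> CountMatrix:
    """Merge per-round1-index matrices into one composite-barcode matrix.

    ``inputs`` holds (round1 index name, genes x barcodes counts, gene
    names, round2 barcodes) per index.  Cell names become composite
    barcodes; gene sets are merged by outer union with zero fill; counts
    are preserved exactly.  A duplicate (round1, round2) pair is an
    error -- it cannot arise from correct demultiplexing.
    """
    all_genes: list[str] = []
    seen_genes: set[str] = set()
    for _, _, genes, _ in inputs:
        for g in genes:
            if g not in seen_genes:
                seen_genes.add(g)
                all_genes.append(g)
    gene_idx = {g: i for i, g in enumerate(all_genes)}

    cell_names: list[str] = []
    seen_cells: set[str] = set()
    blocks = []
    for round1, counts, genes, barcodes in inputs:
        counts = scipy.sparse.csr_matrix(counts)
        if counts.shape != (len(genes), len(barcodes)):
            raise ValueError(f"index {round1!r}: matrix shape does not match names")
        for bc in barcodes:
            name = composite_barcode(bc, round1)
            if name in seen_cells:
                raise ValueError(f"duplicate composite barcode {name!r} across inputs")
            seen_cells.add(name)
            cell_names.append(name)
        rows = np.array([gene_idx[g] for g in genes])
        block = scipy.sparse.csr_matrix(
            (counts.tocoo().data, (rows[counts.tocoo().row], counts.tocoo().col)),
            shape=(len(all_genes), len(barcodes)),
        )
        blocks.append(block)
    merged = scipy.sparse.hstack(blocks).tocsr() if blocks else scipy.sparse.csr_matrix((0, 0))
    return CountMatrix(counts=merged, genes=all_genes, cells=cell_names)


def qc_filter(
    m: CountMatrix,
    min_umi: int | None = 1000,
    max_mito_fraction: float | None = 0.05,
    min_genes: int | None = 50,
    mito_prefixes: Sequence[str] = MITO_PREFIXES,
) -> tuple[CountMatrix, pd.Series]:
    """Remove cells failing any active QC threshold.

    Cells with total UMI below ``min_umi``, mitochondrial fraction above
    ``max_mito_fraction``, or fewer than ``min_genes`` detected genes are
    dropped.  Each threshold is independently optional (pass ``None`` to
    disable).  Returns the filtered matrix and a report of removed-cell
    counts per criterion (a cell can fail several).
    """
    totals = m.cell_totals()
    report = {}
    fail = np.zeros(m.n_cells, dtype=bool)
    if min_umi is not None:
        low_umi = totals < min_umi
        report["low_umi"] = int(low_umi.sum())
        fail |= low_umi
    if max_mito_fraction is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, m.mito_totals(mito_prefixes) / np.maximum(totals, 1), 0.0)
        high_mito = mito_frac > max_mito_fraction
        report["high_mito"] = int(high_mito.sum())
        fail |= high_mito
    if min_genes is not None:
        few_genes = m.genes_per_cell() < min_genes
        report["few_genes"] = int(few_genes.sum())
        fail |= few_genes
    report["removed"] = int(fail.sum())
    report["kept"] = int((~fail).sum())
    if report["kept"] == 0:
        import warnings

        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return m.subset_cells(~fail), pd.Series(report)


def thin_counts(m: CountMatrix, target_mean_per_cell: float, seed: int) -> CountMatrix:
    """Binomially thin counts to a target mean total per cell.

    Each count is replaced by a Binomial(count, p) draw with retention
    probability p = target / current mean, emulating sequencing the
    library to a lower depth.  ``target_mean_per_cell`` must not exceed
    the current mean.
    """
    current = float(m.cell_totals().mean()) if m.n_cells else 0.0
    if target_mean_per_cell > current:
        raise ValueError(
            f"target mean {target_mean_per_cell} exceeds current mean {current:.2f}"
        )
    p = target_mean_per_cell / current if current > 0 else 0.0
    rng = np.random.default_rng(seed)
    coo = m.counts.tocoo()
    if p >= 1.0:
        return CountMatrix(counts=m.counts.copy(), genes=list(m.genes), cells=list(m.cells))
    data = rng.binomial(coo.data.astype(np.int64), p)
    thinned = scipy.sparse.csr_matrix((data, (coo.row, coo.col)), shape=coo.shape)
    thinned.eliminate_zeros()
    return CountMatrix(counts=thinned, genes=list(m.genes), cells=list(m.cells))


def genes_per_cell_curve(
    m: CountMatrix, depths: Sequence[float], seed: int
) -> pd.DataFrame:
    """Mean detected genes per cell at a ladder of thinned depths.

    Reimplements depth-sensitivity analysis at count level: for each
    target depth the matrix is binomially thinned and the mean number of
    genes with nonzero counts per cell recorded.
    """
    rows = []
    for i, depth in enumerate(depths):
        thinned = thin_counts(m, depth, seed=seed + i)
        rows.append({"depth": depth, "mean_genes": float(thinned.genes_per_cell().mean())})
    return pd.DataFrame(rows)
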