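"""Paired TCR repertoire filtering and summaries.

VDJ enrichment happens after droplet barcoding, so VDJ contigs carry
only the droplet (round2) barcode; the Tn5 preindex is lost.  Single
cells are therefore recovered by cross-referencing the matched RNA
data: a contig's droplet barcode must belong to an annotated RNA cell
and must map to exactly one round1 index among RNA cells (otherwise the
droplet held several cells and the contig cannot be attributed).
Clonotypes are cells sharing both TRA and TRB CDR3 sequences; clone
sizes feed the top-k clonal proportion, the diversity indices, and a
Treg-composition "cancer index".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from fipkit.core_stats import DiversityResult, diversity

__all__ = [
    "ContigRecord",
    "Clonotype",
    "vdj_singlet_filter",
    "define_clonotypes",
    "clonal_proportion",
    "repertoire_diversity",
    "cancer_index",
]

CONTIG_COLUMNS = ["barcode", "chain", "cdr3", "cdr3_nt", "reads", "productive"]


@dataclass(frozen=True)
class ContigRecord:
    barcode: str  # round2 droplet barcode
    chain: str  # "TRA" or "TRB"
    cdr3_nt: str
    cdr3_aa: str = ""
    reads: int = 1
    productive: bool = True


@dataclass(frozen=True)
class Clonotype:
    id: str
    cdr3_tra: str
    cdr3_trb: str
    cells: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.cells)


def read_contigs(path) -> pd.DataFrame:
    """Read a VDJ contig CSV (barcode, chain, cdr3, cdr3_nt, reads, productive)."""
    df = pd.read_csv(path)
    missing = set(CONTIG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contig table missing columns {sorted(missing)}")
    return df


def vdj_singlet_filter(
    contigs: pd.DataFrame,
    rna_cells: Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep contigs attributable to exactly one annotated RNA cell.

    ``rna_cells`` lists the annotated RNA cells as (round2 barcode,
    round1 index) pairs.  A contig survives when its round2 barcode
    (i) appears among the annotated cells and (ii) maps to exactly one
    round1 index there -- a droplet whose barcode recurs under several
    preindexes held multiple cells, so its VDJ reads are ambiguous.
    Returns (kept contigs, per-criterion removal report).  The filter is
    idempotent.
    """
    rna = pd.DataFrame(list(rna_cells), columns=["round2", "round1"])
    index_counts = rna.groupby("round2")["round1"].nunique()
    annotated = contigs["barcode"].isin(index_counts.index)
    unique_map = contigs["barcode"].map(index_counts).eq(1)
    keep = annotated & unique_map
    report = pd.Series(
        {
            "input": len(contigs),
            "removed_unannotated": int((~annotated).sum()),
            "removed_nonunique": int((annotated & ~unique_map).sum()),
            "kept": int(keep.sum()),
        }
    )
    return contigs[keep].reset_index(drop=True), report


def _best_chain(sub: pd.DataFrame) -> str | None:
    """CDR3 of the best-supported productive contig of one chain.

    Several productive contigs of the same chain in one cell are
    resolved by highest read support; a tie is unresolvable and the
    cell is excluded (None).
    """
    prod = sub[sub["productive"]]
    if prod.empty:
        return None
    if len(prod) == 1:
        return str(prod["cdr3_nt"].iloc[0])
    top = prod.nlargest(2, "reads")
    if top["reads"].iloc[0] == top["reads"].iloc[1]:
        return None
    return str(top["cdr3_nt"].iloc[0])


def define_clonotypes(
    contigs: pd.DataFrame, key: str = "cdr3_nt"
) -> tuple[list[Clonotype], pd.Series]:
    """Group cells into clonotypes by their paired CDR3 sequences.

    Cells sharing both the TRA and the TRB CDR3 (nucleotide sequences
    by default; set ``key="cdr3"`` for amino acids) form one clonotype.
    Cells lacking a productive contig for either chain are excluded
    from pairing and tallied in the report, as are cells with tied
    duplicate chains.
    """
    if key not in {"cdr3_nt", "cdr3"}:
        raise ValueError("key must be 'cdr3_nt' or 'cdr3'")
    work = contigs.rename(columns={key: "cdr3_nt"}) if key != "cdr3_nt" else contigs
    pairs: dict[tuple[str, str], list[str]] = {}
    n_unpaired = n_ambiguous = 0
    for barcode, sub in work.groupby("barcode"):
        tra = _best_chain(sub[sub["chain"] == "TRA"])
        trb = _best_chain(sub[sub["chain"] == "TRB"])
        has_dup_tie = (tra is None and (sub["chain"] == "TRA").sum() > 1) or (
            trb is None and (sub["chain"] == "TRB").sum() > 1
        )
        if tra is None or trb is None:
            if has_dup_tie:
                n_ambiguous += 1
            else:
                n_unpaired += 1
            continue
        pairs.setdefault((tra, trb), []).append(str(barcode))
    clonotypes = [
        Clonotype(id=f"clonotype{i + 1}", cdr3_tra=tra, cdr3_trb=trb, cells=tuple(sorted(cells)))
        for i, ((tra, trb), cells) in enumerate(
            sorted(pairs.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        )
    ]
    report = pd.Series(
        {
            "cells": int(work["barcode"].nunique()),
            "paired": int(sum(c.size for c in clonotypes)),
            "unpaired": n_unpaired,
            "ambiguous": n_ambiguous,
            "clonotypes": len(clonotypes),
        }
    )
    return clonotypes, report


def clonal_proportion(sizes: Sequence[int], top_k: int = 100) -> float:
    """Fraction of cells belonging to the ``top_k`` largest clonotypes."""
    if len(sizes) == 0:
        raise ValueError("sizes must be nonempty")
    ordered = sorted(sizes, reverse=True)
    return sum(ordered[:top_k]) / sum(ordered)


def repertoire_diversity(
    sizes_per_group: dict[str, Sequence[int]],
) -> dict[str, DiversityResult]:
    """Shannon / inverse Simpson / Chao1 per sample or subpopulation."""
    return {group: diversity(sizes) for group, sizes in sizes_per_group.items()}


def cancer_index(
    labels: Sequence[str], reference_cluster: str
) -> tuple[float, float]:
    """Composition index of cells outside a reference subpopulation.

    Returns (fraction outside the reference cluster, odds
    outside/inside).  The fraction form is bounded in [0, 1] and
    comparable across donors; the odds form is infinite when no cell
    belongs to the reference cluster.
    """
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    n = len(labels)
    n_ref = sum(1 for l in labels if l == reference_cluster)
    fraction = (n - n_ref) / n
    odds = (n - n_ref) / n_ref if n_ref else float("inf")
    return fraction, odds
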