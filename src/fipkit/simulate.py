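"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`SimConfig` (seed
included) and returns in-memory objects plus a ground-truth table
sufficient to score the corresponding pipeline stage.  Defaults mirror
the study conditions of the assay the pipeline targets: 15,300 cells
overloaded onto ~100,000 droplets, a 96-plex round1 preindex, a 1:1
two-species mixture, and a toy two-chromosome genome (1 Mb each) for
the coverage and TSS generators.

A single global seed is expanded into independent per-generator
substreams, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from fipkit.barcoding import BarcodeScheme, ReadTriplet
from fipkit.droplet_model import LoadingModel, simulate_loading
from fipkit.tss_usage import TagSite

__all__ = [
    "SimConfig",
    "make_whitelist",
    "gen_reads",
    "gen_species_mix",
    "gen_coverage",
    "gen_tss_tags",
    "gen_clonotypes",
]

BASES = np.array(list("ACGT"))

# substream indices, one per generator
_STREAMS = {"reads": 0, "species": 1, "coverage": 2, "tss": 3, "clonotypes": 4}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators.  ``seed`` is mandatory."""

    seed: int
    # loading / barcoding
    n_cells: int = 15_300
    n_droplets: int = 100_000
    plexity: int = 96
    species_fractions: tuple[float, float] = (0.5, 0.5)
    reads_per_cell: int = 50
    round1_length: int = 8
    round2_length: int = 16
    umi_length: int = 10
    cdna_length: int = 60
    mismatch_fraction: float = 0.0
    # toy genome
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 4_000_000}
    )
    # eRNA coverage generator
    n_distal_null: int = 500
    n_distal_planted: int = 500
    n_proximal: int = 50
    peak_width: int = 400
    background_reads_per_window: int = 200  # uniform over the 4 kb window
    core_enrichment: float = 5.0
    # TSS usage generator
    n_switch_genes: int = 200
    n_null_genes: int = 200
    reads_per_gene_per_group: int = 300
    tss_spacing: int = 300
    usage_null: tuple[float, float] = (0.6, 0.4)
    usage_switch_early: tuple[float, float] = (0.8, 0.2)
    usage_switch_late: tuple[float, float] = (0.2, 0.8)
    position_jitter: int = 2
    # clonotype generator
    n_t_cells: int = 2_000
    clone_zipf_a: float = 2.2
    duplicated_barcode_fraction: float = 0.02
    unannotated_fraction: float = 0.02

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS[stream]]
        )

    @property
    def loading_model(self) -> LoadingModel:
        return LoadingModel(
            n_cells=self.n_cells, n_droplets=self.n_droplets, plexity=self.plexity
        )


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n unique random DNA strings of the given length."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        batch = ["".join(BASES[rng.integers(0, 4, size=length)]) for _ in range(n)]
        for s in batch:
            if s not in seen:
                seen.add(s)
                seqs.append(s)
                if len(seqs) == n:
                    break
    return seqs


def make_whitelist(cfg: SimConfig) -> dict[str, str]:
    """A ``plexity``-entry round1 whitelist keyed BC001..BCnnn."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 9001)))
    seqs = _random_seqs(rng, cfg.plexity, cfg.round1_length)
    return {f"BC{i + 1:03d}": s for i, s in enumerate(seqs)}


def _mutate_off_whitelist(seq: str, whitelist: set[str], rng: np.random.Generator) -> str:
    """One substitution guaranteed to miss every whitelist entry."""
    for _ in range(100):
        i = int(rng.integers(0, len(seq)))
        alt = rng.choice([b for b in "ACGT" if b != seq[i]])
        mutated = seq[:i] + alt + seq[i + 1 :]
        if mutated not in whitelist:
            return mutated
    raise RuntimeError("could not generate an off-whitelist barcode")


def gen_reads(
    cfg: SimConfig, n_reads: int | None = None
) -> tuple[list[ReadTriplet], BarcodeScheme, pd.DataFrame]:
    """Synthetic read triplets with known cell of origin.

    Each read carries its cell's round2 barcode + UMI on R1 and the
    round1 index at the start of R2 followed by random cDNA.  A
    ``mismatch_fraction`` of reads get one substitution inside the
    round1 bases (guaranteed off-whitelist) and are truth-labelled as
    such.  Returns (reads, scheme, truth) where truth has one row per
    read: read name, cell, round1 index, species, mismatched.
    """
    rng = cfg.rng("reads")
    whitelist = make_whitelist(cfg)
    wl_names = list(whitelist)
    wl_set = set(whitelist.values())
    scheme = BarcodeScheme(
        round1_whitelist=whitelist,
        round1_read="R2",
        round1_offset=0,
        umi_length=cfg.umi_length,
        round2_length=cfg.round2_length,
    )
    n_sim_cells = max(
        1, n_reads // cfg.reads_per_cell if n_reads else cfg.n_cells // 10
    )
    n_reads = n_reads or n_sim_cells * cfg.reads_per_cell
    round2 = _random_seqs(rng, n_sim_cells, cfg.round2_length)
    cell_round1 = rng.integers(0, cfg.plexity, size=n_sim_cells)
    cell_species = (rng.random(n_sim_cells) >= cfg.species_fractions[0]).astype(int)

    reads, truth = [], []
    cell_of_read = rng.integers(0, n_sim_cells, size=n_reads)
    mismatched = rng.random(n_reads) < cfg.mismatch_fraction
    for i in range(n_reads):
        c = int(cell_of_read[i])
        idx_name = wl_names[cell_round1[c]]
        bc1 = whitelist[idx_name]
        if mismatched[i]:
            bc1 = _mutate_off_whitelist(bc1, wl_set, rng)
        umi = "".join(BASES[rng.integers(0, 4, size=cfg.umi_length)])
        cdna = "".join(BASES[rng.integers(0, 4, size=cfg.cdna_length)])
        name = f"read{i}"
        r1_seq = round2[c] + umi
        r2_seq = bc1 + cdna
        reads.append(
            ReadTriplet(name=name, r1=(r1_seq, "I" * len(r1_seq)), r2=(r2_seq, "I" * len(r2_seq)))
        )
        truth.append(
            {
                "read": name,
                "cell": c,
                "round1": idx_name,
                "species": int(cell_species[c]),
                "mismatched": bool(mismatched[i]),
            }
        )
    return reads, scheme, pd.DataFrame(truth)


def gen_species_mix(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-composite-barcode two-species UMI counts with collision truth.

    Cells are loaded by the Monte-Carlo droplet model; every cell
    contributes ``reads_per_cell`` UMIs of its own species, and cells
    that share a composite barcode (droplet + round1 index) have their
    counts summed, exactly as a real collision collapses cells.

    Returns (counts, truth): counts indexed by composite barcode with
    columns counts_a / counts_b; truth adds n_cells and is_collision
    (>= 2 member cells) and spans_species per barcode.
    """
    seed = int(np.random.SeedSequence((cfg.seed, 9002)).generate_state(1)[0] % (2**31))
    cells = simulate_loading(cfg.loading_model, seed=seed, species_fractions=cfg.species_fractions)
    cells["umis"] = cfg.reads_per_cell
    grouped = cells.groupby(["droplet", "round1"])
    agg = grouped.agg(
        n_cells=("species", "size"),
        n_species=("species", "nunique"),
        counts_b=("species", "sum"),
    )
    agg["counts_b"] *= cfg.reads_per_cell
    agg["counts_a"] = agg["n_cells"] * cfg.reads_per_cell - agg["counts_b"]
    agg = agg.reset_index()
    agg["barcode"] = [
        f"D{d}-BC{r + 1:03d}" for d, r in zip(agg["droplet"], agg["round1"])
    ]
    counts = agg.set_index("barcode")[["counts_a", "counts_b"]]
    truth = agg.set_index("barcode")[["droplet", "round1", "n_cells", "n_species"]].assign(
        is_collision=lambda df: df["n_cells"] >= 2,
        spans_species=lambda df: df["n_species"] >= 2,
    )
    return counts, truth


def _place_positions(
    rng: np.random.Generator, chrom_sizes: dict[str, int], n: int, margin: int, spacing: int
) -> list[tuple[str, int]]:
    """n well-separated positions across the toy genome."""
    chroms = list(chrom_sizes)
    out: list[tuple[str, int]] = []
    per_chrom = math.ceil(n / len(chroms))
    for chrom in chroms:
        size = chrom_sizes[chrom]
        usable = size - 2 * margin
        if per_chrom * spacing > usable:
            raise ValueError("toy genome too small for the requested features")
        starts = margin + np.sort(
            rng.choice(usable // spacing, size=per_chrom, replace=False)
        ) * spacing
        out.extend((chrom, int(p)) for p in starts)
    rng.shuffle(out)  # avoid chrom-ordered truth labels
    return out[:n]


def gen_coverage(
    cfg: SimConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """5' tag track + ATAC peaks + TSS annotation with planted eRNA truth.

    Distal peaks are placed > 2 kb + window from every annotated TSS;
    ``n_distal_planted`` of them get core-concentrated extra signal so
    the core (+/- 500 bp) density is ``core_enrichment`` times the
    uniform background, the rest stay background-only (null).  Proximal
    peaks sit right next to a TSS and must be excluded by the distance
    filter.  Returns (track per chrom, peaks BED-like table with a
    ``name`` column, TSS table, truth per peak).
    """
    rng = cfg.rng("coverage")
    track = {c: np.zeros(s) for c, s in cfg.chrom_sizes.items()}
    margin = 3_000
    spacing = 5_000  # keeps feature windows disjoint and TSS > 2 kb away

    n_tss = 60
    n_peaks = cfg.n_distal_null + cfg.n_distal_planted
    slots = _place_positions(
        rng, cfg.chrom_sizes, n_tss + n_peaks, margin, spacing
    )
    tss_slots, peak_slots = slots[:n_tss], slots[n_tss:]

    tss = pd.DataFrame(
        {
            "chrom": [c for c, _ in tss_slots],
            "position": [p for _, p in tss_slots],
            "strand": "+",
            "gene": [f"gene{i}" for i in range(len(tss_slots))],
        }
    )

    half = cfg.peak_width // 2
    window = 2_000
    bg_density = cfg.background_reads_per_window / (2 * window)
    core_extra = int(round((cfg.core_enrichment - 1.0) * bg_density * 1_000))

    peaks, truth = [], []
    planted_flags = np.zeros(n_peaks, dtype=bool)
    planted_flags[: cfg.n_distal_planted] = True
    rng.shuffle(planted_flags)
    for i, ((chrom, center), planted) in enumerate(zip(peak_slots, planted_flags)):
        name = f"peak{i}"
        peaks.append({"chrom": chrom, "start": center - half, "end": center + half, "name": name})
        # uniform background over the 4 kb window (exchangeable bins)
        bg_pos = center - window + rng.integers(0, 2 * window, size=cfg.background_reads_per_window)
        np.add.at(track[chrom], bg_pos, 1.0)
        n_core_reads = 0
        if planted:
            core_pos = center - 500 + rng.integers(0, 1_000, size=core_extra)
            np.add.at(track[chrom], core_pos, 1.0)
            n_core_reads = core_extra
        truth.append({"name": name, "planted": bool(planted), "core_reads": n_core_reads})

    # proximal peaks: adjacent to an annotated TSS, excluded by distance
    for j in range(cfg.n_proximal):
        chrom, pos = tss_slots[j % n_tss]
        center = pos + 1_200  # edge ~1 kb from the TSS point
        peaks.append(
            {"chrom": chrom, "start": center - half, "end": center + half, "name": f"proximal{j}"}
        )
        truth.append({"name": f"proximal{j}", "planted": False, "core_reads": 0})

    return track, pd.DataFrame(peaks), tss, pd.DataFrame(truth)


def gen_tss_tags(
    cfg: SimConfig,
) -> tuple[dict[str, list[TagSite]], pd.DataFrame, pd.DataFrame]:
    """Per-stage 5' tag pileups for genes with two alternative TSSs.

    Each gene has two TSSs ``tss_spacing`` bases apart (far enough that
    the enclosing density cluster exceeds the span filter, so each TSS
    yields its own peak).  Null genes use
    the same usage vector at every stage; switch genes move from
    ``usage_switch_early`` through the midpoint to
    ``usage_switch_late``.  Per stage, ``reads_per_gene_per_group``
    reads are split multinomially over the TSSs and jittered within
    +/- ``position_jitter`` bases so the cluster caller sees realistic
    pileups.

    Returns (tags per stage name, TSS annotation table, truth per gene
    with is_switch and the generating usage vectors).
    """
    rng = cfg.rng("tss")
    n_genes = cfg.n_switch_genes + cfg.n_null_genes
    margin = 2_000
    spacing = 2_000
    slots = _place_positions(rng, cfg.chrom_sizes, n_genes, margin, spacing)
    is_switch = np.zeros(n_genes, dtype=bool)
    is_switch[: cfg.n_switch_genes] = True
    rng.shuffle(is_switch)

    mid = tuple(
        (a + b) / 2 for a, b in zip(cfg.usage_switch_early, cfg.usage_switch_late)
    )
    stages = ("early", "medium", "late")
    ann_rows, truth_rows = [], []
    pile: dict[str, dict[tuple[str, str, int], int]] = {s: {} for s in stages}
    for g, ((chrom, pos), switch) in enumerate(zip(slots, is_switch)):
        gene = f"gene{g}"
        tss_pos = (pos, pos + cfg.tss_spacing)
        for t, p in enumerate(tss_pos):
            ann_rows.append(
                {"chrom": chrom, "position": p, "strand": "+", "gene": gene, "tss": f"{gene}.t{t}"}
            )
        per_stage = (
            {"early": cfg.usage_switch_early, "medium": mid, "late": cfg.usage_switch_late}
            if switch
            else {s: cfg.usage_null for s in stages}
        )
        for stage in stages:
            alloc = rng.multinomial(cfg.reads_per_gene_per_group, per_stage[stage])
            for t, n_t in enumerate(alloc):
                if n_t == 0:
                    continue
                jitter = rng.integers(
                    -cfg.position_jitter, cfg.position_jitter + 1, size=n_t
                )
                for off in jitter:
                    key = (chrom, "+", int(tss_pos[t] + off))
                    pile[stage][key] = pile[stage].get(key, 0) + 1
        truth_rows.append(
            {
                "gene": gene,
                "chrom": chrom,
                "is_switch": bool(switch),
                "usage_early": per_stage["early"],
                "usage_late": per_stage["late"],
            }
        )

    tags = {
        stage: [
            TagSite(chrom=c, strand=s, position=p, count=n)
            for (c, s, p), n in sorted(sites.items())
        ]
        for stage, sites in pile.items()
    }
    return tags, pd.DataFrame(ann_rows), pd.DataFrame(truth_rows)


def gen_clonotypes(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, list[tuple[str, str]], pd.DataFrame]:
    """VDJ contigs with planted barcode duplications and clonotype truth.

    Clonotype sizes follow a truncated Zipf law.  Every T cell yields a
    productive TRA and TRB contig carrying its clonotype's CDR3 pair.
    A ``duplicated_barcode_fraction`` of round2 barcodes are planted in
    the RNA annotation under two round1 indices (so the singlet filter
    must drop them) and an ``unannotated_fraction`` are left out of the
    RNA annotation entirely.

    Returns (contigs, rna_cells as (round2, round1) pairs, truth per
    cell with clonotype id and the planted drop reasons).
    """
    rng = cfg.rng("clonotypes")
    n = cfg.n_t_cells
    # clonotype assignment: draw Zipf ranks, relabel densely
    ranks = rng.zipf(cfg.clone_zipf_a, size=n)
    _, clone_of_cell = np.unique(ranks, return_inverse=True)
    n_clones = int(clone_of_cell.max()) + 1
    tra = _random_seqs(rng, n_clones, 36)
    trb = _random_seqs(rng, n_clones, 39)

    barcodes = _random_seqs(rng, n, cfg.round2_length)
    dup = rng.random(n) < cfg.duplicated_barcode_fraction
    unannot = (~dup) & (rng.random(n) < cfg.unannotated_fraction)

    rna_cells: list[tuple[str, str]] = []
    contigs, truth = [], []
    for i in range(n):
        bc = barcodes[i]
        r1 = f"BC{int(rng.integers(0, cfg.plexity)) + 1:03d}"
        if not unannot[i]:
            rna_cells.append((bc, r1))
            if dup[i]:
                other = f"BC{(int(r1[2:]) % cfg.plexity) + 1:03d}"
                rna_cells.append((bc, other))
        k = int(clone_of_cell[i])
        for chain, seq in (("TRA", tra[k]), ("TRB", trb[k])):
            aa = seq[: len(seq) // 3]
            contigs.append(
                {
                    "barcode": bc,
                    "chain": chain,
                    "cdr3": aa,
                    "cdr3_nt": seq,
                    "reads": int(rng.integers(10, 200)),
                    "productive": True,
                }
            )
        truth.append(
            {
                "barcode": bc,
                "clonotype": k,
                "planted_duplicate": bool(dup[i]),
                "planted_unannotated": bool(unannot[i]),
            }
        )
    return pd.DataFrame(contigs), rna_cells, pd.DataFrame(truth)
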