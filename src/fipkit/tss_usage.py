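"""TSS peak calling and differential TSS-usage testing.

5'-anchored reads pile up at transcription start sites.  Tag clusters
are called per strand by Paraclu-style density clustering: a cluster is
a genomic segment maximal for the score (total tags) - d * (span) at
some density d, and the full nested family of such segments is found by
a recursive weakest-link split.  Clusters are stability-filtered,
union-merged across groups, width- and annotation-filtered into TSS
peaks, and per-gene relative TSS usage across groups (e.g. pseudotime
stages) is tested for switches with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from fipkit.core_stats import bh_adjust, fisher_exact

__all__ = [
    "TagSite",
    "TagCluster",
    "SwitchResult",
    "paraclu",
    "stability_filter",
    "tss_peaks",
    "stage_bins",
    "usage_table",
    "differential_usage",
    "top2_variance",
]


@dataclass(frozen=True)
class TagSite:
    """A 5' read-start position with its tag count (1-based point)."""

    chrom: str
    strand: str
    position: int
    count: int


@dataclass(frozen=True)
class TagCluster:
    """A density cluster of tag sites (positions inclusive).

    ``d_min``/``d_max`` bound the densities d for which the segment is
    maximal-scoring; the cluster's own density total/span lies between
    them.  Span counts bases inclusively: end - start + 1.
    """

    chrom: str
    strand: str
    start: int
    end: int
    n_sites: int
    total: float
    d_min: float
    d_max: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def density(self) -> float:
        return self.total / self.span

    @property
    def stability(self) -> float:
        return self.d_max / self.d_min if self.d_min > 0 else math.inf


def _weakest_prefix(pos: np.ndarray, cnt: np.ndarray) -> tuple[float, int]:
    """Weakest prefix break: min over i>0 of sum(cnt[:i]) / (pos[i]-pos[0]).

    The denominator is the number of bases the prefix occupies up to (but
    not including) the next site, which is exactly the span freed by
    splitting there.  Returns (density, split index); +inf for a single
    site.
    """
    if pos.size < 2:
        return math.inf, 0
    prefix = np.cumsum(cnt)[:-1]
    dens = prefix / (pos[1:] - pos[0])
    i = int(np.argmin(dens))
    return float(dens[i]), i + 1


def _weakest_suffix(pos: np.ndarray, cnt: np.ndarray) -> tuple[float, int]:
    if pos.size < 2:
        return math.inf, 0
    suffix = np.cumsum(cnt[::-1])[:-1][::-1]  # sums of cnt[i:] for i >= 1
    dens = suffix / (pos[-1] - pos[:-1])
    i = int(np.argmin(dens))
    return float(dens[i]), i + 1


def paraclu(sites: Sequence[TagSite]) -> list[TagCluster]:
    """Call the full nested family of density clusters on one strand.

    All sites must share one (chrom, strand); positions must be unique.
    For each block the weakest prefix/suffix break density is the block's
    ``d_max`` (the largest density at which the whole block is still a
    maximal-scoring segment); the block splits there, and each child
    inherits the break density as its ``d_min``.  Single sites get the
    conventional sentinels d_min = 0 (top level) and d_max = +inf.
    Clusters on one strand form a laminar (nested or disjoint) family
    and child density >= parent density.
    """
    if not sites:
        return []
    chroms = {s.chrom for s in sites}
    strands = {s.strand for s in sites}
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError("paraclu operates on sites of a single chrom and strand")
    if any(s.count <= 0 for s in sites):
        raise ValueError("tag counts must be positive")
    ordered = sorted(sites, key=lambda s: s.position)
    pos = np.array([s.position for s in ordered], dtype=np.int64)
    if np.any(np.diff(pos) == 0):
        raise ValueError("duplicate positions; aggregate counts per site first")
    cnt = np.array([s.count for s in ordered], dtype=float)
    chrom, strand = chroms.pop(), strands.pop()

    out: list[TagCluster] = []
    # explicit stack to avoid recursion limits on long chromosomes;
    # d_min is the block's extension threshold: the largest density of
    # any piece by which the block could be extended into its
    # surroundings (0 for the root)
    stack: list[tuple[int, int, float]] = [(0, pos.size, 0.0)]
    while stack:
        lo, hi, d_min = stack.pop()
        if lo >= hi:
            continue
        p, c = pos[lo:hi], cnt[lo:hi]
        pref_d, pref_i = _weakest_prefix(p, c)
        suf_d, suf_i = _weakest_suffix(p, c)
        d_max = min(pref_d, suf_d)
        total = float(c.sum())
        density = total / (p[-1] - p[0] + 1)
        # the block is maximal-scoring exactly for densities d with
        # d_min < d < min(d_max, density); transitional blocks (empty
        # interval) are descended into but not emitted
        if d_min < min(d_max, density):
            out.append(
                TagCluster(
                    chrom=chrom,
                    strand=strand,
                    start=int(p[0]),
                    end=int(p[-1]),
                    n_sites=hi - lo,
                    total=total,
                    d_min=d_min,
                    d_max=d_max,
                )
            )
        if math.isinf(d_max):
            continue  # single site
        split = pref_i if pref_d <= suf_d else suf_i
        # children are absorbed by this block while it is coherent
        # (d < d_max) and by its ancestors while d < d_min, so they
        # only become maximal above both thresholds
        child_d_min = max(d_min, d_max)
        stack.append((lo, lo + split, child_d_min))
        stack.append((lo + split, hi, child_d_min))
    return out


def stability_filter(
    clusters: Sequence[TagCluster],
    fold: float | None = 2.0,
    min_total: float | None = 30,
    max_span: int | None = 200,
) -> list[TagCluster]:
    """Keep clusters that are stable, deep and compact.

    A cluster survives when d_max/d_min >= ``fold``, total tags >=
    ``min_total`` and span <= ``max_span``; each criterion can be
    disabled with ``None``.  Order-independent per-cluster predicate.
    """

    def ok(c: TagCluster) -> bool:
        if fold is not None and c.stability < fold:
            return False
        if min_total is not None and c.total < min_total:
            return False
        if max_span is not None and c.span > max_span:
            return False
        return True

    return [c for c in clusters if ok(c)]


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge overlapping inclusive intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(iv):
        if merged and start <= merged[-1][1] + 0:  # touching at same base overlaps
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def tss_peaks(
    clusters_per_group: Sequence[Sequence[TagCluster]],
    annotated_tss: pd.DataFrame,
    max_width: int = 300,
    max_tss_dist: int = 100,
) -> pd.DataFrame:
    """Merge per-group clusters into TSS peaks near annotated starts.

    Overlapping clusters from all groups are union-merged per (chrom,
    strand); merged peaks wider than ``max_width`` bases are dropped,
    then only peaks whose edge-to-point distance to some annotated TSS
    on the same chromosome is smaller than ``max_tss_dist`` survive.
    Returns a table (chrom, strand, start, end, width, tss_gene).
    """
    if annotated_tss.empty:
        raise ValueError("annotation must be nonempty")
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for group in clusters_per_group:
        for c in group:
            by_key.setdefault((c.chrom, c.strand), []).append((c.start, c.end))

    rows = []
    for (chrom, strand), ivs in sorted(by_key.items()):
        ann = annotated_tss[annotated_tss["chrom"] == chrom]
        tss_pos = ann["position"].to_numpy()
        genes = ann["gene"].to_numpy()
        for start, end in _merge_intervals(ivs):
            width = end - start + 1
            if width > max_width:
                continue
            if tss_pos.size == 0:
                continue
            dist = np.maximum.reduce([start - tss_pos, tss_pos - end, np.zeros_like(tss_pos)])
            j = int(np.argmin(dist))
            if dist[j] < max_tss_dist:
                rows.append(
                    {
                        "chrom": chrom,
                        "strand": strand,
                        "start": start,
                        "end": end,
                        "width": width,
                        "tss_gene": genes[j],
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", "width", "tss_gene"])


def assign_tags_to_peaks(sites: Sequence[TagSite], peaks: pd.DataFrame) -> pd.DataFrame:
    """Count tags whose 5' start falls inside each TSS peak.

    Peaks must be non-overlapping per (chrom, strand), as produced by
    :func:`tss_peaks`.  Returns the peak table with an added ``count``
    column; tags outside every peak are ignored.
    """
    out = peaks.copy()
    out["count"] = 0
    if not len(peaks) or not sites:
        return out
    site_df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "strand": [s.strand for s in sites],
            "position": [s.position for s in sites],
            "n": [s.count for s in sites],
        }
    )
    for (chrom, strand), grp in out.groupby(["chrom", "strand"]):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sub = site_df[(site_df["chrom"] == chrom) & (site_df["strand"] == strand)]
        if sub.empty:
            continue
        idx = np.searchsorted(starts, sub["position"].to_numpy(), side="right") - 1
        inside = (idx >= 0) & (sub["position"].to_numpy() <= ends[np.clip(idx, 0, None)])
        hits = pd.Series(sub["n"].to_numpy()[inside]).groupby(idx[inside]).sum()
        out.loc[grp.index[hits.index], "count"] += hits.to_numpy()
    return out


def tags_to_usage_counts(
    tags_per_group: dict[str, Sequence[TagSite]],
    annotated_tss: pd.DataFrame,
    fold: float | None = 2.0,
    min_total: float | None = 30,
    max_span: int | None = 200,
    max_width: int = 300,
    max_tss_dist: int = 100,
) -> pd.DataFrame:
    """Full tag -> usage-count pipeline across groups.

    Calls density clusters per group (per chrom and strand), stability-
    filters them, merges them into TSS peaks against the annotation,
    then counts each group's tags per peak.  Returns the long count
    table (gene, tss, group, count) that :func:`usage_table` consumes;
    the TSS id is the peak locus string.
    """
    clusters_per_group = []
    for group, sites in tags_per_group.items():
        by_key: dict[tuple[str, str], list[TagSite]] = {}
        for s in sites:
            by_key.setdefault((s.chrom, s.strand), []).append(s)
        clusters: list[TagCluster] = []
        for key_sites in by_key.values():
            clusters.extend(paraclu(key_sites))
        clusters_per_group.append(
            stability_filter(clusters, fold=fold, min_total=min_total, max_span=max_span)
        )
    peaks = tss_peaks(
        clusters_per_group, annotated_tss, max_width=max_width, max_tss_dist=max_tss_dist
    )
    peaks["tss"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])
    ]
    rows = []
    for group, sites in tags_per_group.items():
        counted = assign_tags_to_peaks(sites, peaks)
        for r in counted.itertuples(index=False):
            rows.append(
                {"gene": r.tss_gene, "tss": r.tss, "group": group, "count": int(r.count)}
            )
    return pd.DataFrame(rows)


def stage_bins(pseudotime: Sequence[float]) -> list[str]:
    """Bin cells along pseudotime into early / medium / late stages.

    Pseudotime is cut into 10 equal-width bins over [min, max]; bins 1-3
    form the early stage, 4-7 the medium stage and 8-10 the late stage.
    The maximum value falls in bin 10.  Constant pseudotime is an error
    (no ordering exists).
    """
    t = np.asarray(pseudotime, dtype=float)
    if t.size == 0 or not np.all(np.isfinite(t)):
        raise ValueError("pseudotime must be nonempty and finite")
    lo, hi = float(t.min()), float(t.max())
    if hi == lo:
        raise ValueError("constant pseudotime: cells cannot be ordered")
    bins = np.minimum((10 * (t - lo) / (hi - lo)).astype(int), 9)  # 0..9
    labels = np.array(["early", "medium", "late"])
    return list(labels[np.digitize(bins, [3, 7])])


def scaled_usage(counts: Sequence[float]) -> list[int]:
    """Relative usage of each TSS: proportion x 100, ceiled to integer."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("gene has zero total TSS reads")
    return [int(math.ceil(100 * v / total)) if v > 0 else 0 for v in arr]


def usage_table(
    counts: pd.DataFrame,
    q_low: float = 0.5,
    q_high: float = 0.99,
) -> pd.DataFrame:
    """Per-gene scaled TSS usage with quantile-based missingness.

    ``counts`` has columns gene, tss, group, count.  For each (gene,
    group) the usage of each TSS is its read proportion of the gene's
    total TSS reads in that group, scaled by 100 and ceiled to an
    integer.  A (gene, group) is flagged missing when the gene's total
    is strictly below the group's ``q_low`` quantile or strictly above
    its ``q_high`` quantile of per-gene totals (controlling for overall
    expression differences); zero-total genes are missing, never a
    division by zero.

    Returns a long table (gene, tss, group, count, usage, missing).
    """
    required = {"gene", "tss", "group", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    totals = counts.groupby(["group", "gene"])["count"].sum()
    qlo = totals.groupby("group").quantile(q_low)
    qhi = totals.groupby("group").quantile(q_high)

    rows = []
    for (group, gene), sub in counts.groupby(["group", "gene"]):
        total = int(sub["count"].sum())
        missing = total == 0 or total < qlo[group] or total > qhi[group]
        usages = scaled_usage(sub["count"]) if total > 0 else [0] * len(sub)
        for (_, r), u in zip(sub.iterrows(), usages):
            rows.append(
                {
                    "gene": gene,
                    "tss": r["tss"],
                    "group": group,
                    "count": int(r["count"]),
                    "usage": u,
                    "missing": bool(missing),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SwitchResult:
    """Differential TSS usage for one gene across groups."""

    gene: str
    p_adj_min: float
    comparisons: tuple[str, ...]
    tss_variance: dict[str, float]


def top2_variance(usages: Sequence[float]) -> float:
    """Sample variance (denominator 1) of the two largest usage values."""
    top = sorted(usages, reverse=True)[:2]
    if len(top) < 2:
        return 0.0
    mean = (top[0] + top[1]) / 2.0
    return (top[0] - mean) ** 2 + (top[1] - mean) ** 2


def differential_usage(
    usage: pd.DataFrame,
    use_raw_counts: bool = False,
    fisher_seed: int = 0,
) -> list[SwitchResult]:
    """Test each gene for a TSS switch across groups.

    For each gene with >= 2 TSSs and >= 2 non-missing groups, every pair
    of non-missing groups is compared with Fisher's exact test on the
    2 x n table of scaled usage integers (or raw counts when
    ``use_raw_counts``); p-values are BH-adjusted within the gene's
    comparisons and the minimum adjusted p reported.  Per TSS, the
    variance of the two highest group usages is reported.  Genes
    non-missing in fewer than two groups are skipped.
    """
    value_col = "count" if use_raw_counts else "usage"
    results = []
    for gene, sub in usage.groupby("gene", sort=True):
        tss_ids = sorted(sub["tss"].unique())
        if len(tss_ids) < 2:
            continue
        wide = sub[~sub["missing"]].pivot_table(
            index="group", columns="tss", values=value_col, fill_value=0
        ).reindex(columns=tss_ids, fill_value=0)
        groups = list(wide.index)
        if len(groups) < 2:
            continue
        pvals, labels = [], []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                tab = np.vstack([wide.iloc[i].to_numpy(), wide.iloc[j].to_numpy()]).astype(int)
                if tab[0].sum() == 0 or tab[1].sum() == 0:
                    continue
                res = fisher_exact(tab.tolist(), seed=fisher_seed)
                pvals.append(max(res.p, np.nextafter(0, 1)))
                labels.append(f"{groups[i]}|{groups[j]}")
        if not pvals:
            continue
        p_adj = bh_adjust(pvals)
        usage_wide = sub.pivot_table(index="group", columns="tss", values="usage", fill_value=0)
        variances = {
            str(t): top2_variance(usage_wide[t].to_numpy()) for t in usage_wide.columns
        }
        results.append(
            SwitchResult(
                gene=str(gene),
                p_adj_min=float(min(p_adj)),
                comparisons=tuple(labels),
                tss_variance=variances,
            )
        )
    return results
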