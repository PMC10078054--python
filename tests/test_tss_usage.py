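"""Tests for density clustering, TSS peaks, usage tables and switches."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import paraclu_cluster_set
from fipkit.tss_usage import (
    TagCluster,
    TagSite,
    differential_usage,
    paraclu,
    scaled_usage,
    stability_filter,
    stage_bins,
    top2_variance,
    tss_peaks,
    usage_table,
)


def _sites(pairs, chrom="chr1", strand="+"):
    return [TagSite(chrom, strand, p, c) for p, c in pairs]


class TestParaclu:
    def test_single_site_sentinels(self):
        (c,) = paraclu(_sites([(100, 10)]))
        assert (c.start, c.end, c.total) == (100, 100, 10)
        assert c.d_min == 0.0
        assert math.isinf(c.d_max)

    def test_adjacent_pair_single_cluster(self):
        clusters = paraclu(_sites([(1, 5), (2, 5)]))
        top = max(clusters, key=lambda c: c.span)
        assert (top.start, top.end, top.total) == (1, 2, 10)
        assert top.density == pytest.approx(5.0)

    def test_empty_input(self):
        assert paraclu([]) == []

    def test_mixed_chrom_rejected(self):
        with pytest.raises(ValueError):
            paraclu(_sites([(1, 2)]) + _sites([(5, 1)], chrom="chr2"))

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            paraclu(_sites([(1, 2), (1, 3)]))

    def test_matches_maximal_segment_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = rng.integers(1, 13)
            pos = np.sort(rng.choice(40, size=n, replace=False)).tolist()
            cnt = rng.integers(1, 11, size=n).tolist()
            got = {(c.start, c.end) for c in paraclu(_sites(list(zip(pos, cnt))))}
            assert got == paraclu_cluster_set(pos, cnt)

    def test_laminar_family_and_density_order(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = rng.integers(2, 30)
            pos = np.sort(rng.choice(200, size=n, replace=False)).tolist()
            cnt = rng.integers(1, 20, size=n).tolist()
            clusters = paraclu(_sites(list(zip(pos, cnt))))
            for a in clusters:
                for b in clusters:
                    overlap = a.start <= b.end and b.start <= a.end
                    nested = (a.start <= b.start and b.end <= a.end) or (
                        b.start <= a.start and a.end <= b.end
                    )
                    assert (not overlap) or nested  # laminar
                    if (a.start, a.end) != (b.start, b.end) and (
                        a.start <= b.start and b.end <= a.end
                    ):
                        # nested clusters live at strictly higher densities:
                        # the child's maximality interval starts where the
                        # parent's ends
                        assert b.d_min >= a.d_max - 1e-9

    def test_root_conserves_total_count(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(500, size=25, replace=False)).tolist()
        cnt = rng.integers(1, 15, size=25).tolist()
        clusters = paraclu(_sites(list(zip(pos, cnt))))
        roots = [
            c
            for c in clusters
            if not any(
                o is not c and o.start <= c.start and c.end <= o.end for o in clusters
            )
        ]
        assert sum(r.total for r in roots) == sum(cnt)


class TestStabilityFilter:
    def _cluster(self, d_min=1.0, d_max=4.0, total=50, span=100):
        return TagCluster("chr1", "+", 1, span, 2, total, d_min, d_max)

    def test_fold_rule(self):
        weak = self._cluster(d_min=2.0, d_max=3.0)
        assert stability_filter([weak], fold=2.0) == []
        assert stability_filter([weak], fold=1.4) == [weak]

    def test_all_disabled_is_identity(self):
        clusters = [self._cluster(), self._cluster(total=1, span=10_000)]
        assert stability_filter(clusters, fold=None, min_total=None, max_span=None) == clusters

    def test_span_and_total_rules(self):
        assert stability_filter([self._cluster(total=10)], min_total=30) == []
        assert stability_filter([self._cluster(span=300)], max_span=200) == []


class TestTssPeaks:
    ann = pd.DataFrame(
        {"chrom": ["chr1"], "position": [1_000], "strand": ["+"], "gene": ["g1"]}
    )

    def _cl(self, start, end, strand="+"):
        return TagCluster("chr1", strand, start, end, 2, 100, 1.0, 10.0)

    def test_wide_merged_peak_dropped(self):
        out = tss_peaks([[self._cl(900, 1_200)]], self.ann)  # width 301
        assert len(out) == 0

    def test_far_peak_dropped(self):
        out = tss_peaks([[self._cl(1_150, 1_200)]], self.ann)  # 150 bp away
        assert len(out) == 0

    def test_overlapping_annotated_peak_kept(self):
        out = tss_peaks([[self._cl(990, 1_020)]], self.ann)
        assert len(out) == 1
        assert out["tss_gene"].iloc[0] == "g1"

    def test_cross_group_union_merge(self):
        out = tss_peaks([[self._cl(990, 1_010)], [self._cl(1_005, 1_030)]], self.ann)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (990, 1_030)


class TestStageBins:
    def test_uniform_grid_examples(self):
        t = np.linspace(0, 1, 101)
        stages = dict(zip(t.round(2), stage_bins(t)))
        assert stages[0.05] == "early"
        assert stages[0.55] == "medium"
        assert stages[0.95] == "late"

    def test_extremes(self):
        stages = stage_bins([3.0, 7.5, 12.0])
        assert stages[0] == "early"
        assert stages[-1] == "late"

    def test_monotone_in_pseudotime(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.random(200))
        order = {"early": 0, "medium": 1, "late": 2}
        codes = [order[s] for s in stage_bins(t)]
        assert all(a <= b for a, b in zip(codes, codes[1:]))

    def test_constant_pseudotime_rejected(self):
        with pytest.raises(ValueError):
            stage_bins([2.0, 2.0, 2.0])


class TestUsageTable:
    def test_scaled_ceiling(self):
        assert scaled_usage([1, 2]) == [34, 67]
        assert scaled_usage([5]) == [100]

    def test_sum_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            counts = rng.integers(1, 50, size=rng.integers(1, 6))
            u = scaled_usage(counts)
            assert 100 <= sum(u) <= 100 + len(counts) - 1

    def _counts(self):
        rows = []
        for g, total in [("g1", 10), ("g2", 100), ("g3", 1000)]:
            for grp in ["early", "late"]:
                rows.append({"gene": g, "tss": f"{g}.a", "group": grp, "count": total // 2})
                rows.append({"gene": g, "tss": f"{g}.b", "group": grp, "count": total - total // 2})
        return pd.DataFrame(rows)

    def test_median_gene_not_missing(self):
        u = usage_table(self._counts())
        med = u[(u["gene"] == "g2")]
        assert not med["missing"].any()  # strict "smaller than" bound

    def test_extreme_totals_missing(self):
        u = usage_table(self._counts(), q_low=0.5, q_high=0.6)
        assert u[u["gene"] == "g1"]["missing"].all()  # below the median
        assert u[u["gene"] == "g3"]["missing"].all()  # above the 0.6 quantile

    def test_zero_total_gene_missing_not_nan(self):
        df = pd.DataFrame(
            [
                {"gene": "g1", "tss": "a", "group": "x", "count": 0},
                {"gene": "g1", "tss": "b", "group": "x", "count": 0},
                {"gene": "g2", "tss": "a", "group": "x", "count": 10},
            ]
        )
        u = usage_table(df)
        g1 = u[u["gene"] == "g1"]
        assert g1["missing"].all()
        assert (g1["usage"] == 0).all()


class TestDifferentialUsage:
    def _usage(self, early, late):
        rows = []
        for grp, vec in [("early", early), ("late", late)]:
            for i, c in enumerate(vec):
                rows.append(
                    {"gene": "g1", "tss": f"t{i}", "group": grp, "count": c,
                     "usage": c, "missing": False}
                )
        return pd.DataFrame(rows)

    def test_identical_usage_p_one(self):
        res = differential_usage(self._usage([50, 50], [50, 50]))
        assert res[0].p_adj_min == pytest.approx(1.0)

    def test_switch_detected_with_tiny_p(self):
        res = differential_usage(self._usage([90, 10], [10, 90]))
        assert res[0].p_adj_min < 1e-25

    def test_top2_variance_convention(self):
        # two highest usages 90 and 10: sample variance with denominator 1
        assert top2_variance([90, 10]) == pytest.approx(3200.0)
        assert top2_variance([90, 10, 40]) == pytest.approx(1250.0)

    def test_symmetric_in_group_order(self):
        a = differential_usage(self._usage([80, 20], [30, 70]))
        b = differential_usage(self._usage([30, 70], [80, 20]))
        assert a[0].p_adj_min == pytest.approx(b[0].p_adj_min)

    def test_gene_missing_in_all_but_one_group_skipped(self):
        u = self._usage([60, 40], [60, 40])
        u.loc[u["group"] == "late", "missing"] = True
        assert differential_usage(u) == []
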