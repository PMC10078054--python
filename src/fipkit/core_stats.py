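"""Shared statistical primitives.

Four small tools used throughout the pipeline:

* a one-sided rank-sum test (exact by permutation enumeration for small
  samples, tie-corrected normal approximation otherwise), used to test
  whether 5' signal at an enhancer core exceeds its flanks;
* Benjamini-Hochberg step-up adjustment;
* Fisher's exact test on 2 x n contingency tables (full fixed-margin
  enumeration when feasible, seeded Monte Carlo otherwise), used for
  differential TSS-usage testing;
* clonotype diversity indices (Shannon, inverse Simpson, Chao1).

All tests return both the p-value and a label saying which computational
route produced it, so downstream TSV reports can record the method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PValueSet",
    "ContingencyTable2xN",
    "DiversityResult",
    "TestResult",
    "rank_sum_greater",
    "bh_adjust",
    "fisher_exact",
    "diversity",
]

#: switch from exact enumeration to the normal approximation above this
#: many total observations in the rank-sum test
RANKSUM_EXACT_MAX_N = 12

#: switch from full fixed-margin enumeration to Monte Carlo above this
#: many candidate tables in the Fisher test
FISHER_MAX_TABLES = 1_000_000

#: Monte Carlo replicates for the Fisher test when enumeration is infeasible
FISHER_MC_REPLICATES = 100_000

#: relative tolerance when comparing table probabilities to the observed
#: one (mirrors the convention of common exact-test implementations)
_REL_EPS = 1e-7


@dataclass(frozen=True)
class TestResult:
    """A test statistic, its p-value and the computational route used."""

    statistic: float
    p: float
    method: str


@dataclass(frozen=True)
class PValueSet:
    """Raw p-values with their Benjamini-Hochberg adjusted companions."""

    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    method: str = "benjamini-hochberg"


@dataclass(frozen=True)
class ContingencyTable2xN:
    """A 2 x n table of non-negative integer counts.

    Rows are the two groups being compared (e.g. developmental stages),
    columns are categories (e.g. alternative TSSs of one gene).
    """

    counts: tuple[tuple[int, ...], tuple[int, ...]]
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape[0] != 2 or arr.shape[1] < 2:
            raise ValueError(f"expected a 2 x n table with n >= 2, got shape {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("table entries must be non-negative integers")
        if np.any(arr.sum(axis=1) == 0):
            raise ValueError("degenerate table: each row needs at least one positive entry")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class DiversityResult:
    """Shannon (natural log), inverse Simpson and Chao1 richness."""

    shannon: float
    inverse_simpson: float
    chao1: float


def rank_sum_greater(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_max_n: int = RANKSUM_EXACT_MAX_N,
) -> TestResult:
    """One-sided rank-sum test of ``x`` stochastically greater than ``y``.

    The statistic is the rank sum of ``x`` in the pooled sample using
    midranks for ties.  With at most ``exact_max_n`` total observations
    the p-value is computed by enumerating every assignment of the pooled
    values to the two groups (exact under the permutation null, ties
    included); otherwise a tie-corrected normal approximation with
    continuity correction is used.

    Returns a :class:`TestResult` with ``method`` in
    ``{"exact-enumeration", "normal-approx"}``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_greater requires nonempty samples in both groups")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = float(ranks[:n].sum())

    if n + m <= exact_max_n:
        total = 0
        at_least = 0
        # enumerate all C(n+m, n) assignments of pooled ranks to group x
        for idx in itertools.combinations(range(n + m), n):
            total += 1
            if ranks[list(idx)].sum() >= w_obs - 1e-12:
                at_least += 1
        return TestResult(statistic=w_obs, p=at_least / total, method="exact-enumeration")

    # tie-corrected normal approximation with continuity correction
    mu = n * (n + m + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var <= 0:  # all pooled values identical
        return TestResult(statistic=w_obs, p=1.0, method="normal-approx")
    from scipy.stats import norm

    z = (w_obs - mu - 0.5) / np.sqrt(var)
    return TestResult(statistic=w_obs, p=float(norm.sf(z)), method="normal-approx")


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, capped at 1.

    Input p-values must lie in (0, 1].  The output preserves input order.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def adjust_pvalues(p: Sequence[float]) -> PValueSet:
    """Convenience wrapper bundling raw and BH-adjusted p-values."""
    return PValueSet(raw=tuple(float(v) for v in p), adjusted=tuple(bh_adjust(p)))


def _log_table_prob(row1: np.ndarray, cols: np.ndarray, r1: int, logdenom: float) -> np.ndarray:
    """Log multivariate-hypergeometric probability of first-row vector(s)."""
    row2 = cols - row1
    lp = gammaln(cols + 1) - gammaln(row1 + 1) - gammaln(row2 + 1)
    return lp.sum(axis=-1) - logdenom


def _enumerate_first_rows(cols: np.ndarray, r1: int) -> np.ndarray:
    """All first-row vectors a with 0 <= a_j <= c_j and sum a = r1."""
    grids = np.meshgrid(*[np.arange(c + 1) for c in cols], indexing="ij")
    stacked = np.stack([g.ravel() for g in grids], axis=1)
    return stacked[stacked.sum(axis=1) == r1]


def fisher_exact(
    table: ContingencyTable2xN | Sequence[Sequence[int]],
    *,
    max_tables: int = FISHER_MAX_TABLES,
    n_replicates: int = FISHER_MC_REPLICATES,
    seed: int | None = None,
) -> TestResult:
    """Two-sided Fisher exact test on a 2 x n table.

    Under fixed margins the p-value is the total probability of tables no
    more probable than the observed one ("no-more-probable" two-sided
    convention, as in R's ``fisher.test``).  When the number of candidate
    tables exceeds ``max_tables`` the p-value is instead estimated by
    seeded Monte Carlo sampling from the multivariate hypergeometric null
    using the (b + 1) / (B + 1) estimator (``seed`` then required).

    ``method`` in the result is ``"exact-enumeration"`` or
    ``"monte-carlo"``; ``statistic`` is the observed table probability.
    """
    if not isinstance(table, ContingencyTable2xN):
        table = ContingencyTable2xN(tuple(tuple(int(v) for v in row) for row in table))
    arr = table.array
    cols = arr.sum(axis=0)
    r1 = int(arr[0].sum())
    total = int(arr.sum())
    logdenom = gammaln(total + 1) - gammaln(r1 + 1) - gammaln(total - r1 + 1)
    lp_obs = float(_log_table_prob(arr[0].astype(float), cols.astype(float), r1, logdenom))
    cutoff = lp_obs + np.log1p(_REL_EPS)

    n_candidates = int(np.prod([min(c, r1) + 1 for c in cols]))
    if n_candidates <= max_tables:
        rows = _enumerate_first_rows(cols, r1)
        lp = _log_table_prob(rows.astype(float), cols.astype(float), r1, logdenom)
        p = float(np.exp(lp[lp <= cutoff]).sum())
        return TestResult(statistic=float(np.exp(lp_obs)), p=min(p, 1.0), method="exact-enumeration")

    if seed is None:
        raise ValueError("Monte Carlo Fisher test requires a seed")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, r1, size=n_replicates)
    lp = _log_table_prob(draws.astype(float), cols.astype(float), r1, logdenom)
    b = int(np.sum(lp <= cutoff))
    return TestResult(
        statistic=float(np.exp(lp_obs)),
        p=(b + 1) / (n_replicates + 1),
        method="monte-carlo",
    )


def diversity(counts: Sequence[int]) -> DiversityResult:
    """Shannon, inverse Simpson and Chao1 indices of a count vector.

    Shannon entropy uses natural logs: ``H = -sum f_i ln f_i`` with
    ``f_i`` the relative frequencies.  Inverse Simpson is
    ``1 / sum f_i^2``.  Chao1 is ``S_obs + f1^2 / (2 f2)`` with ``f1``,
    ``f2`` the numbers of singletons and doubletons, falling back to the
    bias-corrected ``S_obs + f1 (f1 - 1) / 2`` when there are no
    doubletons.  Chao1 depends on absolute counts and is therefore not
    invariant to rescaling, unlike the other two indices.
    """
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("diversity requires a nonempty count vector")
    if np.any(arr < 1):
        raise ValueError("all counts must be >= 1")
    freqs = arr / arr.sum()
    shannon = float(-np.sum(freqs * np.log(freqs)))
    inv_simpson = float(1.0 / np.sum(freqs**2))
    s_obs = int(arr.size)
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    if f2 > 0:
        chao1 = s_obs + f1**2 / (2 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / 2
    return DiversityResult(shannon=shannon, inverse_simpson=inv_simpson, chao1=float(chao1))
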