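"""Droplet-overloading models: multiplets, barcode collisions, occupancy.

Cells loaded into a droplet microfluidic channel partition approximately
as Poisson: with N cells over D droplets the per-droplet occupancy is
Poisson(lambda = N / D), and an occupied droplet holds k cells with
zero-truncated Poisson probability.  In a standard run every multi-cell
droplet is a multiplet.  With a B-plex preindex (round1 barcode) added
before encapsulation, two cells in one droplet only collapse into one
apparent cell when they also share the round1 index, so the collision
rate drops by roughly a factor of B and the channel can be overloaded.

This module provides the closed forms, a Monte-Carlo twin, and the
empirical analytics applied to real composite barcodes (occupancy
histograms, species-mixing calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

__all__ = [
    "LoadingModel",
    "SpeciesCall",
    "conditional_multiplet_rate",
    "expected_collision_rates",
    "simulate_loading",
    "occupancy_histogram",
    "assign_species",
]

#: truncate Poisson occupancy sums once the remaining tail mass drops below this
POISSON_TAIL_EPS = 1e-12


@dataclass(frozen=True)
class LoadingModel:
    """Loading conditions of one channel.

    Parameters
    ----------
    n_cells : cells loaded into the channel (N).
    n_droplets : droplet partitions generated (D); roughly 100,000 for a
        standard Chromium channel.
    plexity : number of distinct round1 preindex barcodes (B); 1 recovers
        the non-preindexed standard workflow.
    """

    n_cells: int
    n_droplets: int
    plexity: int = 1

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_droplets <= 0:
            raise ValueError("n_cells and n_droplets must be positive")
        if self.plexity < 1:
            raise ValueError("plexity must be >= 1")

    @property
    def occupancy_rate(self) -> float:
        """Mean cells per droplet, lambda = N / D."""
        return self.n_cells / self.n_droplets


@dataclass(frozen=True)
class SpeciesCall:
    cell: str
    fraction_a: float
    label: str  # "A", "B" or "mixed"


def _k_range(lam: float) -> np.ndarray:
    """Occupancies 1..kmax covering all but POISSON_TAIL_EPS of the mass."""
    kmax = int(poisson.isf(POISSON_TAIL_EPS, lam)) + 1
    return np.arange(1, max(kmax, 2) + 1)


def conditional_multiplet_rate(model: LoadingModel) -> float:
    """Probability a cell-containing droplet holds two or more cells.

    Under Poisson loading with rate lambda this is
    ``1 - lambda * exp(-lambda) / (1 - exp(-lambda))`` -- the multiplet
    rate of the standard (non-preindexed) workflow at the same loading.
    """
    lam = model.occupancy_rate
    return float(1.0 - lam * np.exp(-lam) / -np.expm1(-lam))


def expected_collision_rates(
    model: LoadingModel,
    species_fractions: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Expected barcode-collision and observed mixed-species rates.

    A composite barcode (droplet barcode, round1 index) collides when two
    or more cells in the same droplet carry the same round1 index.  Both
    rates are fractions of *recovered composite barcodes*: summing over
    Poisson droplet occupancy k, a droplet with k cells spread uniformly
    over B round1 indices contributes ``B * (1 - (1-1/B)^k)`` expected
    occupied composite barcodes of which
    ``B * (1 - (1-1/B)^k - (k/B)(1-1/B)^(k-1))`` hold >= 2 cells.

    When ``species_fractions`` (h, 1-h) are given, the second return
    value is the rate of composite barcodes whose member cells span both
    species -- what a species-mixing (barnyard) experiment observes.
    Without fractions it equals the collision rate.
    """
    lam = model.occupancy_rate
    b = model.plexity
    if species_fractions is not None:
        fr = np.asarray(species_fractions, dtype=float)
        if fr.size != 2 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("species_fractions must be two non-negative values summing to 1")

    ks = _k_range(lam)
    pk = poisson.pmf(ks, lam)
    q = 1.0 - 1.0 / b
    occupied = b * (1.0 - q**ks)  # expected occupied composite barcodes
    single = ks * q ** (ks - 1.0)  # expected barcodes holding exactly 1 cell
    collided = occupied - single

    e_occ = float(np.sum(pk * occupied))
    e_coll = float(np.sum(pk * collided))
    barcode_collision = e_coll / e_occ

    if species_fractions is None:
        return barcode_collision, barcode_collision

    # expected barcodes with >= 2 cells spanning species: condition on j
    # cells landing in one barcode (Binomial(k, 1/B)), then mixed with
    # probability 1 - sum_s f_s^j
    from scipy.stats import binom

    e_mixed = 0.0
    for k, p in zip(ks, pk):
        js = np.arange(2, k + 1)
        if js.size == 0:
            continue
        pj = binom.pmf(js, k, 1.0 / b)
        p_same = np.sum(np.asarray(species_fractions, dtype=float)[:, None] ** js, axis=0)
        e_mixed += p * b * float(np.sum(pj * (1.0 - p_same)))
    return barcode_collision, e_mixed / e_occ


def simulate_loading(
    model: LoadingModel,
    seed: int,
    species_fractions: tuple[float, float] = (1.0, 0.0),
) -> pd.DataFrame:
    """Monte-Carlo twin of the analytic loading model.

    Assigns each of the N cells independently to a uniform droplet,
    a uniform round1 index, and a species drawn from
    ``species_fractions``.  Returns one row per cell with columns
    ``droplet``, ``round1``, ``species`` (0/1).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n = model.n_cells
    return pd.DataFrame(
        {
            "droplet": rng.integers(0, model.n_droplets, size=n),
            "round1": rng.integers(0, model.plexity, size=n),
            "species": (rng.random(n) >= species_fractions[0]).astype(int),
        }
    )


def collision_rates_from_simulation(cells: pd.DataFrame) -> tuple[float, float, int]:
    """Empirical (collision rate, mixed rate, n composite barcodes).

    Groups the per-cell table from :func:`simulate_loading` by composite
    barcode (droplet, round1); a barcode with >= 2 member cells is a
    collision, and one whose members span species is observed as mixed.
    """
    grouped = cells.groupby(["droplet", "round1"])["species"]
    sizes = grouped.size()
    n_barcodes = int(sizes.size)
    collision = float((sizes >= 2).mean())
    mixed = float((grouped.nunique() >= 2).mean())
    return collision, mixed, n_barcodes


def occupancy_histogram(cells: Iterable[tuple[str, str]] | pd.DataFrame) -> pd.DataFrame:
    """Cells per droplet, as resolved by the preindex.

    ``cells`` holds one entry per recovered cell: (round2 droplet
    barcode, round1 index), or a DataFrame with ``round2``/``round1``
    columns.  Droplets are keyed by round2; k is the number of distinct
    round1 indices seen in the droplet.  Returns a table with columns
    ``k`` and ``n_droplets``; the attribute ``df.attrs["fraction_1_3"]``
    reports the fraction of droplets holding 1-3 cells.
    """
    if not isinstance(cells, pd.DataFrame):
        cells = pd.DataFrame(list(cells), columns=["round2", "round1"])
    if len(cells) == 0:
        out = pd.DataFrame({"k": [], "n_droplets": []})
        out.attrs["fraction_1_3"] = float("nan")
        return out
    per_droplet = cells.groupby("round2")["round1"].nunique()
    hist = per_droplet.value_counts().sort_index()
    out = pd.DataFrame({"k": hist.index.to_numpy(), "n_droplets": hist.to_numpy()})
    out.attrs["fraction_1_3"] = float(per_droplet.between(1, 3).mean())
    return out


def assign_species(
    counts: pd.DataFrame,
    upper: float = 0.9,
    lower: float = 0.1,
) -> tuple[list[SpeciesCall], float]:
    """Species-mixing calls and the observed collision rate.

    ``counts`` has one row per composite barcode with columns
    ``counts_a`` and ``counts_b`` (UMIs mapped to each genome); the index
    holds the barcode names.  A barcode is species A when its A-fraction
    exceeds ``upper``, species B when below ``lower``, otherwise mixed
    (boundary values count as mixed).  The collision rate is the mixed
    fraction of all barcodes.
    """
    totals = counts["counts_a"] + counts["counts_b"]
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    frac = counts["counts_a"] / totals
    calls = []
    for cell, f in frac.items():
        label = "A" if f > upper else ("B" if f < lower else "mixed")
        calls.append(SpeciesCall(cell=str(cell), fraction_a=float(f), label=label))
    n_mixed = sum(1 for c in calls if c.label == "mixed")
    return calls, n_mixed / len(calls)
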