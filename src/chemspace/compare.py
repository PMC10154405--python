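"""Comparing element sequences and whole periodic systems across years.

A sequence α is summarised by its neighbourhood pair set
B_α = {{x, y} : |α(x) − α(y)| ≤ r}; the directed similarity of α towards
α′ is the overlap fraction z(α→α′) = |B_α ∩ B_α′| / |B_α|. A year's
periodic system is an ensemble of optimised sequences, and two systems
are compared by averaging z over all ordered sequence pairs; the
year-by-year matrix of these averages, normalised by each column's
maximum, is the evolution matrix. Its lower triangle measures
evolutionary preservation (how much of a past system persists later) and
its upper triangle anticipation capacity (how much of a future system was
already present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .optimize import SequenceEnsemble

log = logging.getLogger(__name__)

__all__ = [
    "pair_set",
    "seq_similarity",
    "ensemble_similarity",
    "PSComparisonMatrix",
    "evolution_matrix",
    "preservation_profile",
    "anticipation_profile",
    "anticipation_span",
]

Pair = tuple[str, str]


def pair_set(seq: Sequence[str], r: int) -> set[Pair]:
    """All unordered element pairs within sequence distance ``r``."""
    if r < 1:
        raise ValueError("radius must be >= 1")
    n = len(seq)
    if r >= n and n > 1:
        log.warning("radius %d >= roster size %d: pair set saturates", r, n)
    pairs: set[Pair] = set()
    for i in range(n):
        for j in range(i + 1, min(i + r + 1, n)):
            x, y = seq[i], seq[j]
            pairs.add((x, y) if x < y else (y, x))
    return pairs


def _restricted(pairs: set[Pair], common: frozenset[str] | None) -> set[Pair]:
    if common is None:
        return pairs
    return {p for p in pairs if p[0] in common and p[1] in common}


def seq_similarity(a: Sequence[str], b: Sequence[str], r: int) -> tuple[float, float]:
    """Directed overlap fractions (z(a→b), z(b→a)) of the two pair sets.

    Requires both sequences to run over the same roster; an empty pair set
    (single-element roster) compares as 1 by convention.
    """
    if sorted(a) != sorted(b):
        raise ValueError("sequences must share a roster")
    ba, bb = pair_set(a, r), pair_set(b, r)
    inter = len(ba & bb)
    z_ab = inter / len(ba) if ba else 1.0
    z_ba = inter / len(bb) if bb else 1.0
    return z_ab, z_ba


def ensemble_similarity(
    ens_i: SequenceEnsemble, ens_j: SequenceEnsemble, r: int
) -> float:
    """Raw (un-normalised) mean of z over all ordered sequence pairs.

    Systems over different element rosters (new elements discovered in
    between) are compared on the intersection roster: each pair set is
    built on its own sequence, then restricted to pairs whose both
    elements exist in both rosters, denominators included. This makes the
    measure insensitive to mere roster growth.
    """
    if not ens_i.sequences or not ens_j.sequences:
        raise ValueError("ensembles must be non-empty")
    ri, rj = frozenset(ens_i.roster), frozenset(ens_j.roster)
    common = None if ri == rj else ri & rj
    sets_i = [_restricted(pair_set(s, r), common) for s in ens_i.sequences]
    sets_j = [_restricted(pair_set(s, r), common) for s in ens_j.sequences]
    total = 0.0
    for ba in sets_i:
        for bb in sets_j:
            total += len(ba & bb) / len(ba) if ba else 1.0
    return total / (len(sets_i) * len(sets_j))


@dataclass
class PSComparisonMatrix:
    """Year×year periodic-system similarity (evolution) matrix.

    ``raw[i, j]`` holds the un-normalised mean z̄(year_i → year_j); ``zbar``
    is ``raw`` with each column divided by its maximum, so every column
    attains 1 somewhere. Raw values are kept because the normalisation is
    column-global and would otherwise block incremental updates.
    """

    years: list[int]
    raw: np.ndarray
    radius: int

    @property
    def zbar(self) -> np.ndarray:
        col_max = self.raw.max(axis=0)
        col_max = np.where(col_max > 0, col_max, 1.0)
        return self.raw / col_max

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        m = self.zbar if normalized else self.raw
        return pd.DataFrame(m, index=self.years, columns=self.years)

    def to_csv(self, path, normalized: bool = True) -> None:
        self.to_frame(normalized).to_csv(path)

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.zbar, origin="lower", cmap="RdBu_r", vmin=0, vmax=1,
                       extent=[self.years[0], self.years[-1]] * 2, aspect="auto")
        ax.set_xlabel("year j")
        ax.set_ylabel("year i")
        fig.colorbar(im, ax=ax, label=r"$\bar{z}(i \to j)$")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def evolution_matrix(
    ensembles: Mapping[int, SequenceEnsemble], r: int = 4
) -> PSComparisonMatrix:
    """Raw and column-normalised z̄ over every ordered pair of years."""
    years = sorted(ensembles)
    if len(years) < 2:
        raise ValueError("need at least two years")
    k = len(years)
    raw = np.zeros((k, k))
    for a, yi in enumerate(years):
        for b, yj in enumerate(years):
            raw[a, b] = ensemble_similarity(ensembles[yi], ensembles[yj], r)
    return PSComparisonMatrix(years, raw, r)


def preservation_profile(M: PSComparisonMatrix, year: int) -> dict[int, float]:
    """How much of ``year``'s system remains in each later year's system."""
    a = M.years.index(year)
    z = M.zbar
    return {yj: float(z[a, b]) for b, yj in enumerate(M.years) if yj > year}


def anticipation_profile(M: PSComparisonMatrix, year: int) -> dict[int, float]:
    """How much of ``year``'s system was already present in each earlier year."""
    a = M.years.index(year)
    z = M.zbar
    return {yj: float(z[a, b]) for b, yj in enumerate(M.years) if yj < year}


def anticipation_span(M: PSComparisonMatrix, year: int, threshold: float) -> int:
    """Longest run of consecutive past years whose z̄ exceeds ``threshold``."""
    profile = anticipation_profile(M, year)
    best = run = 0
    for y in sorted(profile):
        if profile[y] > threshold:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best
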