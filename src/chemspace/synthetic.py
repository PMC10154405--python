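"""Synthetic chemical-space generator with planted structure.

Emulates the statistical features of the real, proprietary substance
corpus that the analysis needs ground truth for: a roster of elements with
staggered discovery years, planted families of mutually substitutable
elements, formulas built from shared skeletons with one substitutable
slot, exponential growth of the cumulative formula count, and a tunable
substitution-noise rate. Families are planted by letting family mates fill
the same skeleton slots, which forces shared R–X_n templates and hence
high pairwise similarity downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .corpus import FormulaRecord, collapse_isomers, format_hill

log = logging.getLogger(__name__)

__all__ = [
    "Skeleton",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "growth_check",
    "planted_spec",
]


@dataclass(frozen=True)
class Skeleton:
    """A base formula with one substitutable slot of multiplicity ``m``.

    A record built from the skeleton is ``residual + m atoms of X`` where X
    is drawn from the skeleton's designated family. Slot multiplicity lets
    the generator plant valence-like patterns (X_1 vs X_2 slots).
    """

    residual: tuple[tuple[str, int], ...]  # sorted (element, count) pairs
    slot_multiplicity: int = 1
    family_index: int = 0

    @staticmethod
    def make(residual: dict[str, int], m: int = 1, family_index: int = 0) -> "Skeleton":
        return Skeleton(tuple(sorted(residual.items())), m, family_index)

    def formula_counts(self, element: str) -> dict[str, int]:
        counts = dict(self.residual)
        counts[element] = counts.get(element, 0) + self.slot_multiplicity
        return counts


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic chemical space."""

    elements: dict[str, int]          # symbol -> discovery year
    families: list[frozenset[str]]    # disjoint planted similarity groups
    skeletons: list[Skeleton]
    start_year: int = 1800
    end_year: int = 1860
    initial_count: int = 12           # cumulative record count at start_year
    growth_rate: float = 2 ** (1 / 16)  # per-year multiplicative growth
    noise_rate: float = 0.0           # P(slot filled from outside the family)
    seed: int = 0

    def __post_init__(self) -> None:
        fams = [frozenset(f) for f in self.families]
        self.families = fams
        seen: set[str] = set()
        for fam in fams:
            if fam & seen:
                raise ValueError("families must be pairwise disjoint")
            seen |= fam
            missing = fam - set(self.elements)
            if missing:
                raise ValueError(f"family elements missing from roster: {sorted(missing)}")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must lie in [0, 1]")
        for sk in self.skeletons:
            if not (0 <= sk.family_index < len(fams)):
                raise ValueError(f"skeleton family_index {sk.family_index} out of range")

    @staticmethod
    def from_yaml(path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        skeletons = [
            Skeleton.make(sk["residual"], sk.get("m", 1), sk.get("family", 0))
            for sk in raw.pop("skeletons")
        ]
        families = [frozenset(f) for f in raw.pop("families")]
        return SyntheticSpec(families=families, skeletons=skeletons, **raw)


@dataclass
class SyntheticTruth:
    """Generated records plus the planted ground truth."""

    records: list[FormulaRecord]
    true_families: list[frozenset[str]]
    first_compound_year: dict[str, int] = field(default_factory=dict)


def _year_rng(seed: int, year: int) -> np.random.Generator:
    # Per-year substream: extending the year range never perturbs earlier years.
    return np.random.default_rng(np.random.SeedSequence([seed, year]))


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Generate a record list with planted families and exponential growth.

    Deterministic given ``spec.seed``. The cumulative record count follows
    ``round(initial_count * growth_rate**(y - start_year))`` — the
    start-year batch stands in for the corpus accumulated before the
    window, so cumulative growth is exponential from the first year on.
    Each record is a skeleton whose slot is filled from the skeleton's
    family (probability ``1 - noise_rate``) or from any other
    already-discovered element (probability ``noise_rate``). Elements are
    eligible only from their discovery year on.
    """
    records: list[FormulaRecord] = []
    first_year: dict[str, int] = {}
    counter = 0
    prev_target = 0
    for year in range(spec.start_year, spec.end_year + 1):
        rng = _year_rng(spec.seed, year)
        # the cumulative record count tracks round(n0 * g^(y - y0)) exactly;
        # the year's new records are the successive differences
        target = round(spec.initial_count * spec.growth_rate ** (year - spec.start_year))
        n_new = max(target - prev_target, 0)
        prev_target = max(target, prev_target)
        discovered = sorted(s for s, d in spec.elements.items() if d <= year)
        if not discovered:
            continue
        for _ in range(n_new):
            sk = spec.skeletons[rng.integers(len(spec.skeletons))]
            fam_avail = sorted(s for s in spec.families[sk.family_index] if s in discovered)
            if not fam_avail:
                log.debug("year %d: skeleton %s skipped, family not yet discovered", year, sk)
                continue
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                outside = [s for s in discovered if s not in spec.families[sk.family_index]]
                pool = outside if outside else fam_avail
            else:
                pool = fam_avail
            x = pool[rng.integers(len(pool))]
            counts = sk.formula_counts(x)
            counter += 1
            records.append(FormulaRecord(f"s{counter:07d}", format_hill(counts), year))
            for sym in counts:
                first_year.setdefault(sym, year)
    return SyntheticTruth(records, list(spec.families), first_year)


def planted_spec(
    families: Sequence[Sequence[str]],
    skeletons_per_family: int = 12,
    start_year: int = 1800,
    end_year: int = 1814,
    initial_count: int = 250,
    growth_rate: float = 2 ** (1 / 16),
    noise_rate: float = 0.0,
    seed: int = 0,
    discovery_years: dict[str, int] | None = None,
) -> SyntheticSpec:
    """Build a spec with programmatically generated skeleton pools.

    Each family gets ``skeletons_per_family`` skeletons with distinct
    C/H/O backbone residuals (counts enumerated injectively, so any pool
    size is available) and slot multiplicities alternating between 1 and
    2, planting valence-like patterns. Template diversity matters: every
    skeleton is one compound context in which family mates substitute for
    each other, and similarity counts *distinct* shared contexts, so
    families need many contexts to stay separable once substitution noise
    sprinkles templates across family boundaries.
    """
    families = [frozenset(f) for f in families]
    elements = {e: start_year for f in families for e in f}
    if discovery_years:
        elements.update(discovery_years)
    skeletons: list[Skeleton] = []
    k = 0
    for fi in range(len(families)):
        for j in range(skeletons_per_family):
            # (k % 9, k//9 % 9, k//81) <-> k, so residuals never collide
            residual = {"C": 1 + k % 9, "H": 1 + (k // 9) % 9}
            if k // 81:
                residual["O"] = k // 81
            skeletons.append(Skeleton.make(residual, 1 + j % 2, fi))
            k += 1
    return SyntheticSpec(
        elements=elements,
        families=families,
        skeletons=skeletons,
        start_year=start_year,
        end_year=end_year,
        initial_count=initial_count,
        growth_rate=growth_rate,
        noise_rate=noise_rate,
        seed=seed,
    )


def growth_check(truth: SyntheticTruth) -> float:
    """Estimate the doubling time (years) of the cumulative corpus size.

    The corpus is the set of unique molecular formulas, so duplicate
    records add nothing. Least-squares slope of log10(cumulative distinct
    formulas) against the record years, converted to a doubling time
    log10(2)/slope. A flat corpus (no new formulas) has zero slope and
    returns ``inf``.
    """
    years = sorted({r.year for r in truth.records})
    if len(years) < 3:
        raise ValueError("need records spanning at least 3 years")
    timeline = collapse_isomers(truth.records, (years[0], years[-1]))
    new_by_year: dict[int, int] = {}
    for f in timeline:
        new_by_year[f.year] = new_by_year.get(f.year, 0) + 1
    cum = np.cumsum([new_by_year.get(y, 0) for y in years])
    slope = np.polyfit(np.asarray(years, dtype=float), np.log10(cum), 1)[0]
    if slope <= 0:
        return math.inf
    return math.log10(2.0) / slope
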