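"""Element similarity from molecular-formula templates.

Every molecular formula A_a...Q_q...Z_z is rewritten, for each element Q
with count q and each n ≤ q, as R—Q_n where R is the residual formula
after removing n atoms of Q. The template R—X_n (the residual plus the
slot size; the element itself is not part of the identity) is then *held*
by every element that can fill the slot to give a formula in the corpus.
The co-occurrence c(x, y) counts the templates x and y hold in common —
the number of compound contexts in which the two elements are mutually
replaceable — and is normalised to a similarity

    s(x, y) = sqrt( c(x, y)^2 / ( (sum_x' c(x', y)) (sum_y' c(x, y')) ) )

whose values are bounded to [0, 0.5]. The diagonal c(x, x) is the
self-similarity: the number of x's templates shared with at least one
other element, which is what keeps the normalised values within the
bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus import CorpusTimeline, MolecularFormula, format_hill

__all__ = [
    "Template",
    "TemplateIndex",
    "CooccurrenceMatrix",
    "SimilarityMatrix",
    "extract_templates",
    "build_template_index",
    "build_cooccurrence",
    "normalize_similarity",
    "similarity_from_corpus",
    "similarity_timeline",
]

#: A template identity: (canonical Hill string of the residual R, slot count n).
Template = tuple[str, int]


def extract_templates(counts: Mapping[str, int]) -> set[tuple[str, Template]]:
    """All (element, template) pairs a formula gives rise to.

    For every element Q with count q and every n in 1..q, the formula
    yields the template (R, n) with R the formula minus n atoms of Q, held
    by Q. Single-element formulas yield templates with an empty residual.
    """
    out: set[tuple[str, Template]] = set()
    for q_sym, q in counts.items():
        for n in range(1, q + 1):
            residual = {s: c for s, c in counts.items() if s != q_sym}
            if n < q:
                residual[q_sym] = q - n
            out.add((q_sym, (format_hill(residual) if residual else "", n)))
    return out


@dataclass
class TemplateIndex:
    """Which templates each element holds, with reverse holder lookup."""

    holds: dict[str, set[Template]] = field(default_factory=dict)
    holders: dict[Template, set[str]] = field(default_factory=dict)

    def add_formula(self, counts: Mapping[str, int]) -> None:
        for element, template in extract_templates(counts):
            self.holds.setdefault(element, set()).add(template)
            self.holders.setdefault(template, set()).add(element)

    @property
    def roster(self) -> list[str]:
        return sorted(self.holds)


def build_template_index(corpus: Iterable[MolecularFormula]) -> TemplateIndex:
    index = TemplateIndex()
    for mf in corpus:
        index.add_formula(mf.counts)
    return index


@dataclass
class CooccurrenceMatrix:
    """Symmetric element×element template co-occurrence counts."""

    roster: list[str]
    c: np.ndarray  # (n, n) non-negative integers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=self.roster, columns=self.roster)


@dataclass
class SimilarityMatrix:
    """Normalised element-similarity matrix for one year's chemical space."""

    roster: list[str]
    s: np.ndarray  # (n, n) reals in [0, 0.5]
    year: int | None = None

    def value(self, x: str, y: str) -> float:
        i, j = self.roster.index(x), self.roster.index(y)
        return float(self.s[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.s, index=self.roster, columns=self.roster)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @staticmethod
    def from_csv(path, year: int | None = None) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return SimilarityMatrix(list(df.index), df.to_numpy(dtype=float), year)


def build_cooccurrence(
    corpus: Iterable[MolecularFormula] | TemplateIndex,
    self_mode: str = "shared",
) -> CooccurrenceMatrix:
    """Template co-occurrence counts over a corpus.

    Off-diagonal entries count template identities held by both elements
    (set intersection — a template reachable through many compounds still
    counts once). The diagonal convention is controlled by ``self_mode``:
    ``"shared"`` (default) counts only an element's templates held by at
    least one other element; ``"all"`` counts every template it holds.
    """
    if self_mode not in ("shared", "all"):
        raise ValueError("self_mode must be 'shared' or 'all'")
    index = corpus if isinstance(corpus, TemplateIndex) else build_template_index(corpus)
    roster = index.roster
    pos = {sym: i for i, sym in enumerate(roster)}
    n = len(roster)
    c = np.zeros((n, n), dtype=np.int64)
    for template, holder_set in index.holders.items():
        if len(holder_set) < 2:
            continue
        idx = sorted(pos[h] for h in holder_set)
        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1:]:
                c[i, j] += 1
                c[j, i] += 1
    for sym in roster:
        i = pos[sym]
        if self_mode == "all":
            c[i, i] = len(index.holds[sym])
        else:
            c[i, i] = sum(1 for t in index.holds[sym] if len(index.holders[t]) >= 2)
    return CooccurrenceMatrix(roster, c)


def normalize_similarity(cooc: CooccurrenceMatrix, year: int | None = None) -> SimilarityMatrix:
    """Normalise co-occurrence counts to similarities bounded by 0.5.

    The row and column sums in the denominator run over the full roster
    including the diagonal self-similarity term; pairs with a zero
    denominator get similarity 0.
    """
    c = cooc.c.astype(float)
    sums = c.sum(axis=0)  # symmetric: row sums equal column sums
    denom = np.outer(sums, sums)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, np.sqrt(c**2 / denom), 0.0)
    np.fill_diagonal(s, 0.0)
    return SimilarityMatrix(cooc.roster, s, year)


def similarity_from_corpus(
    corpus: Iterable[MolecularFormula],
    year: int | None = None,
    self_mode: str = "shared",
) -> SimilarityMatrix:
    """Convenience: corpus → templates → co-occurrence → similarity."""
    return normalize_similarity(build_cooccurrence(corpus, self_mode), year)


def similarity_timeline(
    timeline: CorpusTimeline,
    years: Iterable[int],
    self_mode: str = "shared",
) -> dict[int, SimilarityMatrix]:
    """Similarity matrices for the cumulative corpus at each requested year.

    Grows one template index incrementally year by year; because the index
    is a plain union over formulas, the result is identical to recomputing
    each year from scratch.
    """
    years = sorted(set(int(y) for y in years))
    by_year = timeline.by_year()
    index = TemplateIndex()
    out: dict[int, SimilarityMatrix] = {}
    prev = None
    for t in years:
        lo = prev + 1 if prev is not None else min(by_year, default=t)
        for y in range(min(lo, t), t + 1):
            for mf in by_year.get(y, ()):
                index.add_formula(mf.counts)
        prev = t
        out[t] = normalize_similarity(build_cooccurrence(index, self_mode), t)
    return out
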