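"""Molecular-formula corpus handling.

Substances enter the analysis as (id, molecular formula, year of first
publication) records. All isomers collapse onto their molecular formula
(MF), each MF keeping the year and id of its oldest record, and the
chemical space at time ``t`` is the cumulative set of MFs first published
no later than ``t``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .elements import ELEMENT_SET, hill_order

__all__ = [
    "FormulaParseError",
    "FormulaRecord",
    "MolecularFormula",
    "CorpusTimeline",
    "parse_formula",
    "format_hill",
    "collapse_isomers",
    "read_records",
    "write_corpus_summary",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

DEFAULT_YEAR_RANGE = (1800, 2021)


class FormulaParseError(ValueError):
    """A molecular-formula string does not conform to the flat dialect."""

    def __init__(self, text: str, token: str, position: int):
        self.text = text
        self.token = token
        self.position = position
        super().__init__(
            f"cannot parse formula {text!r}: offending token {token!r} at position {position}"
        )


@dataclass(frozen=True)
class FormulaRecord:
    """One raw substance record: identifier, formula string, year."""

    id: str
    formula_text: str
    year: int


def parse_formula(formula_text: str) -> dict[str, int]:
    """Parse a flat Hill-style molecular formula into an element→count map.

    The supported dialect is a sequence of element symbols, each followed by
    an optional positive integer count. No charges, isotope labels,
    hydrates/dots or parenthesised groups. Repeated symbols are summed.

    >>> parse_formula("C6H5Br")
    {'C': 6, 'H': 5, 'Br': 1}
    """
    if not formula_text or not formula_text.strip():
        raise FormulaParseError(formula_text, "", 0)
    text = formula_text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise FormulaParseError(text, text[pos], pos)
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ELEMENT_SET:
            raise FormulaParseError(text, m.group(0), pos)
        pos = m.end()
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n < 1:
                raise FormulaParseError(text, digits, pos - len(digits))
        counts[symbol] = counts.get(symbol, 0) + n
    return counts


def format_hill(counts: Mapping[str, int]) -> str:
    """Render an element→count map as a Hill-ordered formula string."""
    parts = []
    for sym in hill_order(counts):
        n = counts[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


class MolecularFormula:
    """An element-count multiset with the year and id of its oldest record.

    Two instances with identical counts compare (and hash) equal: the count
    multiset is the identity, matching the isomer-collapse semantics.
    """

    __slots__ = ("counts", "year", "id", "_key")

    def __init__(self, counts: Mapping[str, int], year: int, id: str = ""):
        if not counts:
            raise ValueError("empty formula")
        for sym, n in counts.items():
            if sym not in ELEMENT_SET:
                raise ValueError(f"unknown element symbol {sym!r}")
            if n < 1:
                raise ValueError(f"non-positive count for {sym}")
        self.counts = dict(counts)
        self.year = int(year)
        self.id = id
        self._key = tuple(sorted(self.counts.items()))

    @property
    def key(self) -> tuple[tuple[str, int], ...]:
        return self._key

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self.counts)

    def __eq__(self, other) -> bool:
        return isinstance(other, MolecularFormula) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"MolecularFormula({format_hill(self.counts)!r}, year={self.year}, id={self.id!r})"


@dataclass
class CorpusTimeline:
    """Unique molecular formulas indexed by year of first publication."""

    formulas: dict[tuple, MolecularFormula] = field(default_factory=dict)
    skipped: list[tuple[FormulaRecord, str]] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return sorted({mf.year for mf in self.formulas.values()})

    def by_year(self) -> dict[int, list[MolecularFormula]]:
        out: dict[int, list[MolecularFormula]] = {}
        for mf in self.formulas.values():
            out.setdefault(mf.year, []).append(mf)
        return out

    def corpus_at(self, t: int) -> set[MolecularFormula]:
        """Cumulative chemical space: every formula first published by year ``t``."""
        return {mf for mf in self.formulas.values() if mf.year <= t}

    def __len__(self) -> int:
        return len(self.formulas)

    def __iter__(self) -> Iterator[MolecularFormula]:
        return iter(self.formulas.values())


def collapse_isomers(
    records: Iterable[FormulaRecord],
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> CorpusTimeline:
    """Collapse substance records onto unique molecular formulas.

    Every record whose formula parses is mapped to its count multiset; all
    records sharing one multiset (isomers) collapse to a single
    :class:`MolecularFormula` carrying the minimum year, with ties on year
    broken by the lexicographically smallest id. Unparseable records and
    records outside ``year_range`` go to the timeline's skip report.
    """
    lo, hi = year_range
    timeline = CorpusTimeline()
    for rec in records:
        if not (lo <= rec.year <= hi):
            timeline.skipped.append((rec, f"year {rec.year} outside [{lo}, {hi}]"))
            continue
        try:
            counts = parse_formula(rec.formula_text)
        except FormulaParseError as exc:
            timeline.skipped.append((rec, str(exc)))
            continue
        mf = MolecularFormula(counts, rec.year, rec.id)
        prev = timeline.formulas.get(mf.key)
        if prev is None or (mf.year, mf.id) < (prev.year, prev.id):
            timeline.formulas[mf.key] = mf
    return timeline


def read_records(path, id_col="id", formula_col="formula", year_col="year") -> list[FormulaRecord]:
    """Read substance records from a TSV/CSV file with a header row."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={id_col: str, formula_col: str})
    return [
        FormulaRecord(str(r[id_col]), str(r[formula_col]), int(r[year_col]))
        for _, r in df.iterrows()
    ]


def write_records(records: Iterable[FormulaRecord], path) -> None:
    df = pd.DataFrame(
        [(r.id, r.formula_text, r.year) for r in records],
        columns=["id", "formula", "year"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_corpus_summary(timeline: CorpusTimeline, path) -> pd.DataFrame:
    """Write per-year new-formula and cumulative counts as TSV."""
    by_year = timeline.by_year()
    years = sorted(by_year)
    rows, cum = [], 0
    for y in years:
        cum += len(by_year[y])
        rows.append((y, len(by_year[y]), cum))
    df = pd.DataFrame(rows, columns=["year", "n_new_formulas", "n_cumulative"])
    df.to_csv(path, sep="\t", index=False)
    return df


def write_skip_report(timeline: CorpusTimeline, path) -> None:
    df = pd.DataFrame(
        [(r.id, r.formula_text, r.year, reason) for r, reason in timeline.skipped],
        columns=["id", "formula", "year", "reason"],
    )
    df.to_csv(path, sep="\t", index=False)
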