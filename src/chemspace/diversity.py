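"""Per-element variability in compound counts and template diversity.

For each element x and year y, A[x, y] is the accumulated number of
distinct formulas containing x published by y, and T[x, y] the
accumulated number of distinct templates R–X_n held by x. The year-over-
year variability log(A[x, y+1]) − log(A[x, y]) (and likewise for T) is an
indicator of surges in an element's chemistry and its diversity; values
are clipped to [0.0, 0.1] as in the reference visualisation. Logarithms
are base 10 by default (configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .corpus import CorpusTimeline
from .similarity import extract_templates

__all__ = ["accumulate_counts", "variability", "diversity_table"]

DEFAULT_CLIP = (0.0, 0.1)


def accumulate_counts(timeline: CorpusTimeline) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Element×year accumulated compound (A) and template (T) counts.

    Years span the timeline's full range consecutively; both matrices are
    non-decreasing along years. Duplicate formulas contribute once (set
    semantics), and a template held via several compounds counts once.
    """
    formulas = sorted(timeline, key=lambda mf: mf.year)
    if not formulas:
        raise ValueError("empty timeline")
    years = list(range(formulas[0].year, max(mf.year for mf in formulas) + 1))
    elements = sorted({e for mf in formulas for e in mf.counts})
    y_pos = {y: k for k, y in enumerate(years)}
    e_pos = {e: k for k, e in enumerate(elements)}

    new_a = np.zeros((len(elements), len(years)), dtype=np.int64)
    new_t = np.zeros_like(new_a)
    seen_templates: dict[str, set] = {e: set() for e in elements}
    for mf in formulas:  # ascending year: first-appearance bookkeeping is exact
        col = y_pos[mf.year]
        for e in mf.counts:
            new_a[e_pos[e], col] += 1
        for e, tpl in extract_templates(mf.counts):
            if tpl not in seen_templates[e]:
                seen_templates[e].add(tpl)
                new_t[e_pos[e], col] += 1
    A = pd.DataFrame(np.cumsum(new_a, axis=1), index=elements, columns=years)
    T = pd.DataFrame(np.cumsum(new_t, axis=1), index=elements, columns=years)
    return A, T


def variability(
    counts: pd.DataFrame,
    clip_range: tuple[float, float] = DEFAULT_CLIP,
    base: float = 10.0,
) -> pd.DataFrame:
    """Year-over-year log differences of accumulated counts, clipped.

    Entry (x, y) = log(counts[x, y]) − log(counts[x, y−1]), labelled by the
    later year; undefined (NaN) wherever either count is zero — an
    element's first year has no predecessor ratio and is masked, not
    clipped to the ceiling.
    """
    vals = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.where(vals > 0, np.log(vals) / np.log(base), np.nan)
    diff = logs[:, 1:] - logs[:, :-1]
    diff = np.clip(diff, *clip_range)
    return pd.DataFrame(diff, index=counts.index, columns=counts.columns[1:])


def diversity_table(
    timeline: CorpusTimeline,
    clip_range: tuple[float, float] = DEFAULT_CLIP,
    base: float = 10.0,
) -> pd.DataFrame:
    """Long-format table (element, year, dA, dT) of both variability measures."""
    A, T = accumulate_counts(timeline)
    dA = variability(A, clip_range, base)
    dT = variability(T, clip_range, base)
    rows = []
    for e in dA.index:
        for y in dA.columns:
            rows.append((e, int(y), dA.loc[e, y], dT.loc[e, y]))
    return pd.DataFrame(rows, columns=["element", "year", "dA", "dT"])


def plot_variability(dv: pd.DataFrame, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.25 * len(dv.index) + 1.5))
    im = ax.imshow(dv.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                   vmin=DEFAULT_CLIP[0], vmax=DEFAULT_CLIP[1])
    ax.set_yticks(range(len(dv.index)), dv.index)
    step = max(1, len(dv.columns) // 10)
    ax.set_xticks(range(0, len(dv.columns), step), dv.columns[::step])
    ax.set_xlabel("year")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
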