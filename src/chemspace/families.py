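"""Detection of families of similar elements.

A family shows up as a high-contrast square on the diagonal of a
similarity matrix whose rows/columns have been reshuffled by an optimised
element sequence (similar elements sit together, so their mutual
similarities form a bright diagonal block). Detection is a computer-vision
pipeline — diagonal suppression, up-sampling, blurring, Canny edge
detection, and square filtering — run under many sampled parameter sets
and over every sequence of the ensemble, with a statistical
noise-reduction (SNR) consensus step that keeps only element memberships
supported by at least half of the mutually most-similar detections.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import feature

from .optimize import SequenceEnsemble
from .similarity import SimilarityMatrix

__all__ = [
    "CVParams",
    "FamilyCollection",
    "ReshuffledImage",
    "reshuffle",
    "cv_detect",
    "sample_cv_params",
    "tanimoto",
    "snr_reduce",
    "detect_families",
    "family_trajectories",
]

#: Sum of the two Canny thresholds (8-bit Sobel units): high = THRESHOLD_SUM - b.
THRESHOLD_SUM = 40
#: Gain of a 3x3 Sobel kernel on a unit-slope ramp; converts 8-bit Sobel
#: threshold units into the per-pixel gradient units scikit-image uses.
_SOBEL_GAIN = 8.0

Family = frozenset[str]


@dataclass(frozen=True)
class CVParams:
    """Parameters of one computer-vision detection pass."""

    upsample_factor: int = 15
    blur_window: int = 17
    canny_low: float = 10.0       # th, in 8-bit Sobel units
    boltzmann_beta: float = 20.0
    max_family_size: int = 20

    def __post_init__(self) -> None:
        if self.blur_window % 2 == 0:
            raise ValueError("blur_window must be odd")
        if self.canny_low < 0 or self.canny_low > THRESHOLD_SUM:
            raise ValueError(f"canny_low must lie in [0, {THRESHOLD_SUM}]")

    @property
    def canny_high(self) -> float:
        return float(THRESHOLD_SUM)


def sample_cv_params(rng: np.random.Generator, n: int, beta: float = 20.0,
                     **overrides) -> list[CVParams]:
    """Sample ``n`` parameter sets: blur window uniform over {17, 19, 21, 23},
    low threshold th on the grid 0..39 with p(th) ∝ exp(−th/β)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = np.arange(THRESHOLD_SUM)
    p = np.exp(-grid / beta)
    p /= p.sum()
    windows = np.array([17, 19, 21, 23])
    out = []
    for _ in range(n):
        th = int(rng.choice(grid, p=p))
        w = int(windows[rng.integers(len(windows))])
        out.append(CVParams(blur_window=w, canny_low=float(th),
                            boltzmann_beta=beta, **overrides))
    return out


@dataclass
class ReshuffledImage:
    """A similarity matrix permuted into sequence order."""

    values: np.ndarray     # (n, n), pixel (i, j) = s(order[i], order[j])
    order: list[str]


def reshuffle(S: SimilarityMatrix, seq: Sequence[str]) -> ReshuffledImage:
    """Permute rows and columns of ``S`` into the order of ``seq``."""
    if sorted(seq) != sorted(S.roster):
        raise ValueError("sequence is not a permutation of the similarity-matrix roster")
    idx = [S.roster.index(sym) for sym in seq]
    return ReshuffledImage(S.s[np.ix_(idx, idx)].copy(), list(seq))


@dataclass
class FamilyCollection:
    """A set of detected element families with a provenance tag."""

    families: list[Family] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.families = _clean(self.families)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def to_json_obj(self) -> dict:
        return {"provenance": self.provenance,
                "families": [sorted(f) for f in self.families]}


def _clean(families: Iterable[Family]) -> list[Family]:
    """Drop empty and one-element families and duplicates; canonical order."""
    uniq = {f for f in (frozenset(x) for x in families) if len(f) >= 2}
    return sorted(uniq, key=lambda f: tuple(sorted(f)))


def _suppress_diagonal(a: np.ndarray) -> np.ndarray:
    """Replace each diagonal pixel with the mean of its left/right neighbours."""
    out = a.copy()
    n = a.shape[0]
    for i in range(n):
        nb = []
        if i > 0:
            nb.append(a[i, i - 1])
        if i < n - 1:
            nb.append(a[i, i + 1])
        out[i, i] = float(np.mean(nb)) if nb else a[i, i]
    return out


def cv_detect(image: ReshuffledImage, params: CVParams) -> FamilyCollection:
    """Detect diagonal square blocks in a reshuffled similarity image.

    Steps: (a) diagonal suppression; (b) up-sampling by
    ``upsample_factor``, box blur of ``blur_window`` pixels, zero padding;
    (c) Canny edge detection with thresholds (th, 40) in 8-bit Sobel
    units; (d) connected edge shapes filtered to squares centred on the
    diagonal spanning at most ``max_family_size`` original pixels. Each
    retained square [p, q) maps to the family {order[p], …, order[q−1]}.
    """
    n = image.values.shape[0]
    if n < 3:
        return FamilyCollection([], provenance="too-small")
    u = params.upsample_factor

    # (a) diagonal suppression at matrix resolution, then 8-bit intensity
    # scale: the off-diagonal range is contrast-stretched to [0, 255]. For a
    # matrix attaining the 0.5 similarity bound this is exactly the fixed
    # s/0.5*255 mapping; for dimmer matrices it keeps block contrast in the
    # regime the fixed Canny threshold sum was designed for.
    a = _suppress_diagonal(image.values)
    lo, hi = float(a.min()), float(a.max())
    a = (a - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(a)
    # (b) up-sample, Gaussian blur (sigma from window size, the usual
    # kernel-size convention), pad. A smooth ramp keeps a unique gradient
    # maximum at the block boundary for the edge detector.
    big = np.kron(a, np.ones((u, u)))
    sigma = 0.3 * ((params.blur_window - 1) * 0.5 - 1) + 0.8
    big = ndimage.gaussian_filter(big, sigma, mode="nearest")
    pad = u
    big = np.pad(big, pad, mode="constant")
    # (c) Canny; thresholds converted from 8-bit Sobel units to gradient units
    edges = feature.canny(
        big,
        sigma=1.0,
        low_threshold=params.canny_low / _SOBEL_GAIN,
        high_threshold=params.canny_high / _SOBEL_GAIN,
    )
    # (d) squares on the diagonal. Generic contour analysis fails here:
    # blocks tile the diagonal, so their edge rings touch at shared corners
    # and T-junctions merge nested and adjacent rings into one component.
    # Instead every candidate diagonal interval [p, q) is scored by the
    # fraction of its upper-triangle perimeter (top and right side of the
    # square, outside a thin diagonal band) covered by edge pixels, and
    # well-covered candidates are kept.
    found = _score_diagonal_squares(edges, n, u, pad, params.max_family_size)
    fams = [frozenset(image.order[p:q]) for p, q in sorted(found)]
    tag = f"u{u}-w{params.blur_window}-th{params.canny_low:g}"
    return FamilyCollection(fams, provenance=tag)


#: Minimum fraction of a candidate square's perimeter that must carry edges.
_COVERAGE_MIN = 0.6


def _score_diagonal_squares(
    edges: np.ndarray, n: int, u: int, pad: int, max_size: int
) -> set[tuple[int, int]]:
    """Candidate intervals [p, q) whose square outline is traced by edges.

    For each candidate, the top side (row p·u, columns p·u..q·u) and right
    side (column q·u, rows p·u..q·u) of the square are walked in upsampled
    coordinates with a ±u/4 tolerance strip; pixels within u/2 of the main
    diagonal are excluded (the diagonal region carries no shape
    information). Candidates with perimeter coverage ≥ 0.6 then go through
    greedy non-maximum suppression: best-covered first, suppressing any
    candidate whose diagonal extent overlaps an accepted square — nested
    or straddling squares lose to the better-traced outline.
    """
    tol = max(2, u // 4)
    band = u // 2
    size = edges.shape[0]

    def side_coverage(fixed: int, lo: int, hi: int, horizontal: bool) -> tuple[int, int]:
        s0, s1 = max(fixed - tol, 0), min(fixed + tol + 1, size)
        strip = edges[s0:s1, lo:hi] if horizontal else edges[lo:hi, s0:s1]
        hit = strip.any(axis=0 if horizontal else 1)
        along = np.arange(lo, hi)
        keep = np.abs(along - fixed) > band  # outside the diagonal band
        return int(hit[keep].sum()), int(keep.sum())

    scored: list[tuple[float, int, int]] = []
    for p in range(n):
        rp = p * u + pad
        for q in range(p + 2, min(p + max_size, n) + 1):
            cq = q * u + pad
            cov_t, tot_t = side_coverage(rp, rp, cq, horizontal=True)
            cov_r, tot_r = side_coverage(cq, rp, cq, horizontal=False)
            total = tot_t + tot_r
            if total and (cov_t + cov_r) / total >= _COVERAGE_MIN:
                scored.append(((cov_t + cov_r) / total, p, q))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    found: set[tuple[int, int]] = set()
    for _, p, q in scored:
        if all(q <= p2 or q2 <= p for p2, q2 in found):
            found.add((p, q))
    return found


def tanimoto(a: Iterable[str], b: Iterable[str]) -> float:
    """Tanimoto (Jaccard) similarity of two element sets; ∅ vs ∅ is 0."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def _best_match(fam: Family, collection: Sequence[Family]) -> Family | None:
    best, best_t = None, -1.0
    for cand in collection:  # collections are canonically sorted: ties deterministic
        t = tanimoto(fam, cand)
        if t > best_t:
            best, best_t = cand, t
    return best


def snr_reduce(pool: Sequence[FamilyCollection], m: int = 3) -> FamilyCollection:
    """Statistical noise reduction over a pool of family collections.

    Each iteration: (a) every family gathers itself plus the
    most-Tanimoto-similar family from every other collection; (b) the
    gathered set is replaced by its majority family — the elements present
    in at least 50% of the gathered families; (c) empty, one-element and
    duplicate families are dropped. After ``m`` iterations the pool is
    collapsed into a single collection (e), cleaned the same way.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    colls = [list(c) for c in pool]
    for _ in range(m):
        new_colls = []
        for i, coll in enumerate(colls):
            new_coll = []
            for fam in coll:
                gathered = [fam]
                for j, other in enumerate(colls):
                    if j == i or not other:
                        continue
                    match = _best_match(fam, other)
                    if match is not None:
                        gathered.append(match)
                need = math.ceil(0.5 * len(gathered))
                votes = Counter(e for f in gathered for e in f)
                majority = frozenset(e for e, v in votes.items() if v >= need)
                new_coll.append(majority)
            new_colls.append(_clean(new_coll))
        colls = new_colls
    final = _clean(f for coll in colls for f in coll)
    return FamilyCollection(final, provenance=f"snr-m{m}")


def detect_families(
    S: SimilarityMatrix,
    ensemble: SequenceEnsemble,
    n_params: int = 25,
    m_iterations: int = 3,
    rng: np.random.Generator | None = None,
    cv_overrides: dict | None = None,
) -> FamilyCollection:
    """Full family-detection pipeline for one year.

    For each sequence of the ensemble the similarity matrix is reshuffled
    into an image; CV detection runs under ``n_params`` sampled parameter
    sets and the per-image results are SNR-consolidated; a final SNR pass
    over the per-image collections yields the output collection.
    """
    rng = rng or np.random.default_rng(0)
    if len(S.roster) == 0:
        return FamilyCollection([], provenance="empty")
    per_image: list[FamilyCollection] = []
    for k, seq in enumerate(ensemble.sequences):
        image = reshuffle(S, seq)
        params = sample_cv_params(rng, n_params, **(cv_overrides or {}))
        collections = [cv_detect(image, p) for p in params]
        collections = [c for c in collections if len(c)]
        if collections:
            per_image.append(snr_reduce(collections, m_iterations))
    per_image = [c for c in per_image if len(c)]
    if not per_image:
        return FamilyCollection([], provenance="no-detections")
    out = snr_reduce(per_image, m_iterations)
    out.provenance = f"pipeline-N{n_params}-M{m_iterations}"
    return out


@dataclass
class TrajectoryGraph:
    """Year-to-year family links with merge and split events."""

    edges: list[tuple[int, int, int, int, float]]  # (year, i, next_year, j, tanimoto)
    merges: list[tuple[int, int]]                  # (next_year, target family index)
    splits: list[tuple[int, int]]                  # (year, source family index)


def family_trajectories(collections: dict[int, FamilyCollection]) -> TrajectoryGraph:
    """Link each family to its best-Tanimoto successor in the next year.

    A merge is a next-year family matched by two or more current families;
    a split is a current family that is the best backward match of two or
    more next-year families. Families with no positive match terminate.
    """
    years = sorted(collections)
    if len(years) < 2:
        raise ValueError("need at least two years")
    edges, merges, splits = [], [], []
    for y0, y1 in zip(years, years[1:]):
        cur, nxt = list(collections[y0]), list(collections[y1])
        fwd: dict[int, int] = {}
        for i, fam in enumerate(cur):
            best_j, best_t = -1, 0.0
            for j, cand in enumerate(nxt):
                t = tanimoto(fam, cand)
                if t > best_t:
                    best_j, best_t = j, t
            if best_j >= 0:
                fwd[i] = best_j
                edges.append((y0, i, y1, best_j, round(tanimoto(cur[i], nxt[best_j]), 6)))
        hit = Counter(fwd.values())
        merges.extend((y1, j) for j, k in hit.items() if k >= 2)
        back: dict[int, int] = {}
        for j, fam in enumerate(nxt):
            best_i, best_t = -1, 0.0
            for i, cand in enumerate(cur):
                t = tanimoto(fam, cand)
                if t > best_t:
                    best_i, best_t = i, t
            if best_i >= 0:
                back[j] = best_i
        hit_b = Counter(back.values())
        splits.extend((y0, i) for i, k in hit_b.items() if k >= 2)
    return TrajectoryGraph(edges, merges, splits)
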