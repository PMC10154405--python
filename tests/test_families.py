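import numpy as np
import pytest
from scipy import stats

import chemspace as cs
from chemspace.families import FamilyCollection, ReshuffledImage
from chemspace.optimize import SequenceEnsemble
from chemspace.similarity import SimilarityMatrix

from conftest import PLANTED_FAMILIES


def block_matrix(n, blocks, rng=None, value=0.4):
    """Symmetric matrix with high-value diagonal blocks on zero background."""
    s = np.zeros((n, n))
    for lo, hi in blocks:
        if rng is None:
            s[lo:hi, lo:hi] = value
        else:
            blk = 0.3 + 0.2 * rng.random((hi - lo, hi - lo))
            s[lo:hi, lo:hi] = (blk + blk.T) / 2
    np.fill_diagonal(s, 0)
    return s


def as_image(s):
    return ReshuffledImage(s, [f"e{i}" for i in range(s.shape[0])])


def test_reshuffle_identity():
    rng = np.random.default_rng(0)
    a = rng.random((5, 5))
    S = SimilarityMatrix([f"e{i}" for i in range(5)], (a + a.T) / 2)
    img = cs.reshuffle(S, S.roster)
    np.testing.assert_array_equal(img.values, S.s)


def test_reshuffle_roundtrip():
    rng = np.random.default_rng(1)
    a = rng.random((6, 6))
    S = SimilarityMatrix([f"e{i}" for i in range(6)], (a + a.T) / 2)
    seq = [f"e{i}" for i in rng.permutation(6)]
    img = cs.reshuffle(S, seq)
    back = [seq.index(sym) for sym in S.roster]
    np.testing.assert_array_equal(img.values[np.ix_(back, back)], S.s)
    # permutation conserves every pixel value
    assert sorted(img.values.ravel()) == sorted(S.s.ravel())


def test_reshuffle_requires_permutation():
    S = SimilarityMatrix(["a", "b"], np.zeros((2, 2)))
    with pytest.raises(ValueError):
        cs.reshuffle(S, ["a", "a"])


@pytest.mark.parametrize("window", [17, 19, 21, 23])
def test_cv_detect_two_planted_blocks(window):
    """Two bright 5-element diagonal squares are found at every blur window."""
    s = block_matrix(30, [(3, 8), (12, 17)])
    img = as_image(s)
    fams = cs.cv_detect(img, cs.CVParams(blur_window=window, canny_low=10.0))
    expected = [{f"e{i}" for i in range(3, 8)}, {f"e{i}" for i in range(12, 17)}]
    for want in expected:
        assert any(f == want for f in fams), (window, list(fams))


def test_cv_detect_uniform_image_is_empty():
    img = as_image(np.full((20, 20), 0.25) - np.diag(np.full(20, 0.25)))
    assert len(cs.cv_detect(img, cs.CVParams())) == 0


def test_cv_detect_rejects_oversized_block():
    s = block_matrix(30, [(2, 27)])  # 25 elements, above the 20-element cap
    fams = cs.cv_detect(as_image(s), cs.CVParams())
    assert all(len(f) <= 20 for f in fams)
    assert not any(f == {f"e{i}" for i in range(2, 27)} for f in fams)


def test_cv_detect_adjacent_blocks_stay_separate():
    rng = np.random.default_rng(3)
    s = block_matrix(15, [(0, 4), (4, 9), (9, 15)], rng=rng)
    fams = cs.cv_detect(as_image(s), cs.CVParams(blur_window=21, canny_low=5.0))
    want = [{f"e{i}" for i in range(lo, hi)} for lo, hi in [(0, 4), (4, 9), (9, 15)]]
    for w in want:
        assert any(f == w for f in fams), list(fams)


def test_cv_families_are_contiguous_runs_of_the_order():
    rng = np.random.default_rng(4)
    s = block_matrix(24, [(1, 6), (8, 13), (15, 22)], rng=rng)
    img = as_image(s)
    for f in cs.cv_detect(img, cs.CVParams()):
        idx = sorted(img.order.index(e) for e in f)
        assert idx == list(range(idx[0], idx[0] + len(idx)))


def test_sample_cv_params_distribution():
    rng = np.random.default_rng(5)
    params = cs.sample_cv_params(rng, 20000, beta=20.0)
    assert {p.blur_window for p in params} <= {17, 19, 21, 23}
    assert all(p.canny_high == 40.0 for p in params)
    ths = np.array([p.canny_low for p in params])
    grid = np.arange(40)
    expected = np.exp(-grid / 20.0)
    expected = expected / expected.sum() * len(ths)
    observed = np.array([(ths == t).sum() for t in grid])
    # merge sparse upper tail for a valid chi-square comparison
    chi2 = stats.chisquare(
        np.append(observed[:25], observed[25:].sum()),
        np.append(expected[:25], expected[25:].sum()),
    )
    assert chi2.pvalue > 1e-3


def test_tanimoto():
    assert cs.tanimoto({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
    assert cs.tanimoto({"a"}, {"a"}) == 1.0
    assert cs.tanimoto({"a"}, {"b"}) == 0.0
    assert cs.tanimoto(set(), set()) == 0.0


def coll(*fams):
    return FamilyCollection([frozenset(f) for f in fams])


def test_snr_fixed_point():
    pool = [coll("abc", "de")] * 3
    out = cs.snr_reduce(pool, 3)
    assert set(out) == {frozenset("abc"), frozenset("de")}


def test_snr_majority_keeps_supported_family():
    pool = [coll("abc", "xy"), coll("abc"), coll("abc")]
    out = cs.snr_reduce(pool, 2)
    assert frozenset("abc") in set(out)


def test_snr_majority_trims_disputed_members():
    pool = [coll("abc"), coll("abd"), coll("ab")]
    out = cs.snr_reduce(pool, 1)
    # c and d each appear in 1 of 3 gathered families: below 50%
    assert set(out) == {frozenset("ab")}


def test_snr_drops_singletons_and_duplicates():
    pool = [coll("ab", "ab", "c"), coll("ab")]
    out = cs.snr_reduce(pool, 1)
    assert set(out) == {frozenset("ab")}


def test_snr_order_invariant():
    pool = [coll("abc", "de"), coll("abd"), coll("de", "abc")]
    a = cs.snr_reduce(pool, 2)
    b = cs.snr_reduce(pool[::-1], 2)
    assert set(a) == set(b)


def test_detect_families_recovers_noiseless_planted_blocks():
    rng = np.random.default_rng(6)
    s = block_matrix(15, [(0, 4), (4, 9), (9, 15)], rng=rng)
    order = [f"e{i}" for i in range(15)]
    S = SimilarityMatrix(order, s)
    ensemble = SequenceEnsemble(order, [order, order], [0.0, 0.0])
    out = cs.detect_families(S, ensemble, n_params=8, m_iterations=2,
                             rng=np.random.default_rng(0))
    want = {frozenset(f"e{i}" for i in range(lo, hi)) for lo, hi in [(0, 4), (4, 9), (9, 15)]}
    assert want <= set(out)


def test_detect_families_empty_matrix():
    S = SimilarityMatrix([], np.zeros((0, 0)))
    ensemble = SequenceEnsemble([], [[]], [0.0])
    assert len(cs.detect_families(S, ensemble, 3, 1)) == 0


def test_detect_families_deterministic():
    rng = np.random.default_rng(7)
    s = block_matrix(12, [(0, 5), (5, 12)], rng=rng)
    order = [f"e{i}" for i in range(12)]
    S = SimilarityMatrix(order, s)
    ensemble = SequenceEnsemble(order, [order], [0.0])
    a = cs.detect_families(S, ensemble, 5, 2, rng=np.random.default_rng(9))
    b = cs.detect_families(S, ensemble, 5, 2, rng=np.random.default_rng(9))
    assert list(a) == list(b)


def test_family_detector_estimator_recovers_blocks():
    rng = np.random.default_rng(8)
    s = block_matrix(12, [(0, 5), (5, 12)], rng=rng)
    det = cs.FamilyDetector(n_params=6, m_iterations=2, n_runs=3, keep=2,
                            population_size=80, generations=60, random_state=0)
    labels = det.fit_predict(s)
    want = {frozenset(f"e{i}" for i in range(0, 5)),
            frozenset(f"e{i}" for i in range(5, 12))}
    assert want <= set(det.families_)
    assert set(labels) <= {-1, 0, 1}


def test_trajectories_constant_collections():
    colls = {y: coll("abc", "de") for y in (1900, 1910, 1920)}
    g = cs.family_trajectories(colls)
    assert len(g.edges) == 4  # 2 families x 2 transitions
    assert all(t == 1.0 for *_, t in g.edges)
    assert g.merges == [] and g.splits == []


def test_trajectories_merge_event():
    colls = {1900: coll("abc", "de"), 1910: coll("abcde")}
    g = cs.family_trajectories(colls)
    assert (1910, 0) in g.merges


def test_trajectories_split_event():
    colls = {1900: coll("abcde"), 1910: coll("abc", "de")}
    g = cs.family_trajectories(colls)
    assert (1900, 0) in g.splits


def test_trajectories_terminate_without_match():
    colls = {1900: coll("ab", "cd"), 1910: coll("ab")}
    g = cs.family_trajectories(colls)
    sources = {(y, i) for y, i, *_ in g.edges}
    assert (1900, 1) not in sources
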