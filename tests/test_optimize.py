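import itertools

import numpy as np
import pytest

import chemspace as cs
from chemspace.optimize import _pmx
from chemspace.similarity import SimilarityMatrix


def sim(values, roster=None):
    values = np.asarray(values, dtype=float)
    roster = roster or [f"e{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(roster, values)


def pmx_oracle(p1, p2, a, b):
    """Textbook partially-mapped crossover: copy the p1 segment, then place
    each remaining p2 value after resolving the segment mapping chain."""
    n = len(p1)
    child = [None] * n
    child[a:b] = p1[a:b]
    for i in list(range(0, a)) + list(range(b, n)):
        v = p2[i]
        while v in child[a:b]:
            v = p2[p1.index(v)]
        child[i] = v
    return child


TWO = sim([[0, 0.5], [0.5, 0]])


def test_cost_two_elements():
    assert cs.sequence_cost(TWO, ["e0", "e1"]) == pytest.approx(-1.0)
    assert cs.sequence_cost(TWO, ["e1", "e0"]) == pytest.approx(-1.0)


def test_cost_zero_matrix():
    S = sim(np.zeros((4, 4)))
    assert cs.sequence_cost(S, ["e3", "e1", "e0", "e2"]) == 0.0


def test_cost_prefers_adjacent_similars():
    S = sim([[0, 0.4, 0], [0.4, 0, 0], [0, 0, 0]], roster=["a", "b", "c"])
    assert cs.sequence_cost(S, ["a", "c", "b"]) == pytest.approx(-0.4)
    assert cs.sequence_cost(S, ["a", "b", "c"]) == pytest.approx(-0.8)


def test_cost_requires_permutation_of_roster():
    with pytest.raises(ValueError):
        cs.sequence_cost(TWO, ["e0", "e0"])
    with pytest.raises(ValueError):
        cs.sequence_cost(TWO, ["e0"])


def test_cost_reversal_invariant():
    rng = np.random.default_rng(0)
    a = rng.random((7, 7)) * 0.5
    S = sim((a + a.T) / 2 - np.diag(np.diag(a)))
    order = [f"e{i}" for i in rng.permutation(7)]
    assert cs.sequence_cost(S, order) == pytest.approx(
        cs.sequence_cost(S, order[::-1])
    )


def test_pmx_identical_parents_fixed_point():
    rng = np.random.default_rng(1)
    p = list(rng.permutation(9))
    assert cs.pmx_crossover(p, p, rng) == p


def test_pmx_textbook_example():
    p1 = [1, 2, 3, 4, 5, 6, 7, 8]
    p2 = [3, 7, 5, 1, 6, 8, 2, 4]
    child = _pmx(p1, p2, 2, 5)
    assert child == pmx_oracle(p1, p2, 2, 5)
    assert child == [6, 7, 3, 4, 5, 8, 2, 1]


@pytest.mark.parametrize("seed", range(4))
def test_pmx_matches_oracle_and_is_permutation(seed):
    rng = np.random.default_rng(seed)
    for _ in range(250):
        n = int(rng.integers(2, 12))
        p1, p2 = list(rng.permutation(n)), list(rng.permutation(n))
        a, b = sorted(rng.integers(0, n + 1, size=2))
        child = _pmx(p1, p2, a, b)
        assert sorted(child) == list(range(n))
        assert child[a:b] == p1[a:b]
        assert child == pmx_oracle(p1, p2, a, b)


def test_slice_mutation_moves_slice():
    class FixedRng:
        def __init__(self, values):
            self.values = iter(values)

        def integers(self, lo, hi=None):
            return next(self.values)

    # slice (b, c) starting at 1, length 2, reinserted at the end
    assert cs.slice_mutation(["a", "b", "c", "d"], FixedRng([1, 2, 2])) == [
        "a", "d", "b", "c",
    ]
    # zero-displacement move leaves the sequence unchanged
    assert cs.slice_mutation(["a", "b", "c", "d"], FixedRng([1, 2, 1])) == [
        "a", "b", "c", "d",
    ]


def test_slice_mutation_conserves_elements():
    rng = np.random.default_rng(2)
    seq = list(range(11))
    for _ in range(1000):
        seq = cs.slice_mutation(seq, rng)
        assert sorted(seq) == list(range(11))


def test_ga_two_elements(scaled_ga):
    order, cost = cs.run_ga(TWO, scaled_ga.scaled_down(20, 5))
    assert sorted(order) == ["e0", "e1"]
    assert cost == pytest.approx(-1.0)


@pytest.mark.parametrize("seed", range(5))
def test_ga_matches_brute_force_on_small_matrices(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    a = rng.random((n, n)) * 0.5
    S = sim((a + a.T) / 2 - np.diag(np.diag(a)))
    best = min(
        cs.sequence_cost(S, list(p)) for p in itertools.permutations(S.roster)
    )
    _, cost = cs.run_ga(S, cs.GAConfig(population_size=200, generations=100, seed=seed))
    assert cost == pytest.approx(best)


def test_ga_is_deterministic(scaled_ga):
    rng = np.random.default_rng(3)
    a = rng.random((6, 6)) * 0.5
    S = sim((a + a.T) / 2 - np.diag(np.diag(a)))
    cfg = scaled_ga.scaled_down(60, 40)
    assert cs.run_ga(S, cfg) == cs.run_ga(S, cfg)


def test_ga_places_planted_families_contiguously():
    rng = np.random.default_rng(4)
    blocks = [(0, 4), (4, 9), (9, 12)]
    a = np.zeros((12, 12))
    for lo, hi in blocks:
        blk = 0.2 + 0.3 * rng.random((hi - lo, hi - lo))
        a[lo:hi, lo:hi] = (blk + blk.T) / 2
    np.fill_diagonal(a, 0)
    S = sim(a)
    order, _ = cs.run_ga(S, cs.GAConfig(population_size=200, generations=150, seed=0))
    pos = {e: i for i, e in enumerate(order)}
    for lo, hi in blocks:
        idx = sorted(pos[f"e{i}"] for i in range(lo, hi))
        assert idx == list(range(idx[0], idx[0] + len(idx)))


def test_ga_appends_inactive_elements_in_roster_order():
    a = np.zeros((4, 4))
    a[0, 1] = a[1, 0] = 0.5
    S = sim(a)
    order, cost = cs.run_ga(S, cs.GAConfig(population_size=20, generations=5, seed=0))
    assert cost == pytest.approx(-1.0)
    assert order[2:] == ["e2", "e3"]


def test_ensemble_selection_and_sorting(scaled_ga):
    rng = np.random.default_rng(5)
    a = rng.random((5, 5)) * 0.5
    S = sim((a + a.T) / 2 - np.diag(np.diag(a)))
    ens = cs.build_ensemble(S, n_runs=3, keep=2, cfg=scaled_ga.scaled_down(40, 20))
    assert len(ens) == 2
    assert ens.costs == sorted(ens.costs)
    with pytest.raises(ValueError):
        cs.build_ensemble(S, n_runs=2, keep=3, cfg=scaled_ga)


def test_ensemble_converges_on_tiny_matrix(scaled_ga):
    rng = np.random.default_rng(6)
    a = rng.random((4, 4)) * 0.5
    S = sim((a + a.T) / 2 - np.diag(np.diag(a)))
    best = min(cs.sequence_cost(S, list(p)) for p in itertools.permutations(S.roster))
    ens = cs.build_ensemble(S, n_runs=4, keep=4, cfg=scaled_ga.scaled_down(100, 60))
    assert all(c == pytest.approx(best) for c in ens.costs)


def test_ensemble_json_roundtrip(tmp_path, scaled_ga):
    ens = cs.SequenceEnsemble(["a", "b"], [["a", "b"], ["b", "a"]], [-1.0, -1.0], 1900)
    path = tmp_path / "ens.json"
    ens.to_json(path)
    back = cs.SequenceEnsemble.from_json(path)
    assert (back.roster, back.sequences, back.costs, back.year) == (
        ens.roster, ens.sequences, ens.costs, ens.year,
    )


def test_ga_config_validation():
    with pytest.raises(ValueError):
        cs.GAConfig(population_size=7)
    with pytest.raises(ValueError):
        cs.GAConfig(mutation_prob=1.5)


def test_sequence_optimizer_estimator():
    from sklearn.base import clone

    rng = np.random.default_rng(7)
    a = rng.random((5, 5)) * 0.5
    X = (a + a.T) / 2 - np.diag(np.diag(a))
    est = cs.SequenceOptimizer(n_runs=2, keep=2, population_size=40,
                               generations=20, random_state=0)
    est2 = clone(est).fit(X)
    assert sorted(est2.order_) == [f"e{i}" for i in range(5)]
    assert est2.score(X) == pytest.approx(-est2.cost_)
    assert len(est2.ensemble_) == 2
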