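"""scikit-learn-compatible estimator facades.

Two stages of the analysis are genuinely estimator-shaped and are exposed
as sklearn-style classes over the functional core: :class:`SequenceOptimizer`
(seriation of a precomputed element-similarity matrix) and
:class:`FamilyDetector` (clustering-like extraction of element families).
Both accept either a :class:`~chemspace.similarity.SimilarityMatrix` or a
plain square array with an explicit roster.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .families import FamilyCollection, detect_families
from .optimize import GAConfig, SequenceEnsemble, build_ensemble, sequence_cost
from .similarity import SimilarityMatrix

__all__ = ["SequenceOptimizer", "FamilyDetector"]


def _as_similarity(X, roster) -> SimilarityMatrix:
    if isinstance(X, SimilarityMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("X must be a square similarity matrix")
    if not np.allclose(X, X.T):
        raise ValueError("similarity matrix must be symmetric")
    if roster is None:
        roster = [f"e{i}" for i in range(X.shape[0])]
    if len(roster) != X.shape[0]:
        raise ValueError("roster length must match matrix size")
    return SimilarityMatrix(list(roster), X)


class SequenceOptimizer(BaseEstimator):
    """Seriation of a precomputed element-similarity matrix.

    ``fit(X)`` runs ``n_runs`` independent genetic-algorithm optimisations
    of the distance-weighted similarity cost and retains the ``keep`` best
    permutations.

    Attributes
    ----------
    order_ : list of str
        Best permutation found (lowest cost).
    cost_ : float
        Its cost.
    ensemble_ : SequenceEnsemble
        The ``keep`` best sequences with costs, sorted ascending.
    """

    def __init__(self, n_runs=50, keep=15, population_size=1500, generations=600,
                 mutation_prob=0.3, kt_initial=0.7, kt_scale=0.7, kt_interval=200,
                 random_state=0):
        self.n_runs = n_runs
        self.keep = keep
        self.population_size = population_size
        self.generations = generations
        self.mutation_prob = mutation_prob
        self.kt_initial = kt_initial
        self.kt_scale = kt_scale
        self.kt_interval = kt_interval
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            mutation_prob=self.mutation_prob,
            kt_initial=self.kt_initial,
            kt_scale=self.kt_scale,
            kt_interval=self.kt_interval,
            seed=self.random_state,
        )

    def fit(self, X, y=None, roster=None):
        S = _as_similarity(X, roster)
        ens: SequenceEnsemble = build_ensemble(S, self.n_runs, self.keep, self._config())
        self.ensemble_ = ens
        self.order_ = ens.sequences[0]
        self.cost_ = ens.costs[0]
        self.roster_ = list(S.roster)
        return self

    def score(self, X, y=None, roster=None) -> float:
        """Negative sequence cost of the fitted order on ``X`` (higher is better)."""
        check_is_fitted(self, "order_")
        return -sequence_cost(_as_similarity(X, roster), self.order_)


class FamilyDetector(BaseEstimator):
    """Extract families of similar elements from a similarity matrix.

    ``fit(X)`` seriates the matrix (unless an ensemble is supplied) and
    runs the computer-vision + statistical-noise-reduction detection
    pipeline over the sequence ensemble.

    Attributes
    ----------
    families_ : list of frozenset of str
        Detected element families (possibly overlapping).
    labels_ : ndarray of shape (n_elements,)
        Index of the first family containing each element, −1 if none.
    """

    def __init__(self, n_params=25, m_iterations=3, n_runs=8, keep=5,
                 population_size=200, generations=200, random_state=0):
        self.n_params = n_params
        self.m_iterations = m_iterations
        self.n_runs = n_runs
        self.keep = keep
        self.population_size = population_size
        self.generations = generations
        self.random_state = random_state

    def fit(self, X, y=None, roster=None, ensemble: SequenceEnsemble | None = None):
        S = _as_similarity(X, roster)
        if ensemble is None:
            cfg = GAConfig(population_size=self.population_size,
                           generations=self.generations, seed=self.random_state)
            ensemble = build_ensemble(S, self.n_runs, self.keep, cfg)
        rng = np.random.default_rng(self.random_state)
        collection: FamilyCollection = detect_families(
            S, ensemble, self.n_params, self.m_iterations, rng)
        self.collection_ = collection
        self.families_ = list(collection)
        self.roster_ = list(S.roster)
        labels = np.full(len(self.roster_), -1)
        for k, fam in enumerate(self.families_):
            for sym in fam:
                i = self.roster_.index(sym)
                if labels[i] < 0:
                    labels[i] = k
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_
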