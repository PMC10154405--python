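import numpy as np
import pytest

import chemspace as cs
from chemspace.corpus import MolecularFormula

#: Planted families used across recovery tests: halogens, alkali metals,
#: and a divalent-metal group — 4, 5 and 6 elements.
PLANTED_FAMILIES = [
    ["F", "Cl", "Br", "I"],
    ["Li", "Na", "K", "Rb", "Cs"],
    ["Mg", "Ca", "Sr", "Ba", "Zn", "Cd"],
]


def mf(formula: str, year: int = 1800, id: str = "") -> MolecularFormula:
    return MolecularFormula(cs.parse_formula(formula), year, id)


@pytest.fixture
def nacl_nabr_corpus():
    """Two-formula corpus in which Cl and Br are perfectly interchangeable."""
    return {mf("NaCl"), mf("NaBr")}


@pytest.fixture
def halide_corpus():
    """Four formulas: Na/K fill the same two halide contexts."""
    return {mf("NaCl"), mf("KCl"), mf("NaBr"), mf("KBr")}


@pytest.fixture
def scaled_ga():
    return cs.GAConfig(population_size=150, generations=150, seed=0)


def random_corpus(rng: np.random.Generator, max_formulas=200, max_elements=10):
    """A random synthetic corpus over a small element roster."""
    roster = list(rng.choice(cs.elements.ELEMENT_SYMBOLS[:40],
                             size=rng.integers(3, max_elements + 1), replace=False))
    out = set()
    for _ in range(int(rng.integers(2, max_formulas + 1))):
        k = int(rng.integers(1, 4))
        syms = rng.choice(roster, size=k, replace=False)
        counts = {str(s): int(rng.integers(1, 7)) for s in syms}
        out.add(MolecularFormula(counts, 1800))
    return out
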