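"""The 118 IUPAC element symbols and ordering helpers."""

from __future__ import annotations

#: Symbols of the 118 recognised chemical elements, in atomic-number order.
ELEMENT_SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

ELEMENT_SET: frozenset[str] = frozenset(ELEMENT_SYMBOLS)

ATOMIC_NUMBER: dict[str, int] = {s: i + 1 for i, s in enumerate(ELEMENT_SYMBOLS)}


def hill_order(symbols) -> list[str]:
    """Sort element symbols in Hill convention.

    Carbon first, then hydrogen, then everything else alphabetically; when
    no carbon is present every symbol (hydrogen included) sorts
    alphabetically.
    """
    symbols = list(symbols)
    if "C" in symbols:
        rest = sorted(s for s in symbols if s not in ("C", "H"))
        head = ["C"] + (["H"] if "H" in symbols else [])
        return head + rest
    return sorted(symbols)
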