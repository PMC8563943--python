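"""Elemental mass bookkeeping: formulas, monoisotopic masses, ion m/z and DBE.

All exact-mass arithmetic in the package goes through this module.  Atomic
monoisotopic masses are pinned in-code (CODATA/AME-derived values, quoted to
well below 1e-5 Da) so that every derived quantity is bit-stable across
platforms.  Charged species always carry the electron-mass correction: a
singly charged anion weighs one electron more than its neutral composition,
a cation one electron less.  This matters at the second decimal for light
salt-cluster ions such as Na3SO4+.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Tuple

__all__ = [
    "ELECTRON_MASS",
    "ELEMENTS",
    "Element",
    "MolecularFormula",
    "IonSpecies",
    "FormulaError",
    "parse_formula",
    "round_half_even",
]

#: Electron rest mass in Da.
ELECTRON_MASS = 5.48579909e-4


@dataclass(frozen=True)
class Element:
    symbol: str
    monoisotopic_mass: float
    #: Formal valence used by the ring-plus-double-bond count; ``None`` for
    #: elements excluded from the DBE formula (metals, semimetals).
    valence: Optional[int]


#: Pinned monoisotopic mass table (most abundant isotope, Da).
ELEMENTS: Dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("C", 12.0, 4),
        Element("H", 1.00782503207, 1),
        Element("N", 14.0030740048, 3),
        Element("O", 15.9949146196, 2),
        Element("S", 31.97207100, 2),
        Element("P", 30.97376163, 3),
        Element("Na", 22.9897692809, None),
        Element("K", 38.96370668, None),
        Element("Al", 26.98153853, None),
        Element("Fe", 55.93493633, None),
        Element("Si", 27.9769265347, None),
    ]
}

#: Elements the DBE formula is defined over.
DBE_ELEMENTS = frozenset("CHNOSP")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Round-half-to-even at ``ndigits`` decimals (deterministic ties)."""
    return round(x, ndigits)


def _hill_order(counts: Mapping[str, int]) -> Tuple[str, ...]:
    symbols = sorted(counts)
    if "C" in counts:
        head = [s for s in ("C", "H") if s in counts]
        return tuple(head + [s for s in symbols if s not in ("C", "H")])
    return tuple(symbols)


@dataclass(frozen=True)
class MolecularFormula:
    """An element->count map with derived mass, DBE and elemental ratios.

    Instances are immutable and hashable; arithmetic (``+``/``-``) acts on
    element counts, which is how neutral losses and adducts are expressed
    throughout the package.
    """

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int]):
        clean: Dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in ELEMENTS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
            if n:
                clean[sym] = n
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(
            self, "counts", tuple((s, clean[s]) for s in _hill_order(clean))
        )

    # -- mapping-style access -------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return dict(self.counts).get(sym, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    # -- derived quantities ---------------------------------------------------
    @property
    def monoisotopic_mass(self) -> float:
        return sum(ELEMENTS[s].monoisotopic_mass * n for s, n in self.counts)

    @property
    def dbe(self) -> Optional[float]:
        """Rings plus double bonds, ``1 + sum(n_i (v_i - 2)) / 2``.

        Reduces to C - H/2 + N/2 + 1 for CHNOS compositions.  Undefined
        (``None``) when the formula carries elements outside CHNOSP --
        the count is meaningless for salt clusters like Na3SO4+.
        May be half-integral for open-shell fragment compositions; the value
        is reported as-is.
        """
        if any(s not in DBE_ELEMENTS for s, _ in self.counts):
            return None
        acc = 2.0
        for s, n in self.counts:
            acc += n * (ELEMENTS[s].valence - 2)
        return acc / 2.0

    @property
    def hc_ratio(self) -> Optional[float]:
        c = self["C"]
        return self["H"] / c if c else None

    @property
    def oc_ratio(self) -> Optional[float]:
        c = self["C"]
        return self["O"] / c if c else None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for s, n in other.counts:
            merged[s] = merged.get(s, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for s, n in other.counts:
            left = merged.get(s, 0) - n
            if left < 0:
                raise FormulaError(
                    f"cannot remove {n} {s} from {self}: only {merged.get(s, 0)} present"
                )
            merged[s] = left
        merged = {s: n for s, n in merged.items() if n}
        return MolecularFormula(merged)

    def __str__(self) -> str:
        return "".join(
            f"{s}{n}" if n > 1 else s for s, n in self.counts
        )

    def __repr__(self) -> str:
        return f"MolecularFormula({str(self)!r})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string like ``"C27H45SO4"``.

    Repeated element tokens accumulate.  Raises :class:`FormulaError` naming
    the offending token on malformed input.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        sym, digits = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


@dataclass(frozen=True)
class IonSpecies:
    """A molecular formula with an integer charge.

    ``mz`` is the electron-mass-corrected mass-to-charge ratio:
    ``(m_formula - z * m_e) / |z|``, so a -1 ion gains one electron mass and
    a +1 ion loses one.
    """

    formula: MolecularFormula
    charge: int = field(default=1)

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("charge must be nonzero")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def mz(self) -> float:
        return (
            self.formula.monoisotopic_mass - self.charge * ELECTRON_MASS
        ) / abs(self.charge)

    def mz_rounded(self, ndigits: int = 2) -> float:
        """m/z rounded half-to-even, the convention used for printed values."""
        return round_half_even(self.mz, ndigits)

    def __str__(self) -> str:
        sign = "+" if self.charge > 0 else "-"
        mag = abs(self.charge)
        return f"{self.formula}{'' if mag == 1 else mag}{sign}"

    def __repr__(self) -> str:
        return f"IonSpecies({self.formula!r}, charge={self.charge:+d})"


def ion(text: str, charge: int = 1) -> IonSpecies:
    """Shorthand: ``ion("C5H10N", +1)`` -> IonSpecies."""
    return IonSpecies(parse_formula(text), charge)
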