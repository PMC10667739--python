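"""Elemental-formula arithmetic for lipid mass spectrometry.

Provides an immutable :class:`ElementalFormula` (element counts plus net
charge), Hill-notation parsing, exact monoisotopic masses, adduct m/z for
the four electrospray ionization modes used in environmental lipidomics
(``[M+H]+``, ``[M+NH4]+``, ``[M-H]-``, ``[M+HCOO]-``), and the nominal
carbon oxidation state (Zc) of a molecule.

Zc summarizes how reduced or oxidized the carbon in a biomolecule is::

    Zc = (Z + 2*o + 3*n - 5*p - 4*s - h) / c

where ``Z`` is the net charge and ``c, h, n, o, p, s`` count carbon,
hydrogen (deuterium included), nitrogen, oxygen, phosphorus and sulfur
atoms. Methane scores -4 (fully reduced carbon), CO2 scores +4 (fully
oxidized). Lipids fall in between, and abundance-weighted Zc of lipid
parts tracks the redox conditions organisms grow under.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "AdductType",
    "ADDUCTS",
    "parse_formula",
    "combine",
    "monoisotopic_mass",
    "adduct_mz",
    "zc",
    "ELECTRON_MASS",
    "PROTON_MASS",
]

# CODATA/IUPAC monoisotopic isotope masses (Da). D is deuterium (2H),
# carried as its own symbol so deuterated internal standards (e.g.
# d9-DGTS) get correct masses while Zc still counts D as hydrogen.
ISOTOPE_MASS: Mapping[str, float] = MappingProxyType(
    {
        "C": 12.0,
        "H": 1.00782503207,
        "D": 2.01410177785,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "P": 30.97376163,
        "S": 31.97207100,
        "Na": 22.9897692809,
        "K": 38.96370668,
        "Cl": 34.96885268,
    }
)

ELECTRON_MASS = 0.000548579909
PROTON_MASS = ISOTOPE_MASS["H"] - ELECTRON_MASS  # 1.00727645...

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formulas or invalid formula arithmetic."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element-count map with a net charge (in elementary charges).

    Counts must be non-negative integers; zero counts are dropped so that
    equality is element-wise. The all-zero formula is valid and acts as
    the identity of addition.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in ISOTOPE_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise FormulaError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", MappingProxyType(dict(sorted(clean.items()))))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return combine(self, other, +1)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return combine(self, other, -1)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative integer, got {k!r}")
        return ElementalFormula({el: n * k for el, n in self.counts.items()}, self.charge * k)

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts) and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((tuple(self.counts.items()), self.charge))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        parts: list[str] = []
        counts = dict(self.counts)
        # Deuterium is folded into the H position, printed as D.
        for el in ("C", "H", "D"):
            n = counts.pop(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(counts):
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        body = "".join(parts)
        if self.charge > 0:
            body += "+" * self.charge
        elif self.charge < 0:
            body += "-" * (-self.charge)
        return body

    def __str__(self) -> str:
        return self.hill()


EMPTY = ElementalFormula()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C5H15NO4P"``.

    An omitted count means 1. A trailing run of ``+`` or ``-`` (also the
    Unicode minus) gives the net charge, one sign per elementary charge.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    body = text.strip()
    charge = 0
    m = re.search(r"([+−-]+)$", body)
    if m:
        signs = m.group(1).replace("−", "-")
        if len(set(signs)) > 1:
            raise FormulaError(f"mixed charge signs in {text!r}")
        charge = len(signs) if signs[0] == "+" else -len(signs)
        body = body[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ISOTOPE_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts, charge)


def combine(a: ElementalFormula, b: ElementalFormula, sign: int = +1) -> ElementalFormula:
    """Element-wise sum (``sign=+1``) or difference (``sign=-1``) of two formulas.

    Charges are combined the same way. Subtraction that would drive any
    element count negative raises :class:`FormulaError`.
    """
    if sign not in (+1, -1):
        raise FormulaError(f"sign must be +1 or -1, got {sign!r}")
    counts = dict(a.counts)
    for el, n in b.counts.items():
        counts[el] = counts.get(el, 0) + sign * n
        if counts[el] < 0:
            raise FormulaError(
                f"subtraction underflow: {a} - {b} yields negative {el} count"
            )
    return ElementalFormula(counts, a.charge + sign * b.charge)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da, including the electron-mass correction.

    Each positive elementary charge removes one electron mass; each
    negative charge adds one. The empty formula has mass 0.
    """
    m = sum(ISOTOPE_MASS[el] * n for el, n in f.counts.items())
    return m - f.charge * ELECTRON_MASS


@dataclass(frozen=True)
class AdductType:
    """An electrospray adduct: an attached/removed group and a unit charge.

    ``added`` and ``removed`` are neutral formulas; the ion m/z is
    ``(M + mass(added) - mass(removed) - charge * electron) / |charge|``,
    so the electron bookkeeping Orbitrap-grade accuracy requires is built
    in (e.g. ``[M+H]+`` adds exactly one proton mass).
    """

    name: str
    added: ElementalFormula
    removed: ElementalFormula
    charge: int

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise FormulaError(f"adduct {self.name}: only unit charges supported")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def delta_mass(self) -> float:
        return (
            monoisotopic_mass(self.added)
            - monoisotopic_mass(self.removed)
            - self.charge * ELECTRON_MASS
        )


ADDUCTS: Mapping[str, AdductType] = MappingProxyType(
    {
        "[M+H]+": AdductType("[M+H]+", ElementalFormula({"H": 1}), EMPTY, +1),
        "[M+NH4]+": AdductType("[M+NH4]+", ElementalFormula({"N": 1, "H": 4}), EMPTY, +1),
        "[M-H]-": AdductType("[M-H]-", EMPTY, ElementalFormula({"H": 1}), -1),
        "[M+HCOO]-": AdductType(
            "[M+HCOO]-", ElementalFormula({"C": 1, "H": 1, "O": 2}), EMPTY, -1
        ),
    }
)

# Short aliases accepted on the command line and in component tables.
ADDUCT_ALIASES: Mapping[str, str] = MappingProxyType(
    {
        "MH": "[M+H]+",
        "MNH4": "[M+NH4]+",
        "MmH": "[M-H]-",
        "MHCOO": "[M+HCOO]-",
        "[M−H]−": "[M-H]-",
        "[M+H]+": "[M+H]+",
        "[M+NH4]+": "[M+NH4]+",
        "[M-H]-": "[M-H]-",
        "[M+HCOO]-": "[M+HCOO]-",
    }
)


def get_adduct(name: str) -> AdductType:
    key = ADDUCT_ALIASES.get(name, name)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise FormulaError(f"unknown adduct: {name!r}") from None


def adduct_mz(neutral_mass: float, adduct: AdductType | str) -> float:
    """m/z of the ion formed from a neutral of the given monoisotopic mass."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if neutral_mass <= 0:
        raise FormulaError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + adduct.delta_mass) / abs(adduct.charge)


def zc(f: ElementalFormula) -> float:
    """Nominal carbon oxidation state of a formula.

    ``(Z + 2o + 3n - 5p - 4s - h) / c``; deuterium counts as hydrogen.
    Requires at least one carbon atom.
    """
    c = f["C"]
    if c < 1:
        raise FormulaError(f"oxidation state of carbon undefined for carbon-free formula {f}")
    h = f["H"] + f["D"]
    return (f.charge + 2 * f["O"] + 3 * f["N"] - 5 * f["P"] - 4 * f["S"] - h) / c


def zc_numerator(f: ElementalFormula) -> float:
    """Electron-bookkeeping numerator of Zc (``c * zc`` when carbon > 0).

    Exposed separately because abundance-weighted Zc of lipid parts is a
    carbon-weighted mean: numerators and carbon counts are summed across
    species before dividing, and carbon-free parts (e.g. an amide-nitrogen
    backbone) still contribute a numerator term.
    """
    h = f["H"] + f["D"]
    return f.charge + 2 * f["O"] + 3 * f["N"] - 5 * f["P"] - 4 * f["S"] - h
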