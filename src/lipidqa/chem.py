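"""Lipid shorthand nomenclature, elemental composition and mass arithmetic.

This module implements the chemical bookkeeping layer of the toolkit:

* :class:`ElementalFormula` — an immutable multiset of atoms with Hill-order
  serialization and exact monoisotopic mass.
* :class:`ChainSpec` / :class:`LipidSpecies` — parsed LIPID MAPS-style
  shorthand names ("PC(16:0/18:1)", "TG(48:0)", "Cer(d42:2)") carrying the
  subclass, the fatty acyl/alkyl/alkenyl chains and the structural annotation
  level (sum composition, molecular species, or sn-position).
* Per-subclass composition templates: closed forms in the total carbon number
  NC and total double-bond count DB that build the full neutral molecule for
  each of the 20 plasma lipid subclasses covered by the database.
* Equivalent carbon number (ECN = NC − 2·DB) and Kendrick mass quantities
  used by the retention-behavior checks.

Monoisotopic masses are taken from a vendored CODATA/NIST constants table so
mass arithmetic is reproducible across environments.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "Linkage",
    "AnnotationLevel",
    "ChainSpec",
    "LipidSpecies",
    "SUBCLASSES",
    "parse_lipid_name",
    "format_lipid_name",
    "compose_formula",
    "monoisotopic_mass",
    "ecn",
    "kendrick_quantities",
]

# --------------------------------------------------------------------------
# Atomic constants (monoisotopic, Da; CODATA/NIST). Immutable at run time.
# --------------------------------------------------------------------------

ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "P": 30.97376151,
    "S": 31.97207069,
    "K": 38.96370649,
}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990946

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible elemental formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """A multiset of atoms, e.g. C42H82NO8P.

    Addition and subtraction are element-wise; subtraction raises
    :class:`FormulaError` if any count would go negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation string such as ``"C42H82NO8P"``."""
        if not text:
            return cls({})
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r}")
            pos = m.end()
            el = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[el] = counts.get(el, 0) + n
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count: {self} - {other}"
                )
            counts[el] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative int: {k}")
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def hill(self) -> str:
        """Serialize in Hill order: C, H, then remaining elements A→Z."""
        parts: List[str] = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of per-element monoisotopic masses."""
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.counts.items())


# Shared building blocks.
H2O = ElementalFormula.parse("H2O")
CH2 = ElementalFormula.parse("CH2")
H2 = ElementalFormula.parse("H2")
O1 = ElementalFormula.parse("O")


# --------------------------------------------------------------------------
# Shorthand names
# --------------------------------------------------------------------------


class Linkage(str, Enum):
    ACYL = "acyl"
    O_ALKYL = "O-alkyl"
    P_ALKENYL = "P-alkenyl"
    SPHINGOID = "sphingoid-d"


class AnnotationLevel(str, Enum):
    SPECIES = "species"              # sum composition only, e.g. TG(52:2)
    MOLECULAR_SPECIES = "molecular_species"  # chains known, order not: "_"
    SN_POSITION = "sn_position"      # chains placed on the backbone: "/"


@dataclass(frozen=True)
class ChainSpec:
    """One fatty acyl/alkyl/alkenyl or sphingoid chain: carbons:double_bonds."""

    carbons: int
    double_bonds: int
    linkage: Linkage = Linkage.ACYL

    def __post_init__(self):
        if self.carbons < 0 or self.double_bonds < 0:
            raise LipidNameError("chain carbons/double bonds must be >= 0")
        if self.double_bonds > self.carbons:
            raise LipidNameError(
                f"chain {self.carbons}:{self.double_bonds} has more double bonds than carbons"
            )

    def token(self) -> str:
        prefix = {
            Linkage.ACYL: "",
            Linkage.O_ALKYL: "O-",
            Linkage.P_ALKENYL: "P-",
            Linkage.SPHINGOID: "d",
        }[self.linkage]
        return f"{prefix}{self.carbons}:{self.double_bonds}"


class LipidNameError(ValueError):
    """Raised for malformed or chemically inconsistent shorthand names."""


#: head token → (number of chains at full resolution, is sphingolipid)
_HEAD_INFO: Mapping[str, Tuple[int, bool]] = {
    "FA": (1, False),
    "CAR": (1, False),
    "Cer": (2, True),
    "SM": (2, True),
    "HexCer": (2, True),
    "PC": (2, False),
    "PE": (2, False),
    "PI": (2, False),
    "LPC": (1, False),
    "LPE": (1, False),
    "LPI": (1, False),
    "DG": (2, False),
    "TG": (3, False),
    "CE": (1, False),
    "Cholesterol": (0, False),
}

#: the 20 subclass labels used throughout the database
SUBCLASSES: Tuple[str, ...] = (
    "FA", "CAR", "Cer", "SM", "HexCer",
    "PC", "PC O/P", "PE", "PE O/P", "PI",
    "LPC", "LPC O", "LPC O/P", "LPE", "LPE O/P", "LPI",
    "DG", "TG", "CE", "Cholesterol",
)

#: (head, ether prefix) → subclass label; plasmalogen-unresolved classes pool
#: O- and P- forms, except LPC where the O- form is its own subclass.
_ETHER_SUBCLASS: Mapping[Tuple[str, str], str] = {
    ("PC", "O"): "PC O/P",
    ("PC", "P"): "PC O/P",
    ("PE", "O"): "PE O/P",
    ("PE", "P"): "PE O/P",
    ("LPC", "O"): "LPC O",
    ("LPC", "P"): "LPC O/P",
    ("LPE", "O"): "LPE O/P",
    ("LPE", "P"): "LPE O/P",
}

_CHAIN_TOKEN = re.compile(r"^(d|O-|P-)?(\d+):(\d+)$")
_NAME = re.compile(r"^([A-Za-z]+)\((.*)\)$")


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid shorthand name.

    ``subclass`` is one of the 20 database labels (ether forms resolve PC →
    "PC O/P" etc.); ``chains`` is empty for Cholesterol and holds one
    sum-composition pseudo-chain at species level.  ``plasmalogen_unresolved``
    marks O/P-pooled labels where the alkyl vs alkenyl linkage was reported
    jointly.
    """

    subclass: str
    chains: Tuple[ChainSpec, ...]
    annotation_level: AnnotationLevel
    plasmalogen_unresolved: bool = False

    @property
    def nc(self) -> int:
        """Sum-composition carbon number NC."""
        return sum(c.carbons for c in self.chains)

    @property
    def db(self) -> int:
        """Sum-composition double-bond count DB."""
        return sum(c.double_bonds for c in self.chains)

    @property
    def name(self) -> str:
        return format_lipid_name(self)

    def __str__(self) -> str:
        return self.name


def _parse_chain(token: str, head: str) -> ChainSpec:
    m = _CHAIN_TOKEN.match(token)
    if not m:
        raise LipidNameError(f"malformed chain token {token!r}")
    prefix, c, d = m.group(1), int(m.group(2)), int(m.group(3))
    if prefix == "d":
        _, is_sp = _HEAD_INFO[head]
        if not is_sp:
            raise LipidNameError(
                f"sphingoid 'd' prefix is only legal on sphingolipid subclasses, not {head}"
            )
        linkage = Linkage.SPHINGOID
    elif prefix == "O-":
        linkage = Linkage.O_ALKYL
    elif prefix == "P-":
        linkage = Linkage.P_ALKENYL
    else:
        linkage = Linkage.ACYL
    return ChainSpec(c, d, linkage)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a LIPID MAPS-style shorthand name.

    The separator convention sets the annotation level: a single C:D token is
    sum-composition (*species*) level, ``_`` separates chains of unresolved
    position (*molecular species*), and ``/`` fixes sn-positions.

    >>> parse_lipid_name("TG(48:0)").nc
    48
    >>> parse_lipid_name("SM(d18:1/12:0)").annotation_level.value
    'sn_position'
    """
    name = name.strip()
    if name == "Cholesterol":
        return LipidSpecies("Cholesterol", (), AnnotationLevel.SPECIES)
    m = _NAME.match(name)
    if not m:
        raise LipidNameError(f"cannot parse lipid name {name!r}")
    head, body = m.group(1), m.group(2)
    if head not in _HEAD_INFO:
        raise LipidNameError(f"unknown subclass token {head!r} in {name!r}")
    if not body:
        raise LipidNameError(f"empty chain list in {name!r}")

    if "/" in body and "_" in body:
        raise LipidNameError(f"mixed '/' and '_' separators in {name!r}")
    if "/" in body:
        tokens, level = body.split("/"), AnnotationLevel.SN_POSITION
    elif "_" in body:
        tokens, level = body.split("_"), AnnotationLevel.MOLECULAR_SPECIES
    else:
        tokens, level = [body], AnnotationLevel.SPECIES

    chains = tuple(_parse_chain(t, head) for t in tokens)
    n_full, is_sp = _HEAD_INFO[head]

    # Lyso species are often written with an explicit 0:0 placeholder,
    # e.g. LPC(18:0/0:0); drop the placeholder but keep the level.
    if head.startswith("L") and len(chains) == 2 and chains[1].carbons == 0:
        chains = chains[:1]

    if all(c.carbons == 0 for c in chains):
        raise LipidNameError(f"all-zero chains in {name!r}")
    if level is not AnnotationLevel.SPECIES:
        expected = 1 if head.startswith("L") else n_full
        if len(chains) != expected:
            raise LipidNameError(
                f"{head} expects {expected} chains at {level.value} level, got {len(chains)}"
            )
        if any(c.carbons == 0 for c in chains):
            raise LipidNameError(f"zero-carbon chain in {name!r}")
        if is_sp and chains[0].linkage is not Linkage.SPHINGOID:
            raise LipidNameError(
                f"{head} requires a sphingoid (d-) backbone as first chain"
            )
        if is_sp and any(c.linkage is Linkage.SPHINGOID for c in chains[1:]):
            raise LipidNameError("sphingoid chain only legal in first position")
    else:
        if len(chains) != 1:
            raise LipidNameError(f"species-level name must have one C:D token: {name!r}")
        if is_sp and chains[0].linkage is not Linkage.SPHINGOID:
            raise LipidNameError(
                f"{head} species-level names carry the d prefix, e.g. {head}(d34:1)"
            )

    # Resolve ether subclasses from the first chain's linkage.
    ether = None
    for c in chains:
        if c.linkage is Linkage.O_ALKYL:
            ether = "O"
            break
        if c.linkage is Linkage.P_ALKENYL:
            ether = "P"
            break
    if ether is not None:
        key = (head, ether)
        if key not in _ETHER_SUBCLASS:
            raise LipidNameError(f"ether linkage not supported for subclass {head}")
        subclass = _ETHER_SUBCLASS[key]
        unresolved = subclass.endswith("O/P") and ether == "O"
    else:
        subclass = head
        unresolved = False

    return LipidSpecies(subclass, chains, level, plasmalogen_unresolved=unresolved)


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_lipid_name`."""
    if species.subclass == "Cholesterol":
        return "Cholesterol"
    head = species.subclass.split(" ")[0]
    sep = {
        AnnotationLevel.SPECIES: "",
        AnnotationLevel.MOLECULAR_SPECIES: "_",
        AnnotationLevel.SN_POSITION: "/",
    }[species.annotation_level]
    body = sep.join(c.token() for c in species.chains)
    return f"{head}({body})"


# --------------------------------------------------------------------------
# Composition templates
# --------------------------------------------------------------------------

# Head-group scaffolds assembled once from standard structures; the full
# molecule is scaffold + Σ chains − one H2O per ester/amide bond.  Expressed
# here directly as closed forms in (NC, DB): C/H/N/O/P counts as affine
# functions of NC and DB.  Each template is unit-tested against a
# hand-assembled reference formula.


@dataclass(frozen=True)
class _Template:
    c_off: int
    h_off: int
    extra: Mapping[str, int]  # non-C/H element counts

    def build(self, nc: int, db: int) -> ElementalFormula:
        counts = {"C": nc + self.c_off, "H": 2 * nc - 2 * db + self.h_off}
        counts.update(self.extra)
        if counts["H"] <= 0:
            raise FormulaError(f"infeasible composition NC={nc}, DB={db}")
        return ElementalFormula(counts)


_TEMPLATES: Mapping[str, _Template] = {
    "FA": _Template(0, 0, {"O": 2}),                      # CnH(2n-2d)O2
    "CAR": _Template(7, 13, {"N": 1, "O": 4}),            # carnitine + acyl - H2O
    "Cer": _Template(0, 1, {"N": 1, "O": 3}),             # sphingoid + N-acyl - H2O
    "SM": _Template(5, 13, {"N": 2, "O": 6, "P": 1}),     # Cer + phosphocholine
    "HexCer": _Template(6, 11, {"N": 1, "O": 8}),         # Cer + hexose - H2O
    "PC": _Template(8, 16, {"N": 1, "O": 8, "P": 1}),
    "PE": _Template(5, 10, {"N": 1, "O": 8, "P": 1}),
    "PI": _Template(9, 15, {"O": 13, "P": 1}),
    "LPC": _Template(8, 18, {"N": 1, "O": 7, "P": 1}),
    "LPE": _Template(5, 12, {"N": 1, "O": 7, "P": 1}),
    "LPI": _Template(9, 17, {"O": 12, "P": 1}),
    "DG": _Template(3, 4, {"O": 5}),                      # glycerol + 2 acyl - 2 H2O
    "TG": _Template(3, 2, {"O": 6}),                      # glycerol + 3 acyl - 3 H2O
    "CE": _Template(27, 44, {"O": 2}),                    # cholesterol + acyl - H2O
}

CHOLESTEROL_FORMULA = ElementalFormula.parse("C27H46O")


def compose_formula(species: LipidSpecies) -> ElementalFormula:
    """Neutral full-molecule elemental composition of a lipid species.

    Diacyl/triacyl templates are closed forms in (NC, DB).  Ether (O-) chains
    replace one ester oxygen with an ether bond (−O +2H relative to the acyl
    template); plasmenyl (P-) chains are the O- composition with one extra
    double-bond equivalent (−2H), i.e. the vinyl-ether double bond is *not*
    counted in the shorthand DB.
    """
    if species.subclass == "Cholesterol":
        if species.chains:
            raise FormulaError("Cholesterol carries no chains")
        return CHOLESTEROL_FORMULA
    head = species.subclass.split(" ")[0]
    if head not in _TEMPLATES:
        raise FormulaError(f"no composition template for subclass {species.subclass!r}")
    formula = _TEMPLATES[head].build(species.nc, species.db)
    for chain in species.chains:
        if chain.linkage is Linkage.O_ALKYL:
            formula = formula - O1 + H2
        elif chain.linkage is Linkage.P_ALKENYL:
            formula = formula - O1  # +H2 for the ether, -H2 for the vinyl DBE
    return formula


# --------------------------------------------------------------------------
# ECN and Kendrick quantities
# --------------------------------------------------------------------------


def ecn(species: LipidSpecies) -> int:
    """Equivalent carbon number, ECN = NC − 2·DB."""
    return species.nc - 2 * species.db


def kendrick_quantities(mz: float) -> Tuple[float, float]:
    """Kendrick mass and Kendrick mass defect (CH2 base unit).

    ``kendrick_mass = mz × 14 / m(CH2)``; ``KMD = round(KM) − KM`` with
    nearest-integer rounding.  Members of a CH2 homologous series share KMD.
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    km = mz * 14.0 / monoisotopic_mass(CH2)
    return km, round(km) - km
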