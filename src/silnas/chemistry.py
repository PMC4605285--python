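"""Elemental-composition arithmetic, nucleoside/modification registries and
isotope-label schemes.

All masses in this package are *monoisotopic* and derive from the single
atomic-mass table below, so that every theoretical m/z printed downstream is
reproducible to well under 0.01 Da.  Carbon-13 is carried as a separate
element symbol (``"13C"``) rather than as a mass correction, which keeps
composition arithmetic exact for the heavy (in-vitro transcribed,
13C-nucleoside labeled) reference species.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "C13_SHIFT",
    "ElementalComposition",
    "NucleosideDef",
    "ModificationDef",
    "LabelScheme",
    "NUCLEOSIDES",
    "MODIFICATIONS",
    "LABEL_SCHEMES",
    "WATER",
    "HPO3",
    "METHYL",
    "CYANOETHYL",
    "composition_mass",
    "modification_delta",
    "label_delta",
]

#: Monoisotopic atomic masses (Da), CODATA/IUPAC values.  Fixed here in one
#: table; nothing else in the package defines an atomic mass.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "13C": 13.0033548,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Mass of a proton (Da); used for (de)protonation when charging.
PROTON_MASS = 1.00727646

#: Mass difference of one 12C -> 13C substitution (Da).
C13_SHIFT = MONOISOTOPIC_MASS["13C"] - MONOISOTOPIC_MASS["C"]

_FORMULA_TOKEN = re.compile(r"(13C|[A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping[str, int]):
    """Immutable map element symbol -> count with element-wise arithmetic.

    Counts are non-negative integers; subtraction raising below zero is an
    error (a composition is a physical inventory, not a signed delta).
    Unknown element symbols are rejected at construction time.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: Dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for symbol, n in source.items():
                if symbol not in MONOISOTOPIC_MASS:
                    raise KeyError(f"unknown element symbol: {symbol!r}")
                if int(n) != n or n < 0:
                    raise ValueError(
                        f"count for {symbol} must be a non-negative integer, got {n!r}"
                    )
                if n:
                    merged[symbol] = merged.get(symbol, 0) + int(n)
        object.__setattr__(self, "_counts", merged)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a plain formula such as ``"C9H13N3O5"`` or ``"13C10"``.

        An empty string or ``"-"`` denotes the empty composition (used for
        mass-silent modifications such as pseudouridine).
        """
        formula = formula.strip()
        if formula in ("", "-"):
            return cls()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            symbol, digits = match.groups()
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for symbol, n in other.items():
            counts[symbol] = counts.get(symbol, 0) + n
        return ElementalComposition(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for symbol, n in other.items():
            remaining = counts.get(symbol, 0) - n
            if remaining < 0:
                raise ValueError(
                    f"subtraction yields negative count for {symbol}: "
                    f"{counts.get(symbol, 0)} - {n}"
                )
            counts[symbol] = remaining
        return ElementalComposition({k: v for k, v in counts.items() if v})

    def __mul__(self, n: int) -> "ElementalComposition":
        if int(n) != n or n < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementalComposition({k: v * int(n) for k, v in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula!r})"

    @property
    def formula(self) -> str:
        order = ["C", "13C", "H", "N", "O", "P"]
        parts = []
        for symbol in order:
            n = self._counts.get(symbol, 0)
            if n:
                parts.append(f"{symbol}{n if n != 1 else ''}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass (Da)."""
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self._counts.items())

    def substitute_c13(self, n: int) -> "ElementalComposition":
        """Replace ``n`` 12C atoms with 13C (isotope labeling)."""
        return self - ElementalComposition(C=n) + ElementalComposition({"13C": n})


def composition_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass of a composition (Da)."""
    return comp.mass


# -- shared small compositions ---------------------------------------------
WATER = ElementalComposition.from_formula("H2O")
HPO3 = ElementalComposition.from_formula("HPO3")
METHYL = ElementalComposition.from_formula("CH2")  # net methylation delta
CYANOETHYL = ElementalComposition.from_formula("C3H3N")  # acrylonitrile adduct


@dataclass(frozen=True)
class NucleosideDef:
    """A canonical ribonucleoside: full (base+ribose) and free-base formulas."""

    code: str
    composition: ElementalComposition
    base_composition: ElementalComposition

    @property
    def carbon_count(self) -> int:
        return self.composition["C"]


NUCLEOSIDES: Dict[str, NucleosideDef] = {
    "A": NucleosideDef(
        "A",
        ElementalComposition.from_formula("C10H13N5O4"),  # adenosine
        ElementalComposition.from_formula("C5H5N5"),  # adenine
    ),
    "C": NucleosideDef(
        "C",
        ElementalComposition.from_formula("C9H13N3O5"),  # cytidine
        ElementalComposition.from_formula("C4H5N3O"),  # cytosine
    ),
    "G": NucleosideDef(
        "G",
        ElementalComposition.from_formula("C10H13N5O5"),  # guanosine
        ElementalComposition.from_formula("C5H5N5O"),  # guanine
    ),
    "U": NucleosideDef(
        "U",
        ElementalComposition.from_formula("C9H12N2O6"),  # uridine
        ElementalComposition.from_formula("C4H4N2O2"),  # uracil
    ),
}


@dataclass(frozen=True)
class ModificationDef:
    """A registered post-transcriptional modification.

    ``placement`` is one of ``ribose`` (2'-O-methyl class), ``base`` (base
    methyl/acetyl/adduct chemistry) or ``backbone-isomer`` (pseudouridine:
    a C-C glycosidic isomer of uridine, hence a zero mass delta).
    ``blocks_cleavage_3prime`` marks modifications (2'-O-methyls) that
    protect the 3'-adjacent phosphodiester bond from RNase cleavage.
    """

    code: str
    target_base: str
    delta: ElementalComposition
    placement: str
    blocks_cleavage_3prime: bool
    mod_class: str

    @property
    def delta_mass(self) -> float:
        return self.delta.mass


def _load_modifications() -> Dict[str, ModificationDef]:
    registry: Dict[str, ModificationDef] = {}
    text = resources.files("silnas.data").joinpath("modifications.tsv").read_text()
    reader = csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#")),
        delimiter="\t",
    )
    for row in reader:
        code = row["code"]
        if code in registry:
            raise ValueError(f"duplicate modification code {code!r}")
        if row["target_base"] not in NUCLEOSIDES:
            raise ValueError(f"unknown target base for {code!r}")
        registry[code] = ModificationDef(
            code=code,
            target_base=row["target_base"],
            delta=ElementalComposition.from_formula(row["delta_formula"]),
            placement=row["placement"],
            blocks_cleavage_3prime=row["blocks_3prime_cleavage"].lower() == "true",
            mod_class=row["mod_class"],
        )
    return registry


MODIFICATIONS: Dict[str, ModificationDef] = _load_modifications()


def modification_delta(code: str) -> float:
    """Monoisotopic mass delta (Da) of a registered modification."""
    try:
        return MODIFICATIONS[code].delta_mass
    except KeyError:
        raise KeyError(f"unregistered modification code {code!r}") from None


@dataclass(frozen=True)
class LabelScheme:
    """A stable-isotope labeling scheme for the in-vitro reference transcript.

    ``n_substituted`` maps a base symbol to the number of 13C substitutions
    carried by every residue of that base (10 for guanosine, 9 for cytidine
    or uridine, matching the commercially available 13C-NTPs).  Enrichment is
    treated as complete: the heavy species is matched at the fully labeled
    mass.
    """

    name: str
    n_substituted: Mapping[str, int] = field(default_factory=dict)

    def delta(self, base: str) -> float:
        return self.n_substituted.get(base, 0) * C13_SHIFT

    @property
    def is_null(self) -> bool:
        return not any(self.n_substituted.values())


LABEL_SCHEMES: Dict[str, LabelScheme] = {
    "heavy-g": LabelScheme("heavy-g", {"G": 10}),
    "heavy-c": LabelScheme("heavy-c", {"C": 9}),
    "heavy-u": LabelScheme("heavy-u", {"U": 9}),
    # combined C+U labeling, used for pyrimidine-cutting digests so every
    # product (which always ends in C or U) carries at least one label
    "heavy-cu": LabelScheme("heavy-cu", {"C": 9, "U": 9}),
    "none": LabelScheme("none", {}),
}


def label_delta(base: str, scheme: LabelScheme) -> float:
    """Heavy-minus-light mass delta (Da) of one residue under a label scheme."""
    if base not in NUCLEOSIDES:
        raise KeyError(f"unknown base {base!r}")
    return scheme.delta(base)


def sequence_label_delta(sequence: str, scheme: LabelScheme) -> float:
    """Total heavy-minus-light mass delta over an oligonucleotide sequence."""
    return sum(label_delta(b, scheme) for b in sequence)
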