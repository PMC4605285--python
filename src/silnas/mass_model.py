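"""Neutral masses, negative-mode m/z, CID ion ladders and base-loss
diagnostics for oligonucleotide fragments.

Mass bookkeeping: an n-mer is the sum of its nucleoside compositions plus
one (HPO3 - H2O) per internal phosphodiester bond, plus terminal groups
(5'-p: +HPO3, 5'-ppp: +3 HPO3; 3'-linear-p: +HPO3, 3'-cyclic-p:
+HPO3 - H2O).  Isotope labels substitute 12C -> 13C in the composition
itself, so heavy masses are exact, not approximate shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chemistry import (
    CYANOETHYL,
    HPO3,
    MODIFICATIONS,
    NUCLEOSIDES,
    PROTON_MASS,
    WATER,
    ElementalComposition,
    LabelScheme,
    LABEL_SCHEMES,
)
from .digestion import Fragment

__all__ = [
    "species_composition",
    "neutral_mass",
    "mz",
    "mass_from_mz",
    "charge_states",
    "IonLadder",
    "ion_ladder",
    "base_loss_candidates",
    "residue_base_losses",
]

NONE_LABEL = LABEL_SCHEMES["none"]

_TERMINAL_5P = {
    "OH": ElementalComposition(),
    "p": HPO3,
    "ppp": 3 * HPO3,
}
_CE_TARGETS = frozenset("U")  # cyanoethylation targets U and its isomer psi


@lru_cache(maxsize=4096)
def _residue_composition_cached(
    base: str, mods: Tuple[str, ...], label_name: str, n13: int
) -> ElementalComposition:
    comp = NUCLEOSIDES[base].composition
    for code in mods:
        mod = MODIFICATIONS[code]
        if mod.target_base != base:
            raise ValueError(f"{code} does not target {base}")
        comp = comp + mod.delta
    if n13:
        comp = comp.substitute_c13(n13)
    return comp


def _residue_composition(
    base: str, mods: Sequence[str], label: LabelScheme
) -> ElementalComposition:
    return _residue_composition_cached(
        base, tuple(mods), label.name, label.n_substituted.get(base, 0)
    )


def species_composition(
    fragment: Fragment,
    label: LabelScheme = NONE_LABEL,
    n_cyanoethyl: int = 0,
    extra: Optional[ElementalComposition] = None,
) -> ElementalComposition:
    """Elemental composition of a fragment ion species (neutral form).

    ``n_cyanoethyl`` adds unlocalized acrylonitrile adducts (+C3H3N each);
    it must not exceed the number of U/psi residues.  ``extra`` adds an
    arbitrary unlocalized composition (used for variable-modification
    search hypotheses such as +CH2 methyls).
    """
    seq = fragment.sequence
    if not seq:
        raise ValueError("empty fragment")
    if n_cyanoethyl < 0:
        raise ValueError("n_cyanoethyl must be >= 0")
    n_u = sum(1 for b in seq if b in _CE_TARGETS)
    localized_ce = sum(
        1 for _, codes in fragment.mods for c in codes if c == "ce"
    )
    if n_cyanoethyl + localized_ce > n_u:
        raise ValueError(
            f"{n_cyanoethyl + localized_ce} cyanoethyl groups on {n_u} U residues"
        )
    local = fragment.local_mods()
    comp = ElementalComposition()
    for i, base in enumerate(seq, start=1):
        comp = comp + _residue_composition(base, local.get(i, ()), label)
    n_bonds = len(seq) - 1
    comp = comp + n_bonds * HPO3
    for _ in range(n_bonds):
        comp = comp - WATER
    comp = comp + _TERMINAL_5P[fragment.five_prime]
    if fragment.three_prime == "p":
        comp = comp + HPO3
    elif fragment.three_prime == "cp":
        comp = comp + HPO3 - WATER
    elif fragment.three_prime != "OH":
        raise ValueError(f"invalid 3' terminus {fragment.three_prime!r}")
    if n_cyanoethyl:
        comp = comp + n_cyanoethyl * CYANOETHYL
    if extra is not None:
        comp = comp + extra
    return comp


@lru_cache(maxsize=8192)
def _residue_mass(base: str, mods: Tuple[str, ...], label_name: str, n13: int) -> float:
    return _residue_composition_cached(base, mods, label_name, n13).mass


_BOND_MASS = HPO3.mass - WATER.mass
_TERMINAL_5P_MASS = {k: v.mass for k, v in _TERMINAL_5P.items()}
_TERMINAL_3P_MASS = {"OH": 0.0, "p": HPO3.mass, "cp": HPO3.mass - WATER.mass}


def neutral_mass(
    fragment: Fragment,
    label: LabelScheme = NONE_LABEL,
    n_cyanoethyl: int = 0,
    extra: Optional[ElementalComposition] = None,
) -> float:
    """Monoisotopic neutral mass (Da) of a fragment species.

    Float fast path over cached per-residue masses; agrees with
    :func:`species_composition` to numerical round-off (the composition
    route is the reference and is exercised as such in the test suite).
    """
    seq = fragment.sequence
    if not seq:
        raise ValueError("empty fragment")
    if n_cyanoethyl < 0:
        raise ValueError("n_cyanoethyl must be >= 0")
    n_u = sum(1 for b in seq if b in _CE_TARGETS)
    localized_ce = sum(1 for _, codes in fragment.mods for c in codes if c == "ce")
    if n_cyanoethyl + localized_ce > n_u:
        raise ValueError(
            f"{n_cyanoethyl + localized_ce} cyanoethyl groups on {n_u} U residues"
        )
    if fragment.three_prime not in _TERMINAL_3P_MASS:
        raise ValueError(f"invalid 3' terminus {fragment.three_prime!r}")
    local = fragment.local_mods()
    mass = 0.0
    for i, base in enumerate(seq, start=1):
        mass += _residue_mass(
            base, local.get(i, ()), label.name, label.n_substituted.get(base, 0)
        )
    mass += (len(seq) - 1) * _BOND_MASS
    mass += _TERMINAL_5P_MASS[fragment.five_prime]
    mass += _TERMINAL_3P_MASS[fragment.three_prime]
    mass += n_cyanoethyl * CYANOETHYL.mass
    if extra is not None:
        mass += extra.mass
    return mass


def mz(neutral: float, charge: int) -> float:
    """Negative-mode m/z of an n-fold deprotonated species."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral - charge * PROTON_MASS) / charge


def mass_from_mz(mz_value: float, charge: int) -> float:
    """Inverse of :func:`mz`."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz_value * charge + charge * PROTON_MASS


def charge_states(neutral: float) -> range:
    """Default precursor charge enumeration: 1..ceil(mass/1000).

    Covers 2- for a 5-mer (~1.6 kDa) through 4- and beyond for an 18-mer
    (~5.7 kDa), matching how such species are observed in negative mode.
    """
    return range(1, max(1, math.ceil(neutral / 1000.0)) + 1)


@dataclass(frozen=True)
class IonLadder:
    """Singly charged c/y/w/a-B product-ion m/z per internucleotide bond.

    Keys are the bond index i = 1..n-1 (bond 3' of residue i).  c and a-B
    are 5' (prefix) ions; y and w are 3' (suffix) ions covering the same
    bond from the other side.
    """

    precursor_neutral: float
    c: Dict[int, float]
    y: Dict[int, float]
    w: Dict[int, float]
    a_minus_b: Dict[int, float]

    def all_mz(self) -> List[float]:
        vals: List[float] = []
        for series in (self.c, self.y, self.w, self.a_minus_b):
            vals.extend(series.values())
        return vals

    def series(self) -> Dict[str, Dict[int, float]]:
        return {"c": self.c, "y": self.y, "w": self.w, "a-B": self.a_minus_b}


def _sub_fragment(fragment: Fragment, lo: int, hi: int, fp: str, tp: str) -> Fragment:
    """Sub-span [lo, hi] (fragment-local, 1-based) with chosen termini."""
    g_lo = fragment.start + lo - 1
    g_hi = fragment.start + hi - 1
    mods = {p: c for p, c in fragment.mods if g_lo <= p <= g_hi}
    return Fragment(
        parent_id=fragment.parent_id,
        start=g_lo,
        end=g_hi,
        sequence=fragment.sequence[lo - 1 : hi],
        mods=tuple(sorted(mods.items())),
        five_prime=fp,
        three_prime=tp,
    )


def residue_base_losses(fragment: Fragment, label: LabelScheme = NONE_LABEL) -> Dict[int, float]:
    """Neutral free-base loss mass per fragment-local position.

    The lost base carries its base-placement modifications (a base methyl
    travels with the base; a ribose methyl does not), which is the entire
    basis of the base-vs-sugar methyl diagnostic.
    """
    local = fragment.local_mods()
    losses: Dict[int, float] = {}
    for i, base in enumerate(fragment.sequence, start=1):
        comp = NUCLEOSIDES[base].base_composition
        for code in local.get(i, ()):
            mod = MODIFICATIONS[code]
            if mod.placement == "base":
                comp = comp + mod.delta
        n13 = label.n_substituted.get(base, 0)
        if n13:
            base_c = comp["C"]
            comp = comp.substitute_c13(min(n13, base_c))
        losses[i] = comp.mass
    return losses


def ion_ladder(fragment: Fragment, label: LabelScheme = NONE_LABEL) -> IonLadder:
    """Theoretical c/y/w/a-B ladder at charge 1 for a fragment species.

    Definitions (neutral forms): c_i = prefix(1..i) with 3'-phosphate;
    y_j = suffix with 5'-OH; w_j = suffix with 5'-phosphate;
    a_i = prefix with 3'-OH minus water at the cleaved bond (= c_i - HPO3);
    (a-B)_i additionally loses the 3'-terminal base of the prefix as a
    neutral.  Complementarity: c_i + y_(n-i) = M + H2O exactly.
    """
    n = len(fragment.sequence)
    if n < 2:
        raise ValueError("ion ladder requires fragment length >= 2")
    precursor = neutral_mass(fragment, label)
    base_losses = residue_base_losses(fragment, label)
    c: Dict[int, float] = {}
    y: Dict[int, float] = {}
    w: Dict[int, float] = {}
    a_b: Dict[int, float] = {}
    hpo3 = HPO3.mass
    for i in range(1, n):
        prefix = _sub_fragment(fragment, 1, i, fragment.five_prime, "p")
        suffix = _sub_fragment(fragment, i + 1, n, "OH", fragment.three_prime)
        c_neutral = neutral_mass(prefix, label)
        y_neutral = neutral_mass(suffix, label)
        a_neutral = c_neutral - hpo3
        c[i] = mz(c_neutral, 1)
        y[n - i] = mz(y_neutral, 1)
        w[n - i] = mz(y_neutral + hpo3, 1)
        a_b[i] = mz(a_neutral - base_losses[i], 1)
    return IonLadder(precursor_neutral=precursor, c=c, y=y, w=w, a_minus_b=a_b)


@dataclass(frozen=True)
class MethylHypothesis:
    """A candidate placement of one methyl group on a fragment."""

    position: int  # fragment-local, 1-based
    placement: str  # "base" | "ribose"


def base_loss_candidates(
    fragment: Fragment, hypotheses: Iterable[MethylHypothesis]
) -> Dict[MethylHypothesis, float]:
    """Expected diagnostic neutral loss from the precursor per hypothesis.

    A base-placed methyl yields loss of the *methylated* free base
    (+14.0157 over the plain base); a ribose (2'-O) methyl leaves the base
    untouched, so only the unmethylated base loss is expected.
    """
    from .chemistry import METHYL

    losses: Dict[MethylHypothesis, float] = {}
    for hyp in hypotheses:
        base = fragment.sequence[hyp.position - 1]
        comp = NUCLEOSIDES[base].base_composition
        if hyp.placement == "base":
            comp = comp + METHYL
        elif hyp.placement != "ribose":
            raise ValueError(f"unknown placement {hyp.placement!r}")
        losses[hyp] = comp.mass
    return losses
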