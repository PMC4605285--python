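"""Modification-aware in-silico nuclease digestion.

RNase T1 cleaves 3' of guanosine, RNase A 3' of pyrimidines; both leave
5'-OH products with a 3'-(linear or 2',3'-cyclic) phosphate.  A residue
carrying a 2'-O-methyl is not cleaved (the 2'-OH is the nucleophile of the
transesterification), which is what makes these enzymes informative about
ribose methylation: the methylated site shows up as a merged fragment.

Coordinates are 1-based inclusive throughout, matching the positional
notation used for rRNA modification sites (e.g. "Y76" = pseudouridine at
position 76); converters to 0-based half-open live at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

from .chemistry import MODIFICATIONS

__all__ = [
    "AnnotatedSequence",
    "Fragment",
    "DigestParams",
    "ENZYME_TARGETS",
    "digest",
    "rnase_h_segment",
    "find_redundant_fragments",
    "RedundantGroup",
]

#: Residues 3' of which each enzyme cleaves.
ENZYME_TARGETS: Dict[str, frozenset] = {
    "T1": frozenset("G"),
    "A": frozenset("CU"),
}

ModMap = Dict[int, Tuple[str, ...]]


def _normalize_mods(mods) -> ModMap:
    out: ModMap = {}
    for pos, codes in (mods or {}).items():
        if isinstance(codes, str):
            codes = (codes,)
        out[int(pos)] = tuple(codes)
    return out


@dataclass
class AnnotatedSequence:
    """An RNA sequence with per-position modification state.

    ``mods`` maps 1-based position -> tuple of modification codes (more than
    one code per position occurs for e.g. a cyanoethylated pseudouridine).
    ``origin_offset`` records the 0-based offset of this sequence within a
    parent molecule, so that RNase-H segments keep recoverable global
    coordinates: global = local + origin_offset.
    """

    id: str
    residues: str
    mods: ModMap = field(default_factory=dict)
    five_prime: str = "OH"  # OH | p | ppp
    three_prime: str = "OH"  # OH | p
    origin_offset: int = 0

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("T", "U")
        bad = set(self.residues) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: non-RNA residues {sorted(bad)}")
        if self.five_prime not in ("OH", "p", "ppp"):
            raise ValueError(f"invalid 5' terminus {self.five_prime!r}")
        if self.three_prime not in ("OH", "p"):
            raise ValueError(f"invalid 3' terminus {self.three_prime!r}")
        self.mods = _normalize_mods(self.mods)
        for pos, codes in self.mods.items():
            if not 1 <= pos <= len(self.residues):
                raise ValueError(f"{self.id}: mod position {pos} out of range")
            for code in codes:
                mod = MODIFICATIONS.get(code)
                if mod is None:
                    raise KeyError(f"{self.id}: unregistered modification {code!r}")
                if mod.target_base != self.residues[pos - 1]:
                    raise ValueError(
                        f"{self.id}: {code} targets {mod.target_base}, "
                        f"residue at {pos} is {self.residues[pos - 1]}"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    def blocks_cleavage(self, pos: int) -> bool:
        return any(
            MODIFICATIONS[c].blocks_cleavage_3prime for c in self.mods.get(pos, ())
        )


@dataclass(frozen=True)
class Fragment:
    """A nuclease product with parent coordinates and modification payload.

    ``mods`` keeps *global* (parent) positions so fragments from different
    digests of the same molecule are directly comparable.  Terminal
    chemistry: 5' in {OH, p, ppp}; 3' in {OH, p (linear), cp (2',3'-cyclic)}.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    mods: Tuple[Tuple[int, Tuple[str, ...]], ...] = ()
    missed_cleavages: int = 0
    five_prime: str = "OH"
    three_prime: str = "p"

    @property
    def mod_map(self) -> ModMap:
        return dict(self.mods)

    def mods_at(self, global_pos: int) -> Tuple[str, ...]:
        return self.mod_map.get(global_pos, ())

    def local_mods(self) -> ModMap:
        """Modifications keyed by position within the fragment (1-based)."""
        return {pos - self.start + 1: codes for pos, codes in self.mods}

    @property
    def identity(self) -> Tuple[str, int, int]:
        return (self.parent_id, self.start, self.end)

    @property
    def species_key(self) -> tuple:
        """What mass spectrometry can distinguish: sequence, mods, termini."""
        local = tuple(sorted(self.local_mods().items()))
        return (self.sequence, local, self.five_prime, self.three_prime)

    def with_mods(self, mods: ModMap) -> "Fragment":
        return replace(self, mods=tuple(sorted(mods.items())))


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "T1"
    max_missed: int = 1
    product_three_prime: str = "p"  # p (linear) | cp (2',3'-cyclic)

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYME_TARGETS:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.product_three_prime not in ("p", "cp"):
            raise ValueError("product 3' chemistry must be 'p' or 'cp'")


def cleavage_sites(seq: AnnotatedSequence, enzyme: str) -> List[int]:
    """1-based positions whose 3' phosphodiester bond is cleaved.

    Only internal bonds count (a target residue at the very 3' end produces
    no new fragment).  Sites carrying a cleavage-blocking modification
    (2'-O-methyl) are skipped.
    """
    targets = ENZYME_TARGETS[enzyme]
    return [
        i
        for i in range(1, len(seq))
        if seq.residues[i - 1] in targets and not seq.blocks_cleavage(i)
    ]


def digest(seq: AnnotatedSequence, params: DigestParams) -> List[Fragment]:
    """All digestion products with 0..max_missed missed cleavages.

    End fragments inherit the parent termini; internal boundaries get 5'-OH
    and the configured 3' product chemistry.
    """
    if not seq.residues:
        raise ValueError("empty sequence")
    sites = cleavage_sites(seq, params.enzyme)
    bounds = [0] + sites + [len(seq)]
    fragments: List[Fragment] = []
    for i in range(len(bounds) - 1):
        for missed in range(params.max_missed + 1):
            j = i + 1 + missed
            if j > len(bounds) - 1:
                break
            start, end = bounds[i] + 1, bounds[j]
            frag_mods = {
                pos: codes for pos, codes in seq.mods.items() if start <= pos <= end
            }
            fragments.append(
                Fragment(
                    parent_id=seq.id,
                    start=start,
                    end=end,
                    sequence=seq.residues[start - 1 : end],
                    mods=tuple(sorted(frag_mods.items())),
                    missed_cleavages=missed,
                    five_prime=seq.five_prime if start == 1 else "OH",
                    three_prime=seq.three_prime
                    if end == len(seq)
                    else params.product_three_prime,
                )
            )
    return fragments


def rnase_h_segment(
    seq: AnnotatedSequence, cut_points: Sequence[int]
) -> List[AnnotatedSequence]:
    """Partition a sequence at guide-DNA-directed RNase H cut points.

    ``cut_points`` are 1-based positions *after* which the backbone is cut
    (cut at 40 -> segments 1-40 and 41-end).  RNase H leaves 5'-phosphate /
    3'-OH ends at new junctions; parent termini are kept at the outer ends.
    Modification coordinates are re-expressed per segment, with
    ``origin_offset`` recording how to recover global positions.
    """
    n = len(seq)
    if any(not 1 <= p < n for p in cut_points):
        raise ValueError(f"cut points must lie in [1, {n - 1}]")
    pts = sorted(set(cut_points))
    if len(pts) != len(cut_points):
        raise ValueError("cut points must be strictly increasing and unique")
    bounds = [0] + pts + [n]
    segments: List[AnnotatedSequence] = []
    for i in range(len(bounds) - 1):
        start, end = bounds[i] + 1, bounds[i + 1]
        local_mods = {
            pos - start + 1: codes
            for pos, codes in seq.mods.items()
            if start <= pos <= end
        }
        segments.append(
            AnnotatedSequence(
                id=f"{seq.id}[{start}-{end}]" if pts else seq.id,
                residues=seq.residues[start - 1 : end],
                mods=local_mods,
                five_prime=seq.five_prime if start == 1 else "p",
                three_prime=seq.three_prime if end == n else "OH",
                origin_offset=seq.origin_offset + start - 1,
            )
        )
    return segments


@dataclass(frozen=True)
class RedundantGroup:
    """Fragments indistinguishable by MS (same sequence/mods/termini) that
    arise from more than one location in the parent."""

    species_key: tuple
    members: Tuple[Fragment, ...]
    cut_windows: Tuple[Tuple[int, int], ...]

    @property
    def placements(self) -> Tuple[Tuple[int, int], ...]:
        return tuple((f.start, f.end) for f in self.members)


def find_redundant_fragments(fragments: Iterable[Fragment]) -> List[RedundantGroup]:
    """Group fragments with identical MS-visible species from distinct
    coordinates, and suggest RNase-H cut windows separating each group.

    A cut window (lo, hi) means: cutting after any position p with
    lo <= p <= hi leaves the two neighbouring group members in different
    RNase-H segments.
    """
    by_key: Dict[tuple, List[Fragment]] = {}
    parents = set()
    for frag in fragments:
        parents.add(frag.parent_id)
        by_key.setdefault(frag.species_key, []).append(frag)
    if len(parents) > 1:
        raise ValueError("redundancy analysis expects fragments from one parent")
    groups: List[RedundantGroup] = []
    for key, members in by_key.items():
        placements = sorted(set(f.identity for f in members))
        if len(placements) < 2:
            continue
        ordered = sorted(
            {f.identity: f for f in members}.values(), key=lambda f: f.start
        )
        windows = []
        for a, b in zip(ordered, ordered[1:]):
            if a.end < b.start:
                windows.append((a.end, b.start - 1))
        groups.append(
            RedundantGroup(
                species_key=key,
                members=tuple(ordered),
                cut_windows=tuple(windows),
            )
        )
    groups.sort(key=lambda g: g.members[0].start)
    return groups
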