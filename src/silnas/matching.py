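"""Theoretical light/heavy ion index, ppm feature matching, light-heavy
pairing, and MS/MS site localization.

The index enumerates every digest fragment as a light species (with
variable-modification hypotheses: up to ``max_variable_methyl`` extra
methyls plus any configured single-site variable mods) and as a heavy
species (the in-vitro reference transcript carries no modifications, so
heavy entries get no variable mods), across charge states and optionally
cyanoethylation states.  Observed features are matched by binary search at
a ppm tolerance; light/heavy pairs of the same fragment identity and charge
are the quantification unit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .chemistry import (
    METHYL,
    MODIFICATIONS,
    LabelScheme,
    LABEL_SCHEMES,
)
from .digestion import Fragment
from .mass_model import (
    charge_states,
    ion_ladder,
    mass_from_mz,
    mz,
    neutral_mass,
    residue_base_losses,
)

__all__ = [
    "Feature",
    "SearchParams",
    "IndexEntry",
    "TheoreticalIndex",
    "build_index",
    "Match",
    "match_features",
    "FeaturePair",
    "PairingResult",
    "pair_light_heavy",
    "LocalizationCandidate",
    "localize_msms",
    "candidates_for_entry",
]

#: Canonical code assigned when MS evidence shows a base-placed methyl on a
#: given base; positional isomers on the base ring (e.g. m1A vs m6A) are not
#: distinguishable from CID data alone.
CANONICAL_BASE_METHYL = {"A": "m6A", "C": "m5C", "G": "m7G", "U": "m3U"}
CANONICAL_RIBOSE_METHYL = {"A": "Am", "C": "Cm", "G": "Gm", "U": "Um"}


@dataclass(frozen=True)
class Feature:
    """An observed LC-MS feature (apex of an extracted-ion chromatogram)."""

    mz: float
    charge: int
    rt: float  # seconds
    intensity: float
    msms: Optional[Tuple[Tuple[float, float], ...]] = None
    run_id: str = "run"
    replicate: int = 0
    feature_id: int = -1

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("feature intensity must be > 0")
        if self.charge < 1:
            raise ValueError("feature charge must be >= 1")

    @property
    def neutral_mass(self) -> float:
        return mass_from_mz(self.mz, self.charge)


@dataclass(frozen=True)
class SearchParams:
    """Database-search settings (defaults follow common practice for RNA
    RNase mapping: 20 ppm precursor, 750 ppm product-ion tolerance, at most
    two variable methylations per fragment, one missed cleavage upstream)."""

    ms1_tol_ppm: float = 20.0
    ms2_tol_ppm: float = 750.0
    max_variable_methyl: int = 2
    variable_mods: Tuple[Tuple[str, int], ...] = ()  # (code, max count)
    charge_range: Optional[Tuple[int, int]] = None
    enable_ce: bool = False
    max_ce: int = 2
    rt_pair_window: float = 30.0  # seconds; co-elution window (0.5 min)
    base_loss_weight: float = 0.1

    def charges_for(self, neutral: float) -> Iterable[int]:
        if self.charge_range is not None:
            lo, hi = self.charge_range
            return range(lo, hi + 1)
        return charge_states(neutral)


@dataclass(frozen=True)
class IndexEntry:
    """One (fragment x label x variable-mod state x CE state x charge) ion."""

    fragment: Fragment
    label_name: str
    is_heavy: bool
    n_methyl: int
    var_mods: Tuple[Tuple[str, int], ...]
    n_ce: int
    charge: int
    neutral: float
    mz: float

    @property
    def identity(self) -> Tuple[str, int, int]:
        return self.fragment.identity

    @property
    def is_plain(self) -> bool:
        """No variable-mod or CE hypothesis attached."""
        return self.n_methyl == 0 and not self.var_mods and self.n_ce == 0


class TheoreticalIndex:
    """m/z-sorted species index supporting ppm-window queries."""

    def __init__(self, entries: Sequence[IndexEntry], label: LabelScheme,
                 params: SearchParams):
        self.entries: List[IndexEntry] = sorted(entries, key=lambda e: e.mz)
        self._mzs = np.array([e.mz for e in self.entries])
        self.label = label
        self.params = params

    def __len__(self) -> int:
        return len(self.entries)

    def query(self, mz_value: float, tol_ppm: float) -> List[IndexEntry]:
        tol = mz_value * tol_ppm * 1e-6
        lo = int(np.searchsorted(self._mzs, mz_value - tol, side="left"))
        hi = int(np.searchsorted(self._mzs, mz_value + tol, side="right"))
        return self.entries[lo:hi]


def _variable_states(
    params: SearchParams, n_u: int, heavy: bool
) -> List[Tuple[int, Tuple[Tuple[str, int], ...], int]]:
    """(n_methyl, var_mods, n_ce) states to enumerate for one fragment."""
    if heavy:
        methyl_counts: Sequence[int] = (0,)
        var_ranges: List[Tuple[str, Sequence[int]]] = []
    else:
        methyl_counts = range(params.max_variable_methyl + 1)
        var_ranges = [(code, range(mx + 1)) for code, mx in params.variable_mods]
    ce_counts = range(min(params.max_ce, n_u) + 1) if params.enable_ce else (0,)
    states = []
    for n_methyl in methyl_counts:
        var_combos = itertools.product(*(rng for _, rng in var_ranges)) if var_ranges else [()]
        for combo in var_combos:
            var = tuple(
                (code, k) for (code, _), k in zip(var_ranges, combo) if k > 0
            )
            for n_ce in ce_counts:
                states.append((n_methyl, var, n_ce))
    return states


def build_index(
    digest: Sequence[Fragment],
    label: LabelScheme,
    params: SearchParams,
    heavy_digest: Optional[Sequence[Fragment]] = None,
) -> TheoreticalIndex:
    """Build the light+heavy theoretical ion index for a digest.

    ``heavy_digest`` lets the reference transcript differ in terminal
    chemistry (its 5'-end fragment carries the in-vitro 5'-triphosphate);
    by default the same fragments are used for both channels.
    """
    if not digest:
        raise ValueError("digest must be non-empty")
    entries: List[IndexEntry] = []
    channels = [(False, digest, LABEL_SCHEMES["none"])]
    if not label.is_null:
        channels.append((True, heavy_digest if heavy_digest is not None else digest, label))
    for is_heavy, fragments, channel_label in channels:
        for frag in fragments:
            n_u = frag.sequence.count("U")
            for n_methyl, var, n_ce in _variable_states(params, n_u, is_heavy):
                extra = n_methyl * METHYL
                for code, k in var:
                    extra = extra + k * MODIFICATIONS[code].delta
                try:
                    neutral = neutral_mass(
                        frag, channel_label, n_cyanoethyl=n_ce, extra=extra
                    )
                except ValueError:
                    continue
                for z in params.charges_for(neutral):
                    entries.append(
                        IndexEntry(
                            fragment=frag,
                            label_name=channel_label.name,
                            is_heavy=is_heavy,
                            n_methyl=n_methyl,
                            var_mods=var,
                            n_ce=n_ce,
                            charge=z,
                            neutral=neutral,
                            mz=mz(neutral, z),
                        )
                    )
    return TheoreticalIndex(entries, label, params)


@dataclass(frozen=True)
class Match:
    """An observed feature matched to an index entry within tolerance.

    ``isomer_ambiguous`` marks light matches whose fragment contains uridine:
    the mass alone cannot exclude that some U is pseudouridine (mass-silent),
    so identity as un- vs psi-modified awaits retention-time or
    cyanoethylation evidence.
    """

    feature: Feature
    entry: IndexEntry
    ppm: float

    @property
    def isomer_ambiguous(self) -> bool:
        return (not self.entry.is_heavy) and "U" in self.entry.fragment.sequence


def match_features(
    features: Sequence[Feature], index: TheoreticalIndex, params: SearchParams
) -> List[Match]:
    """All (feature, entry) matches within the precursor ppm tolerance.

    A feature may match several entries (isobaric fragments); per feature,
    matches are ordered by |ppm|.
    """
    matches: List[Match] = []
    for feat in features:
        hits = []
        for entry in index.query(feat.mz, params.ms1_tol_ppm):
            if entry.charge != feat.charge:
                continue
            ppm = (feat.mz - entry.mz) / entry.mz * 1e6
            hits.append(Match(feature=feat, entry=entry, ppm=ppm))
        hits.sort(key=lambda m: (abs(m.ppm), m.entry.identity))
        matches.extend(hits)
    return matches


@dataclass(frozen=True)
class FeaturePair:
    """A light feature coupled to its heavy (reference) partner."""

    light: Feature
    heavy: Feature
    light_entry: IndexEntry
    heavy_entry: IndexEntry
    expected_delta: float
    rt_shift: float
    co_eluting: bool
    ambiguous: bool = False

    @property
    def identity(self) -> Tuple[str, int, int]:
        return self.light_entry.identity

    @property
    def charge(self) -> int:
        return self.light_entry.charge

    @property
    def ratio(self) -> float:
        """Light/heavy intensity ratio."""
        return self.light.intensity / self.heavy.intensity


@dataclass
class PairingResult:
    pairs: List[FeaturePair] = field(default_factory=list)
    orphan_light: List[Match] = field(default_factory=list)
    orphan_heavy: List[Match] = field(default_factory=list)


def pair_light_heavy(
    matches: Sequence[Match], params: SearchParams
) -> PairingResult:
    """Pair light and heavy matches of the same fragment identity and charge.

    The heavy partner is always the *plain* (unmodified, un-derivatized)
    reference species; a light species carrying extra mass (variable methyl,
    CE) or an rt shift still pairs with that reference, which is exactly how
    modified species are discovered.  The pair is ``co_eluting`` when the rt
    shift is inside the co-elution window.  Orphans are reported, not
    dropped.
    """
    groups: Dict[tuple, Dict[str, List[Match]]] = {}
    feature_identities: Dict[int, set] = {}
    for m in matches:
        key = (
            m.entry.identity,
            m.entry.charge,
            m.feature.run_id,
            m.feature.replicate,
        )
        side = "heavy" if m.entry.is_heavy else "light"
        groups.setdefault(key, {"light": [], "heavy": []})[side].append(m)
        feature_identities.setdefault(id(m.feature), set()).add(m.entry.identity)

    result = PairingResult()
    for key in sorted(groups, key=str):
        group = groups[key]
        heavies = [m for m in group["heavy"] if m.entry.is_plain]
        lights = group["light"]
        if not heavies:
            result.orphan_light.extend(lights)
            continue
        if not lights:
            result.orphan_heavy.extend(heavies)
            continue
        for lm in lights:
            hm = min(heavies, key=lambda m: abs(m.feature.rt - lm.feature.rt))
            rt_shift = lm.feature.rt - hm.feature.rt
            result.pairs.append(
                FeaturePair(
                    light=lm.feature,
                    heavy=hm.feature,
                    light_entry=lm.entry,
                    heavy_entry=hm.entry,
                    expected_delta=hm.entry.neutral - lm.entry.neutral,
                    rt_shift=rt_shift,
                    co_eluting=abs(rt_shift) <= params.rt_pair_window,
                    ambiguous=(
                        len(feature_identities[id(lm.feature)]) > 1
                        or len(feature_identities[id(hm.feature)]) > 1
                    ),
                )
            )
    return result


# ---------------------------------------------------------------------------
# MS/MS localization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalizationCandidate:
    """A hypothesized fully localized species for an observed feature.

    ``sites``: tuple of (fragment-local position, modification code)
    hypothesized beyond the fragment's fixed modifications.
    """

    fragment: Fragment  # carries the hypothesized mods
    sites: Tuple[Tuple[int, str], ...]
    label: LabelScheme = LABEL_SCHEMES["none"]

    @property
    def global_sites(self) -> Tuple[Tuple[int, str], ...]:
        return tuple(
            (self.fragment.start + pos - 1, code) for pos, code in self.sites
        )


def _place(fragment: Fragment, placements: Sequence[Tuple[int, str]]) -> Optional[Fragment]:
    """Fragment with extra (local position, code) mods; None if invalid."""
    mods = {pos: list(codes) for pos, codes in fragment.local_mods().items()}
    for pos, code in placements:
        base = fragment.sequence[pos - 1]
        if MODIFICATIONS[code].target_base != base:
            return None
        if code in mods.get(pos, ()):  # already placed
            return None
        mods.setdefault(pos, []).append(code)
    global_mods = {
        fragment.start + pos - 1: tuple(codes) for pos, codes in mods.items()
    }
    return fragment.with_mods(global_mods)


def candidates_for_entry(entry: IndexEntry) -> List[LocalizationCandidate]:
    """Enumerate localized placements consistent with an index entry's
    unlocalized variable-mod state.

    Methyl hypotheses cover every residue twice (2'-O-ribose, canonical
    base-methyl); two methyls may also land on one adenosine as a base
    dimethyl.  CE hypotheses cover the U/psi residues.  Specific variable
    mods (e.g. ac4C) cover residues of their target base.
    """
    frag = entry.fragment
    n = len(frag.sequence)
    label = LABEL_SCHEMES[entry.label_name]

    single_methyls: List[Tuple[int, str]] = []
    for pos in range(1, n + 1):
        base = frag.sequence[pos - 1]
        single_methyls.append((pos, CANONICAL_RIBOSE_METHYL[base]))
        single_methyls.append((pos, CANONICAL_BASE_METHYL[base]))

    methyl_sets: List[Tuple[Tuple[int, str], ...]]
    if entry.n_methyl == 0:
        methyl_sets = [()]
    elif entry.n_methyl == 1:
        methyl_sets = [(m,) for m in single_methyls]
    elif entry.n_methyl == 2:
        methyl_sets = [
            tuple(pair) for pair in itertools.combinations(single_methyls, 2)
            if pair[0][0] != pair[1][0]
        ]
        methyl_sets += [
            ((pos, "m62A"),)
            for pos in range(1, n + 1)
            if frag.sequence[pos - 1] == "A"
        ]
    else:  # >2 methyls: positions only, ribose placement as representative
        methyl_sets = [
            tuple(combo)
            for combo in itertools.combinations(single_methyls, entry.n_methyl)
            if len({p for p, _ in combo}) == entry.n_methyl
        ]

    var_sets: List[Tuple[Tuple[int, str], ...]] = [()]
    for code, count in entry.var_mods:
        target = MODIFICATIONS[code].target_base
        positions = [i for i in range(1, n + 1) if frag.sequence[i - 1] == target]
        placements = [
            tuple((p, code) for p in combo)
            for combo in itertools.combinations(positions, count)
        ]
        var_sets = [vs + pl for vs in var_sets for pl in placements]

    u_positions = [i for i in range(1, n + 1) if frag.sequence[i - 1] == "U"]
    if entry.n_ce == 0:
        ce_sets: List[Tuple[Tuple[int, str], ...]] = [()]
    else:
        ce_sets = [
            tuple((p, "ce") for p in combo)
            for combo in itertools.combinations(u_positions, entry.n_ce)
        ]

    candidates: List[LocalizationCandidate] = []
    for msites in methyl_sets:
        for vsites in var_sets:
            for csites in ce_sets:
                sites = tuple(sorted(msites + vsites + csites))
                placed = _place(frag, sites)
                if placed is not None:
                    candidates.append(
                        LocalizationCandidate(fragment=placed, sites=sites, label=label)
                    )
    return candidates


def _match_peak(peaks_mz: np.ndarray, target: float, tol_ppm: float) -> bool:
    if peaks_mz.size == 0:
        return False
    idx = np.searchsorted(peaks_mz, target)
    for j in (idx - 1, idx):
        if 0 <= j < peaks_mz.size and abs(peaks_mz[j] - target) <= target * tol_ppm * 1e-6:
            return True
    return False


@dataclass(frozen=True)
class LocalizationResult:
    candidate: LocalizationCandidate
    score: float
    matched_fraction: float
    base_loss_consistent: Optional[bool]


def localize_msms(
    feature: Feature,
    candidates: Sequence[LocalizationCandidate],
    params: SearchParams,
) -> List[LocalizationResult]:
    """Rank candidate site placements against an MS/MS spectrum.

    Score = fraction of the theoretical c/y/w/a-B ladder matched at the
    MS/MS ppm tolerance, plus a small bonus (``base_loss_weight``) when the
    precursor base-loss diagnostic agrees with the hypothesized placement
    (a base-placed methyl predicts loss of the methylated base from the
    precursor; a ribose methyl predicts its absence).  Ranking is
    deterministic: ties break on the candidate's site tuple.
    """
    if feature.msms is None or len(feature.msms) == 0:
        raise ValueError("feature carries no MS/MS peak list")
    peaks = np.sort(np.array([p[0] for p in feature.msms], dtype=float))
    results: List[LocalizationResult] = []
    for cand in candidates:
        if len(cand.fragment.sequence) < 2:
            continue
        ladder = ion_ladder(cand.fragment, cand.label)
        targets = ladder.all_mz()
        n_hit = sum(_match_peak(peaks, t, params.ms2_tol_ppm) for t in targets)
        frac = n_hit / len(targets) if targets else 0.0

        consistent: Optional[bool] = None
        base_methyl_sites = [
            (pos, code)
            for pos, code in cand.sites
            if MODIFICATIONS[code].placement == "base"
            and MODIFICATIONS[code].mod_class in ("base_methyl", "base_dimethyl")
        ]
        ribose_methyl_sites = [
            (pos, code)
            for pos, code in cand.sites
            if MODIFICATIONS[code].placement == "ribose"
        ]
        if base_methyl_sites or ribose_methyl_sites:
            losses = residue_base_losses(cand.fragment, cand.label)
            precursor = ladder.precursor_neutral
            z = feature.charge
            found_methylated_loss = False
            for pos in range(1, len(cand.fragment.sequence) + 1):
                local = cand.fragment.local_mods().get(pos, ())
                methylated = any(
                    MODIFICATIONS[c].placement == "base"
                    and MODIFICATIONS[c].mod_class
                    in ("base_methyl", "base_dimethyl")
                    for c in local
                )
                if methylated and _match_peak(
                    peaks, mz(precursor - losses[pos], z), params.ms2_tol_ppm
                ):
                    found_methylated_loss = True
            if base_methyl_sites:
                consistent = found_methylated_loss
            else:
                consistent = not found_methylated_loss
        score = frac + (params.base_loss_weight if consistent else 0.0)
        results.append(
            LocalizationResult(
                candidate=cand,
                score=score,
                matched_fraction=frac,
                base_loss_consistent=consistent,
            )
        )
    results.sort(key=lambda r: (-r.score, r.candidate.sites))
    return results
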