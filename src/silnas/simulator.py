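"""Synthetic LC-MS data generator for the light + heavy workflow.

The generator emulates what the isotope-dilution experiment measures: a
cellular RNA carrying partial modifications, mixed 1:1 with an unmodified,
fully 13C-base-labeled in-vitro transcript, digested and observed as LC-MS
features.  For every digest fragment it emits

* the heavy reference species at the labeled mass (relative intensity 1),
* light species split over modification-occupancy patterns: a site modified
  at fraction f contributes its modified form with weight f and its
  unmodified form with weight 1-f (independent across sites), and
* missed-cleavage variants at a fixed relative abundance.

Cleavage-blocking 2'-O-methyls are handled at the fragmentation level: a
partially methylated site yields the cut fragments with weight 1-f and the
merged (blocked) fragment, carrying the methyl, with weight f — exactly the
signature by which such sites are discovered.

Noise model: multiplicative lognormal intensity noise (CV), Gaussian ppm
mass error, Gaussian retention-time jitter; retention-time *shifts* for
modified species are deterministic per modification class.  With a fixed
seed the output is bit-identical.
"""

from __future__ import annotations

import itertools
import json
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import PtmMap, PtmSite
from .chemistry import LABEL_SCHEMES, MODIFICATIONS, LabelScheme
from .digestion import AnnotatedSequence, DigestParams, Fragment, cleavage_sites
from .mass_model import charge_states, ion_ladder, mz, neutral_mass, residue_base_losses
from .quantification import CEParams

__all__ = [
    "SimConfig",
    "SimSpecies",
    "SimResult",
    "simulate",
    "simulate_ce",
    "simulate_calibration",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "run_id",
    "replicate",
    "mz",
    "charge",
    "rt_sec",
    "intensity",
    "msms",
    "species_id",
    "parent_id",
    "start",
    "end",
    "is_heavy",
    "mods",
    "missed_cleavages",
]

#: Default retention-time shifts (seconds) per modification class, relative
#: to the unmodified fragment.  Signs follow the observed behaviour that a
#: pseudouridylated fragment can elute earlier and a methylated one later;
#: magnitudes are plausible for a 60-min gradient and are configurable.
DEFAULT_RT_OFFSETS: Dict[str, float] = {
    "pseudouridine": -48.0,
    "Nm": 90.0,
    "base_methyl": 60.0,
    "base_dimethyl": 75.0,
    "acetyl": 45.0,
    "composite": 75.0,
    "adduct": 60.0,  # per cyanoethyl group
}


@dataclass
class SimConfig:
    """Ground truth and instrument model for one simulated experiment."""

    parents: Sequence[AnnotatedSequence]
    fractions: Mapping[Tuple[str, int], float] = field(default_factory=dict)
    label: str = "heavy-g"
    enzymes: Sequence[str] = ("T1",)
    #: optional per-enzyme label override (e.g. heavy-cu for an RNase A
    #: digest, so every pyrimidine-terminated product carries label)
    labels: Mapping[str, str] = field(default_factory=dict)
    intensity_cv: float = 0.05
    mass_error_ppm_sd: float = 3.0
    rt_jitter_sd: float = 2.0
    rt_offsets: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RT_OFFSETS))
    missed_cleavage_fraction: float = 0.1
    base_intensity: float = 1e6
    min_rel_intensity: float = 1e-5
    #: CE states are enumerated exactly up to this many adducts per species;
    #: the residual probability mass of higher states is lumped into one
    #: species at ce_max_adducts+1 so total intensity stays conserved
    ce_max_adducts: int = 2
    replicates: int = 1
    include_msms: bool = False
    gradient_window: Tuple[float, float] = (360.0, 3240.0)
    light_five_prime: str = "p"  # mature cellular RNA: 5'-monophosphate
    heavy_five_prime: str = "ppp"  # in-vitro transcript: 5'-triphosphate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_cv < 0:
            raise ValueError("intensity CV must be >= 0")
        for (pid, pos), f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction at {pid}:{pos} outside [0, 1]")
        ids = [p.id for p in self.parents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate parent ids")

    def fraction(self, parent_id: str, pos: int) -> float:
        return float(self.fractions.get((parent_id, pos), 1.0))

    def label_for(self, enzyme: str) -> str:
        return self.labels.get(enzyme, self.label)

    def truth_map(self) -> PtmMap:
        sites = []
        for parent in self.parents:
            for pos, codes in sorted(parent.mods.items()):
                for code in codes:
                    sites.append(
                        PtmSite(
                            parent_id=parent.id,
                            position=pos,
                            mod_code=code,
                            f=self.fraction(parent.id, pos),
                        )
                    )
        return PtmMap(sites=sites)


@dataclass(frozen=True)
class SimSpecies:
    """One distinct molecular species entering the LC-MS feature list."""

    species_id: int
    fragment: Fragment
    enzyme: str
    is_heavy: bool
    rel_intensity: float
    rt: float
    n_ce: int = 0


@dataclass
class SimResult:
    config: SimConfig
    species: List[SimSpecies]
    features: pd.DataFrame
    truth: PtmMap


def _base_rt(identity: Tuple[str, int, int], window: Tuple[float, float]) -> float:
    """Deterministic per-fragment elution position on the gradient."""
    key = f"{identity[0]}:{identity[1]}-{identity[2]}".encode()
    frac = zlib.crc32(key) / 0xFFFFFFFF
    lo, hi = window
    return lo + frac * (hi - lo)


def _mod_rt_offset(fragment: Fragment, offsets: Mapping[str, float]) -> float:
    shift = 0.0
    for _pos, codes in fragment.mods:
        for code in codes:
            shift += offsets.get(MODIFICATIONS[code].mod_class, 0.0)
    return shift


def _subset_weights(
    sites: Sequence[int], fractions: Mapping[int, float]
) -> Iterable[Tuple[Tuple[int, ...], float]]:
    """(present-subset, probability) over independent per-site occupancy."""
    if not sites:
        yield (), 1.0
        return
    for mask in itertools.product((False, True), repeat=len(sites)):
        weight = 1.0
        present = []
        for site, on in zip(sites, mask):
            f = fractions[site]
            weight *= f if on else (1.0 - f)
            if on:
                present.append(site)
        if weight > 0.0:
            yield tuple(present), weight


def _pattern_fragments(
    parent: AnnotatedSequence,
    enzyme: str,
    config: SimConfig,
) -> List[Tuple[Fragment, float]]:
    """Light digest species with occupancy weights (before missed cleavage).

    Enumerates patterns of cleavage-blocking sites region by region (sites
    between two never-blocked cuts interact, distant ones do not), then
    splits each concrete fragment over subsets of its remaining
    (non-blocking for this enzyme) modification sites.
    """
    n = len(parent)
    plain = AnnotatedSequence(
        id=parent.id,
        residues=parent.residues,
        five_prime=parent.five_prime,
        three_prime=parent.three_prime,
    )
    all_sites = cleavage_sites(plain, enzyme)
    blocking = [
        pos
        for pos in all_sites
        if any(
            MODIFICATIONS[c].blocks_cleavage_3prime
            for c in parent.mods.get(pos, ())
        )
    ]
    blocking_set = set(blocking)
    fixed_cuts = [pos for pos in all_sites if pos not in blocking_set]
    fractions = {pos: config.fraction(parent.id, pos) for pos in blocking}

    # regions between consecutive always-cut boundaries
    bounds = [0] + fixed_cuts + [n]
    weighted: List[Tuple[Fragment, float]] = []
    for lo, hi in zip(bounds, bounds[1:]):
        region_block = [p for p in blocking if lo < p < hi]
        if len(region_block) > 16:
            raise ValueError(
                "too many partially blocking sites in one region to enumerate"
            )
        for present, weight in _subset_weights(region_block, fractions):
            # cuts inside the region are the blocked sites NOT present
            cuts = sorted(set(region_block) - set(present))
            seg_bounds = [lo] + cuts + [hi]
            frags = list(zip(seg_bounds, seg_bounds[1:]))
            merged = [
                (a[0], b[1])
                for a, b in zip(frags, frags[1:])
            ]
            for start0, end in frags + merged:
                missed = 0 if (start0, end) in frags else 1
                w = weight * (
                    config.missed_cleavage_fraction if missed else 1.0
                )
                weighted.append(
                    (
                        _make_light_fragment(
                            parent, start0 + 1, end, present, config, missed
                        ),
                        w,
                    )
                )
    # 1-missed species spanning an always-cut boundary (between regions)
    weighted.extend(
        _cross_boundary_missed(parent, enzyme, config, fixed_cuts, blocking, fractions)
    )
    return weighted


def _make_light_fragment(
    parent: AnnotatedSequence,
    start: int,
    end: int,
    blocked_present: Sequence[int],
    config: SimConfig,
    missed: int,
) -> Fragment:
    """Skeleton fragment carrying only the forced (blocking) mods; the
    remaining site splitting happens in :func:`_split_variable_sites`."""
    mods = {
        pos: parent.mods[pos]
        for pos in blocked_present
        if start <= pos <= end
    }
    return Fragment(
        parent_id=parent.id,
        start=start,
        end=end,
        sequence=parent.residues[start - 1 : end],
        mods=tuple(sorted(mods.items())),
        missed_cleavages=missed,
        five_prime=(config.light_five_prime if start == 1 else "OH"),
        three_prime=(parent.three_prime if end == len(parent) else "p"),
    )


def _cross_boundary_missed(
    parent: AnnotatedSequence,
    enzyme: str,
    config: SimConfig,
    fixed_cuts: Sequence[int],
    blocking: Sequence[int],
    fractions: Mapping[int, float],
) -> List[Tuple[Fragment, float]]:
    """1-missed fragments spanning one *always-cut* boundary.

    Adjacent 0-missed neighbours on each side are taken at the most likely
    blocking pattern only (all blocked sites cut with weight 1-f, merged
    variants already covered inside regions); this keeps enumeration linear
    while still producing the dominant missed species.
    """
    n = len(parent)
    blocking_set = set(blocking)
    out: List[Tuple[Fragment, float]] = []
    all_bounds = [0] + sorted(set(list(fixed_cuts) + list(blocking))) + [n]
    for i in range(1, len(all_bounds) - 1):
        cut = all_bounds[i]
        if cut not in fixed_cuts:
            continue
        start = all_bounds[i - 1] + 1
        end = all_bounds[i + 1]
        weight = config.missed_cleavage_fraction
        # neighbouring bounds that are blocking sites must be *cut* here
        for neighbour in (all_bounds[i - 1], all_bounds[i + 1]):
            if neighbour in blocking_set:
                weight *= 1.0 - fractions[neighbour]
        out.append(
            (_make_light_fragment(parent, start, end, (), config, 1), weight)
        )
    return out


def _split_variable_sites(
    fragment: Fragment,
    weight: float,
    parent: AnnotatedSequence,
    pattern_sites: frozenset,
    config: SimConfig,
) -> Iterable[Tuple[Fragment, float]]:
    """Split a fragment over occupancy subsets of its remaining sites.

    ``pattern_sites`` (cleavage-blocking sites of the current enzyme) were
    already decided by the fragmentation-pattern enumeration: present ones
    are in the fragment's forced mods, absent ones must stay absent — they
    are excluded here so occupancy is not double-counted.
    """
    forced = {pos for pos, _ in fragment.mods}
    variable = [
        pos
        for pos in sorted(parent.mods)
        if fragment.start <= pos <= fragment.end
        and pos not in forced
        and pos not in pattern_sites
    ]
    fractions = {pos: config.fraction(parent.id, pos) for pos in variable}
    for present, w in _subset_weights(variable, fractions):
        mods = dict(fragment.mods)
        for pos in present:
            mods[pos] = parent.mods[pos]
        yield fragment.with_mods(mods), weight * w


_LADDER_CACHE: Dict[tuple, object] = {}


def _cached_ladder(fragment: Fragment, label: LabelScheme):
    key = (fragment, label.name)
    ladder = _LADDER_CACHE.get(key)
    if ladder is None:
        if len(_LADDER_CACHE) > 4096:
            _LADDER_CACHE.clear()
        ladder = ion_ladder(fragment, label)
        _LADDER_CACHE[key] = ladder
    return ladder


def _msms_payload(
    fragment: Fragment, label: LabelScheme, charge: int
) -> str:
    """JSON peak list: full c/y/w/a-B ladder plus precursor base-loss peaks."""
    ladder = _cached_ladder(fragment, label)
    peaks = [(m, 1.0) for m in ladder.all_mz()]
    losses = residue_base_losses(fragment, label)
    seen = set()
    for pos, loss in losses.items():
        key = round(loss, 6)
        if key in seen:
            continue
        seen.add(key)
        peaks.append((mz(ladder.precursor_neutral - loss, charge), 0.5))
    peaks.sort()
    return json.dumps([[round(m, 6), i] for m, i in peaks])


def _collapse(
    weighted: Iterable[Tuple[Fragment, float]]
) -> List[Tuple[Fragment, float]]:
    acc: Dict[tuple, Tuple[Fragment, float]] = {}
    for frag, w in weighted:
        key = (frag.identity, frag.species_key, frag.missed_cleavages)
        if key in acc:
            prev_frag, prev_w = acc[key]
            acc[key] = (prev_frag, prev_w + w)
        else:
            acc[key] = (frag, w)
    return [acc[k] for k in sorted(acc, key=str)]


def build_species(config: SimConfig) -> List[SimSpecies]:
    """Enumerate all light and heavy species with noise-free intensities."""
    species: List[SimSpecies] = []
    sid = 0
    for enzyme in config.enzymes:
        for parent in config.parents:
            # light channel: occupancy-pattern digest of the annotated RNA
            plain_parent = AnnotatedSequence(
                id=parent.id,
                residues=parent.residues,
                five_prime=parent.five_prime,
                three_prime=parent.three_prime,
            )
            pattern_sites = frozenset(
                pos
                for pos in cleavage_sites(plain_parent, enzyme)
                if any(
                    MODIFICATIONS[c].blocks_cleavage_3prime
                    for c in parent.mods.get(pos, ())
                )
            )
            weighted: List[Tuple[Fragment, float]] = []
            for frag, w in _pattern_fragments(parent, enzyme, config):
                weighted.extend(
                    _split_variable_sites(frag, w, parent, pattern_sites, config)
                )
            for frag, w in _collapse(weighted):
                if w < config.min_rel_intensity:
                    continue
                rt = _base_rt(frag.identity, config.gradient_window)
                rt += _mod_rt_offset(frag, config.rt_offsets)
                species.append(
                    SimSpecies(sid, frag, enzyme, False, w, rt)
                )
                sid += 1
            # heavy channel: plain digest of the unmodified reference
            heavy_parent = AnnotatedSequence(
                id=parent.id,
                residues=parent.residues,
                five_prime=config.heavy_five_prime,
                three_prime=parent.three_prime,
            )
            for frag in sorted(
                (
                    f
                    for f in _digest_plain(heavy_parent, enzyme)
                ),
                key=lambda f: (f.start, f.end),
            ):
                w = (
                    config.missed_cleavage_fraction
                    if frag.missed_cleavages
                    else 1.0
                )
                if w < config.min_rel_intensity:
                    continue
                rt = _base_rt(frag.identity, config.gradient_window)
                species.append(SimSpecies(sid, frag, enzyme, True, w, rt))
                sid += 1
    return species


def _digest_plain(parent: AnnotatedSequence, enzyme: str) -> List[Fragment]:
    from .digestion import digest

    return digest(parent, DigestParams(enzyme=enzyme, max_missed=1))


def _emit_features(
    species: Sequence[SimSpecies],
    config: SimConfig,
    rng: np.random.Generator,
    run_suffix: str,
) -> pd.DataFrame:
    sigma = (
        math.sqrt(math.log(1.0 + config.intensity_cv**2))
        if config.intensity_cv > 0
        else 0.0
    )
    rows = []
    for rep in range(config.replicates):
        for sp in species:
            label = LABEL_SCHEMES[config.label_for(sp.enzyme)]
            sp_label = label if sp.is_heavy else LABEL_SCHEMES["none"]
            neutral = neutral_mass(sp.fragment, sp_label)
            intensity0 = sp.rel_intensity * config.base_intensity
            modded = bool(sp.fragment.mods) or sp.n_ce > 0
            for z in charge_states(neutral):
                intensity = intensity0
                if sigma:
                    intensity *= math.exp(rng.normal(0.0, sigma))
                mz_val = mz(neutral, z)
                if config.mass_error_ppm_sd > 0:
                    mz_val *= 1.0 + rng.normal(0.0, config.mass_error_ppm_sd * 1e-6)
                rt = sp.rt
                if config.rt_jitter_sd > 0:
                    rt += rng.normal(0.0, config.rt_jitter_sd)
                msms = None
                if config.include_msms and modded and not sp.is_heavy and len(
                    sp.fragment.sequence
                ) >= 2:
                    msms = _msms_payload(sp.fragment, sp_label, z)
                rows.append(
                    {
                        "run_id": f"{sp.enzyme}-{label.name}{run_suffix}",
                        "replicate": rep,
                        "mz": mz_val,
                        "charge": z,
                        "rt_sec": rt,
                        "intensity": intensity,
                        "msms": msms,
                        "species_id": sp.species_id,
                        "parent_id": sp.fragment.parent_id,
                        "start": sp.fragment.start,
                        "end": sp.fragment.end,
                        "is_heavy": sp.is_heavy,
                        "mods": json.dumps(
                            [[p, list(c)] for p, c in sp.fragment.mods]
                        ),
                        "missed_cleavages": sp.fragment.missed_cleavages,
                    }
                )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def simulate(config: SimConfig) -> SimResult:
    """Simulate replicate light+heavy feature tables and the truth map."""
    rng = np.random.default_rng(config.seed)
    species = build_species(config)
    features = _emit_features(species, config, rng, run_suffix="")
    return SimResult(
        config=config,
        species=species,
        features=features,
        truth=config.truth_map(),
    )


# ---------------------------------------------------------------------------
# Cyanoethylation run
# ---------------------------------------------------------------------------


def _ce_split(
    sp: SimSpecies, params: CEParams, config: SimConfig
) -> List[SimSpecies]:
    """Redistribute one species over cyanoethyl adduct counts.

    Each U-type residue reacts independently: probability
    ``efficiency_psi`` if the residue is pseudouridine in this species,
    ``efficiency_u`` otherwise.  Same-count states are isobaric, so the
    count distribution is computed exactly (Poisson-binomial) and one
    species per count is emitted, carrying the *modal* placement (most
    reactive residues first) for its MS/MS; counts above
    ``ce_max_adducts`` are lumped into one species so total intensity is
    conserved.
    """
    frag = sp.fragment
    local = frag.local_mods()
    u_positions = [
        i
        for i, b in enumerate(frag.sequence, start=1)
        if b == "U" and "ce" not in local.get(i, ())
    ]
    if not u_positions:
        return [sp]
    eff = {
        i: (
            params.efficiency_psi
            if "Y" in local.get(i, ())
            else params.efficiency_u
        )
        for i in u_positions
    }
    # exact adduct-count distribution (Poisson-binomial convolution)
    probs = [1.0]
    for i in u_positions:
        p = eff[i]
        probs = [
            (probs[c] if c < len(probs) else 0.0) * (1.0 - p)
            + (probs[c - 1] * p if c >= 1 else 0.0)
            for c in range(len(probs) + 1)
        ]
    cap = min(len(u_positions), config.ce_max_adducts)
    by_reactivity = sorted(u_positions, key=lambda i: (-eff[i], i))

    def _with_ce(count: int) -> Fragment:
        mods = {pos: list(codes) for pos, codes in local.items()}
        for i in by_reactivity[:count]:
            mods.setdefault(i, []).append("ce")
        global_mods = {
            frag.start + pos - 1: tuple(codes) for pos, codes in mods.items()
        }
        return frag.with_mods(global_mods)

    out: List[SimSpecies] = []
    for count in range(cap + 1):
        weight = probs[count]
        if count == cap and cap < len(u_positions):
            pass  # residual handled below
        if weight * sp.rel_intensity < config.min_rel_intensity:
            continue
        if count == 0:
            out.append(replace(sp, rel_intensity=sp.rel_intensity * weight))
            continue
        out.append(
            replace(
                sp,
                fragment=_with_ce(count),
                rel_intensity=sp.rel_intensity * weight,
                n_ce=count,
                rt=sp.rt + count * config.rt_offsets.get("adduct", 60.0),
            )
        )
    residual = sum(probs[cap + 1 :])
    if residual * sp.rel_intensity >= config.min_rel_intensity and cap < len(
        u_positions
    ):
        out.append(
            replace(
                sp,
                fragment=_with_ce(cap + 1),
                rel_intensity=sp.rel_intensity * residual,
                n_ce=cap + 1,
                rt=sp.rt + (cap + 1) * config.rt_offsets.get("adduct", 60.0),
            )
        )
    return out


def simulate_ce(
    result: SimResult,
    params: Optional[CEParams] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Post-cyanoethylation feature table for a simulated experiment.

    With both efficiencies zero this is the identity (up to the independent
    noise draw).
    """
    params = params or CEParams()
    config = result.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    ce_species: List[SimSpecies] = []
    for sp in result.species:
        ce_species.extend(_ce_split(sp, params, config))
    return _emit_features(ce_species, config, rng, run_suffix="-ce")


def design_ground_truth(
    n_sites: int = 30,
    seed: int = 7,
    parent_id: str = "synthetic-rRNA",
    max_attempts: int = 50,
    site_plan: Optional[Sequence[str]] = None,
    palette: Optional[Sequence[float]] = None,
    spacing: int = 0,
    segment_length: Tuple[int, int] = (7, 18),
) -> Tuple[AnnotatedSequence, Dict[Tuple[str, int], float]]:
    """Design a synthetic rRNA-like parent and PTM truth for validation runs.

    The parent is built from RNase-T1-sized segments (one G every 7-14 nt)
    and sites are placed so that the map is *identifiable* from a T1
    digest, the way a validation experiment would be designed:

    * at most one modified site per digest fragment,
    * the fragment downstream of a cleavage-blocking Gm is left unmodified
      (its light signal is consumed by the merged fragment),
    * psi-bearing fragments keep a modest uridine count so cyanoethylation
      states remain enumerable,
    * sites land only on fragments free of exact-mass confounds: fragments
      whose species coincide in m/z with another fragment's (anagrammatic
      compositions in the extreme) are real and unavoidable at this scale,
      but the pipeline flags them as ambiguous, so a validation design
      keeps its ground truth off them (verified after placement; the
      sequence is re-drawn otherwise).

    Site classes follow the composition seen in eukaryotic rRNA maps:
    pseudouridine and 2'-O-methyls dominate, with a few base methyls,
    dimethyls and acetylations.  Fractions cycle through a fixed palette
    spanning partial to complete modification.
    """
    from .digestion import digest as _digest

    rng = np.random.default_rng(seed)
    default_floor = palette is None
    fractions_palette = list(palette) if palette is not None else [
        1.0, 0.997, 0.9, 0.76, 0.68, 0.44,
    ]
    for _attempt in range(max_attempts):
        segments = []
        n_segments = max(50, n_sites + 25)
        for _ in range(n_segments):
            length = int(rng.integers(segment_length[0], segment_length[1] + 1))
            body = "".join(rng.choice(list("ACU"), size=length - 1))
            segments.append(body + "G")
        residues = "".join(segments) + "AAC"
        plain = AnnotatedSequence(id=parent_id, residues=residues)
        frags = [
            f
            for f in _digest(plain, DigestParams(enzyme="T1", max_missed=0))
            if f.missed_cleavages == 0
        ]
        interior = frags[1:-1]
        if len(interior) < n_sites + 10:
            continue

        # fragments entangled in exact-mass confounds are off-limits
        confounded = _colliding_identities(plain, {}, tol_ppm=5.0)
        blocked_idx = {
            i
            for i, frag in enumerate(interior)
            for (_pid, s, e) in confounded
            if frag.start <= e and s <= frag.end
        }

        # class plan: 10 psi, 7 Nm internal, 3 Gm (blocking), 6 base methyl,
        # 2 base dimethyl, 2 acetyl for the default 30; scaled otherwise
        if site_plan is not None:
            plan: List[str] = list(site_plan)
        else:
            plan = (
                ["Y"] * 10 + ["Nm"] * 7 + ["Gm"] * 3 + ["mB"] * 6
                + ["m62A"] * 2 + ["ac4C"] * 2
            )
            plan = plan[:n_sites]
        order = rng.permutation(len(interior))
        used: set = set()
        reserved: set = set()  # fragments downstream of a blocking Gm
        assigned_kind: Dict[int, str] = {}
        mods: Dict[int, Tuple[str, ...]] = {}
        fractions: Dict[Tuple[str, int], float] = {}
        f_cycle = 0
        queue = list(plan)
        # methyl-equivalents (CH2 count) per site class: a missed-cleavage
        # merge of two site-bearing fragments must stay inside the search
        # space (at most two variable methyls, one acetyl per fragment)
        methyl_eq = {"Y": 0, "Nm": 1, "Gm": 1, "mB": 1, "m62A": 2, "ac4C": 0}
        for idx in order:
            if not queue:
                break
            if idx in used or idx in reserved or idx in blocked_idx:
                continue
            if spacing and any(
                (idx + d) in used for d in range(-spacing, spacing + 1) if d
            ):
                continue
            frag = interior[idx]
            kind = queue[0]
            neighbour_clash = False
            for nb in (idx - 1, idx + 1):
                nk = assigned_kind.get(nb)
                if nk is None:
                    continue
                if methyl_eq[kind] + methyl_eq[nk] > 2 or (
                    kind == "ac4C" and nk == "ac4C"
                ):
                    neighbour_clash = True
            if neighbour_clash:
                continue
            if kind == "Gm" and (
                (idx + 1) in used
                or (idx + 1) in reserved
                or (idx + 1) in blocked_idx
            ):
                continue  # the merged span must stay single-site and clean
            pos = _pick_site(frag, kind, rng)
            if pos is None:
                continue
            queue.pop(0)
            code = _site_code(frag, pos, kind)
            mods[pos] = (code,)
            f = fractions_palette[f_cycle % len(fractions_palette)]
            if code == "Y" and default_floor:
                f = max(f, 0.44)  # detectability floor for the CE contrast
            fractions[(parent_id, pos)] = f
            f_cycle += 1
            used.add(idx)
            assigned_kind[idx] = kind
            if kind == "Gm":
                reserved.add(idx + 1)  # downstream fragment joins the merged span
        if queue:
            continue
        parent = AnnotatedSequence(id=parent_id, residues=residues, mods=mods)
        # placement changed the species inventory: verify no confound
        # touches a site-bearing span
        confounded_final = _colliding_identities(parent, fractions, tol_ppm=5.0)
        site_positions = set(mods)
        if any(
            any(s <= pos <= e for pos in site_positions)
            for (_pid, s, e) in confounded_final
        ):
            continue
        return parent, fractions
    raise RuntimeError("could not design a collision-free ground truth")


def _pick_site(frag: Fragment, kind: str, rng: np.random.Generator) -> Optional[int]:
    seq = frag.sequence
    n = len(seq)
    if kind == "Y":
        n_u = seq.count("U")
        if not 1 <= n_u <= 6:
            return None
        choices = [i for i, b in enumerate(seq, 1) if b == "U"]
    elif kind == "Nm":
        choices = [i for i, b in enumerate(seq[: n - 1], 1) if b in "ACU"]
    elif kind == "Gm":
        choices = [n] if seq.endswith("G") else []
    elif kind == "mB":
        choices = list(range(1, n))  # any residue; G only at the end
        choices.append(n)
    elif kind == "m62A":
        choices = [i for i, b in enumerate(seq, 1) if b == "A"]
    elif kind == "ac4C":
        choices = [i for i, b in enumerate(seq, 1) if b == "C"]
    else:
        raise ValueError(kind)
    if not choices:
        return None
    local = int(rng.choice(choices))
    return frag.start + local - 1


def _site_code(frag: Fragment, global_pos: int, kind: str) -> str:
    base = frag.sequence[global_pos - frag.start]
    if kind == "Y":
        return "Y"
    if kind == "Nm":
        return {"A": "Am", "C": "Cm", "U": "Um"}[base]
    if kind == "Gm":
        return "Gm"
    if kind == "mB":
        return {"A": "m6A", "C": "m5C", "G": "m7G", "U": "m3U"}[base]
    if kind == "m62A":
        return "m62A"
    if kind == "ac4C":
        return "ac4C"
    raise ValueError(kind)


def _colliding_identities(
    parent: AnnotatedSequence,
    fractions: Mapping[Tuple[str, int], float],
    tol_ppm: float = 5.0,
) -> set:
    """Fragment identities whose simulated species coincide in m/z with a
    species of a *different* identity at matching charge.

    Species several ppm apart are separable by best-match ranking;
    species within ``tol_ppm`` (anagrammatic fragments in the extreme:
    identical base composition, hence identical mass) are genuinely
    confounded for MS1 pairing and are flagged ambiguous downstream.
    """
    config = SimConfig(
        parents=[parent],
        fractions=fractions,
        intensity_cv=0.0,
        mass_error_ppm_sd=0.0,
        rt_jitter_sd=0.0,
        replicates=1,
        seed=0,
    )
    species = build_species(config)
    by_charge: Dict[int, List[Tuple[float, Tuple[str, int, int]]]] = {}
    for sp in species:
        label = LABEL_SCHEMES[config.label_for(sp.enzyme)]
        sp_label = label if sp.is_heavy else LABEL_SCHEMES["none"]
        neutral = neutral_mass(sp.fragment, sp_label)
        for z in charge_states(neutral):
            by_charge.setdefault(z, []).append((mz(neutral, z), sp.fragment.identity))
    confounded: set = set()
    for z, vals in by_charge.items():
        vals.sort()
        for i, (m1, i1) in enumerate(vals):
            for m2, i2 in vals[i + 1 :]:
                if (m2 - m1) > m1 * tol_ppm * 1e-6:
                    break
                if i1 != i2:
                    confounded.add(i1)
                    confounded.add(i2)
    return confounded


def simulate_calibration(
    ratios: Sequence[float] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0),
    replicates: int = 4,
    cv: float = 0.05,
    seed: int = 0,
    base_intensity: float = 1e6,
) -> pd.DataFrame:
    """Heavy/light mixing series for the linearity validation.

    For each molar heavy:light ratio r, both channel intensities receive
    independent multiplicative lognormal noise at the given CV; the
    measured ratio is their quotient.  Columns: molar_ratio,
    measured_ratio, replicate.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    rows = []
    for r in ratios:
        for rep in range(replicates):
            heavy = r * base_intensity
            light = base_intensity
            if sigma:
                heavy *= math.exp(rng.normal(0.0, sigma))
                light *= math.exp(rng.normal(0.0, sigma))
            rows.append(
                {
                    "molar_ratio": float(r),
                    "measured_ratio": heavy / light,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
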