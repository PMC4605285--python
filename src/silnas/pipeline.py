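"""End-to-end orchestration: feature tables in, PTM map out.

The flow mirrors the isotope-dilution mapping experiment:

1. digest each parent in silico (light cellular termini; heavy in-vitro
   reference termini) and build the light+heavy theoretical index;
2. match observed features at ppm tolerance and pair light species with
   the co-eluting heavy reference;
3. estimate each fragment's modified fraction from the *unmodified* light
   vs heavy signal heights;
4. localize mass-shifted species (methyls, acetyls) from their MS/MS
   ladders and the methylated-base-loss diagnostic;
5. call pseudouridine from the cyanoethylated run (reaction-efficiency
   contrast psi ~30% vs U ~5%), localizing via the CE'd species' MS/MS;
6. attribute fragment-level fractions to single-site fragments, aggregate
   across enzymes/charges/replicates, and assemble the coverage report and
   final per-position map.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .assembly import CoverageReport, PtmMap, assemble_coverage, build_ptm_map
from .chemistry import LABEL_SCHEMES, MODIFICATIONS
from .digestion import AnnotatedSequence, DigestParams, Fragment, digest
from .io import features_from_table
from .matching import (
    FeaturePair,
    IndexEntry,
    Match,
    PairingResult,
    SearchParams,
    build_index,
    candidates_for_entry,
    localize_msms,
    match_features,
    pair_light_heavy,
)
from .quantification import (
    CEParams,
    PsiCall,
    SiteQuant,
    aggregate,
    ce_psi_detect_fragments,
    site_stoichiometry,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

Identity = Tuple[str, int, int]


@dataclass
class PipelineConfig:
    label: str = "heavy-g"
    enzymes: Sequence[str] = ("T1",)
    #: optional per-enzyme label override (e.g. heavy-cu for RNase A runs)
    labels: Mapping[str, str] = field(default_factory=dict)
    search: SearchParams = field(default_factory=SearchParams)
    ce_params: CEParams = field(default_factory=CEParams)
    max_missed: int = 1
    light_five_prime: str = "p"
    heavy_five_prime: str = "ppp"
    #: rt window (s) around the heavy reference inside which light species
    #: are credited to a fragment in the post-CE run; must cover the
    #: modification + cyanoethylation rt shifts but exclude isobaric
    #: fragments eluting elsewhere in the gradient
    ce_rt_window: float = 300.0
    #: per feature, keep only interpretations within this many ppm of the
    #: best one (winner-take-all with a tie margin); near-isobaric species
    #: several ppm away are discarded rather than treated as candidates
    best_match_margin_ppm: float = 1.0


@dataclass
class LocalizedMod:
    """A mass-shifted species localized to specific positions."""

    identity: Identity
    sites: Tuple[Tuple[int, str], ...]  # global positions
    score: float
    resolved: bool
    state: Tuple = ()  # (n_methyl, var_mods, n_ce) of the index entry


@dataclass
class PipelineResult:
    ptm_map: PtmMap
    coverage: CoverageReport
    site_quants: List[SiteQuant]
    psi_calls: List[PsiCall]
    localized: List[LocalizedMod]
    pairing: Dict[str, PairingResult]
    fragment_fractions: Dict[Identity, float]
    ambiguous_identities: set = field(default_factory=set)
    #: raw (unclipped) per-observation modified-fraction estimates per
    #: fragment identity: one value per charge state x replicate x variant
    fragment_observations: Dict[Identity, List[float]] = field(default_factory=dict)


def _run_enzyme_of(run_id: str) -> str:
    return run_id.split("-", 1)[0]


def _is_ce_run(run_id: str) -> bool:
    return run_id.endswith("-ce")


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def _best_matches(matches: Sequence[Match], margin_ppm: float) -> List[Match]:
    """Per feature, keep interpretations within ``margin_ppm`` of the best."""
    best: Dict[int, float] = {}
    for m in matches:
        fid = id(m.feature)
        if fid not in best or abs(m.ppm) < best[fid]:
            best[fid] = abs(m.ppm)
    return [m for m in matches if abs(m.ppm) <= best[id(m.feature)] + margin_ppm]


def run_pipeline(
    parents: Sequence[AnnotatedSequence],
    features: pd.DataFrame,
    ce_features: Optional[pd.DataFrame] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run matching, quantification, psi inference and assembly.

    ``parents`` are *plain* sequences (the point of the method is that no
    prior modification knowledge is needed); ``features`` is the pre-CE
    feature table covering one or more enzyme runs; ``ce_features`` the
    optional post-cyanoethylation table.
    """
    config = config or PipelineConfig()
    search = config.search

    all_pairs: List[FeaturePair] = []
    pairing_by_enzyme: Dict[str, PairingResult] = {}
    digests: Dict[Tuple[str, str], List[Fragment]] = {}
    ce_matches_by_enzyme: Dict[str, List[Match]] = {}
    parent_by_id = {p.id: p for p in parents}

    for enzyme in config.enzymes:
        light_frags: List[Fragment] = []
        heavy_frags: List[Fragment] = []
        for parent in parents:
            light_parent = AnnotatedSequence(
                id=parent.id,
                residues=parent.residues,
                five_prime=config.light_five_prime,
                three_prime=parent.three_prime,
            )
            heavy_parent = AnnotatedSequence(
                id=parent.id,
                residues=parent.residues,
                five_prime=config.heavy_five_prime,
                three_prime=parent.three_prime,
            )
            dp = DigestParams(enzyme=enzyme, max_missed=config.max_missed)
            light_frags.extend(digest(light_parent, dp))
            heavy_frags.extend(digest(heavy_parent, dp))
        label_name = config.labels.get(enzyme, config.label)
        label = LABEL_SCHEMES[label_name]
        digests[(enzyme, label_name)] = light_frags

        index = build_index(light_frags, label, search, heavy_digest=heavy_frags)
        enz_rows = features[
            features["run_id"].map(
                lambda r: _run_enzyme_of(str(r)) == enzyme and not _is_ce_run(str(r))
            )
        ]
        feats = features_from_table(enz_rows)
        matches = _best_matches(
            match_features(feats, index, search), config.best_match_margin_ppm
        )
        pairing = pair_light_heavy(matches, search)
        pairing_by_enzyme[enzyme] = pairing
        all_pairs.extend(pairing.pairs)

        if ce_features is not None:
            ce_search = SearchParams(
                ms1_tol_ppm=search.ms1_tol_ppm,
                ms2_tol_ppm=search.ms2_tol_ppm,
                max_variable_methyl=search.max_variable_methyl,
                variable_mods=search.variable_mods,
                charge_range=search.charge_range,
                enable_ce=True,
                max_ce=search.max_ce,
                rt_pair_window=search.rt_pair_window,
                base_loss_weight=search.base_loss_weight,
            )
            ce_index = build_index(
                light_frags, label, ce_search, heavy_digest=heavy_frags
            )
            ce_rows = ce_features[
                ce_features["run_id"].map(
                    lambda r: _run_enzyme_of(str(r)) == enzyme
                )
            ]
            ce_matches_by_enzyme[enzyme] = _best_matches(
                match_features(features_from_table(ce_rows), ce_index, ce_search),
                config.best_match_margin_ppm,
            )

    # ------------------------------------------------------------------
    # fragment-level stoichiometry observations
    # ------------------------------------------------------------------
    plain_obs: Dict[Identity, List[float]] = defaultdict(list)
    plain_evidence: Dict[Identity, set] = defaultdict(set)
    heavy_seen: Dict[Identity, set] = defaultdict(set)
    shifted_plain: Dict[Identity, List[FeaturePair]] = defaultdict(list)
    modified_pairs: Dict[Identity, List[FeaturePair]] = defaultdict(list)

    ambiguous_idents: set = set()
    for pair in all_pairs:
        if pair.ambiguous:
            ambiguous_idents.add(pair.identity)
    for pair in all_pairs:
        ident = pair.identity
        if ident in ambiguous_idents:
            continue  # exact-mass confound: needs segmentation/another digest
        heavy_seen[ident].add(_run_enzyme_of(pair.heavy.run_id))
        entry = pair.light_entry
        if entry.is_plain:
            if pair.co_eluting:
                plain_obs[ident].append(site_stoichiometry(pair, clip=False))
                plain_evidence[ident].add(_run_enzyme_of(pair.light.run_id))
            else:
                shifted_plain[ident].append(pair)
        else:
            modified_pairs[ident].append(pair)

    fragment_fractions: Dict[Identity, float] = {}
    for ident in heavy_seen:
        if plain_obs.get(ident):
            fragment_fractions[ident] = _mean(plain_obs[ident])
        else:
            # heavy reference observed but no co-eluting unmodified light:
            # the fragment is (effectively) fully modified
            fragment_fractions[ident] = 1.0

    # ------------------------------------------------------------------
    # MS/MS localization of mass-shifted species
    # ------------------------------------------------------------------
    localized: List[LocalizedMod] = []
    for ident, pairs in sorted(modified_pairs.items(), key=str):
        by_entry: Dict[IndexEntry, List[FeaturePair]] = defaultdict(list)
        for p in pairs:
            by_entry[p.light_entry].append(p)
        # one species (entry modulo charge) may appear at several charges;
        # localize once per distinct variable-mod state
        seen_states = set()
        for entry, entry_pairs in sorted(
            by_entry.items(), key=lambda kv: (kv[0].n_methyl, kv[0].var_mods, kv[0].n_ce, kv[0].charge)
        ):
            state = (entry.n_methyl, entry.var_mods, entry.n_ce)
            if state in seen_states:
                continue
            candidates = candidates_for_entry(entry)
            if not candidates:
                continue
            with_msms = [
                p for p in entry_pairs if p.light.msms
            ]
            if with_msms:
                best_feature = max(with_msms, key=lambda p: p.light.intensity).light
                ranked = localize_msms(best_feature, candidates, search)
                if not ranked:
                    continue
                top = ranked[0]
                if top.matched_fraction < 0.3:
                    # spectrum does not support this fragment at all: likely a
                    # mass coincidence with another species
                    continue
                resolved = len(ranked) == 1 or top.score > ranked[1].score
                sites = top.candidate.global_sites
            else:
                resolved = len(candidates) == 1
                sites = candidates[0].global_sites
            seen_states.add(state)
            localized.append(
                LocalizedMod(
                    identity=ident,
                    sites=sites,
                    score=1.0 if resolved else 0.0,
                    resolved=resolved,
                    state=state,
                )
            )

    # ------------------------------------------------------------------
    # cyanoethylation-based psi detection
    # ------------------------------------------------------------------
    psi_calls: List[PsiCall] = []
    if ce_features is not None and ce_matches_by_enzyme:
        frag_stats: Dict[Identity, dict] = {}
        ce_light: Dict[Identity, Dict[int, Dict[str, float]]] = defaultdict(
            lambda: defaultdict(lambda: {"ce": 0.0, "all": 0.0})
        )
        ce_msms_features: Dict[Identity, List[Tuple[Match, IndexEntry]]] = defaultdict(list)
        # anchor rt per identity: the heavy reference in the post-CE run
        heavy_rt: Dict[Identity, List[float]] = defaultdict(list)
        for matches in ce_matches_by_enzyme.values():
            for m in matches:
                if m.entry.is_heavy and m.entry.n_ce == 0:
                    heavy_rt[m.entry.identity].append(m.feature.rt)
        counted = set()
        for enzyme, matches in ce_matches_by_enzyme.items():
            for m in matches:
                e = m.entry
                if e.is_heavy or e.n_methyl or e.var_mods:
                    continue
                anchors = heavy_rt.get(e.identity)
                if anchors and all(
                    abs(m.feature.rt - a) > config.ce_rt_window for a in anchors
                ):
                    continue  # isobaric species eluting elsewhere
                key = (id(m.feature), e.identity, e.n_ce)
                if key in counted:
                    continue
                counted.add(key)
                # pool across charge states (a CE shift can change the charge
                # enumeration, so per-charge fractions would be biased)
                bucket = ce_light[e.identity][m.feature.replicate]
                bucket["all"] += m.feature.intensity
                if e.n_ce >= 1:
                    bucket["ce"] += m.feature.intensity
                    if m.feature.msms:
                        ce_msms_features[e.identity].append((m, e))
        for ident, buckets in ce_light.items():
            if ident in ambiguous_idents:
                continue
            fracs = [
                b["ce"] / b["all"] for b in buckets.values() if b["all"] > 0
            ]
            if not fracs:
                continue
            parent = parent_by_id.get(ident[0])
            if parent is None:
                continue
            seq = parent.residues[ident[1] - 1 : ident[2]]
            n_u = seq.count("U")
            if n_u == 0:
                continue
            u_positions = tuple(
                ident[1] + i for i, b in enumerate(seq) if b == "U"
            )
            position = None
            if ce_msms_features.get(ident):
                best_match, best_entry = max(
                    ce_msms_features[ident], key=lambda t: t[0].feature.intensity
                )
                cands = [
                    c
                    for c in candidates_for_entry(best_entry)
                ]
                if cands:
                    ranked = localize_msms(best_match.feature, cands, search)
                    if ranked:
                        ce_sites = [
                            pos
                            for pos, code in ranked[0].candidate.global_sites
                            if code == "ce"
                        ]
                        if len(ce_sites) == 1:
                            position = ce_sites[0]
            if position is None and len(u_positions) == 1:
                position = u_positions[0]
            frag_stats[ident] = {
                "parent_id": ident[0],
                "identity": ident,
                "n_u": n_u,
                "f_modified": max(0.0, min(1.0, fragment_fractions.get(ident, 0.0))),
                "ce_fraction": _mean(fracs),
                "position": position,
                "positions_candidate": u_positions,
            }
        psi_calls = ce_psi_detect_fragments(
            [frag_stats[k] for k in sorted(frag_stats, key=str)], config.ce_params
        )
    else:
        # retention-time-only psi evidence (no CE run): a plain-mass light
        # species at a shifted rt in a fragment with positive modified
        # fraction is the classic mass-silent signature
        for ident, pairs in sorted(shifted_plain.items(), key=str):
            parent = parent_by_id.get(ident[0])
            if parent is None:
                continue
            seq = parent.residues[ident[1] - 1 : ident[2]]
            u_positions = tuple(ident[1] + i for i, b in enumerate(seq) if b == "U")
            if not u_positions:
                continue
            f_mod = max(0.0, min(1.0, fragment_fractions.get(ident, 0.0)))
            psi_calls.append(
                PsiCall(
                    parent_id=ident[0],
                    identity=ident,
                    n_u=len(u_positions),
                    f_modified=f_mod,
                    ce_fraction_observed=float("nan"),
                    expected_null=float("nan"),
                    expected_psi=float("nan"),
                    p_value=float("nan"),
                    called=f_mod > 0.0,
                    position=u_positions[0] if len(u_positions) == 1 else None,
                    positions_candidate=u_positions,
                )
            )

    # ------------------------------------------------------------------
    # attribution: fragment fraction -> single variable site
    # ------------------------------------------------------------------
    final_sites: Dict[Tuple[str, int], str] = {}
    unresolved_localized: List[LocalizedMod] = []
    for loc in localized:
        if not loc.resolved:
            unresolved_localized.append(loc)
            continue
        for pos, code in loc.sites:
            if code == "ce":
                continue
            key = (loc.identity[0], pos)
            final_sites.setdefault(key, code)
    for call in psi_calls:
        if call.called and call.position is not None:
            final_sites.setdefault((call.parent_id, call.position), "Y")

    site_obs: Dict[Tuple[str, int], List[float]] = defaultdict(list)
    site_evidence: Dict[Tuple[str, int], List[str]] = defaultdict(list)
    multi_site_idents: Dict[Identity, List[Tuple[str, int]]] = {}
    for ident, obs in plain_obs.items():
        parent_id, start, end = ident
        in_span = [
            (parent_id, pos)
            for (pid, pos) in final_sites
            if pid == parent_id and start <= pos <= end
        ]
        parent = parent_by_id.get(parent_id)
        boundary_blocked = False
        if parent is not None and start > 1:
            up_code = final_sites.get((parent_id, start - 1))
            if up_code and MODIFICATIONS[up_code].blocks_cleavage_3prime:
                boundary_blocked = True
        if boundary_blocked:
            continue
        if len(in_span) == 1:
            key = in_span[0]
            site_obs[key].extend(obs)
            site_evidence[key].extend(
                f"{enz}:{parent_id}:{start}-{end}" for enz in sorted(plain_evidence[ident])
            )
        elif len(in_span) > 1:
            multi_site_idents[ident] = in_span

    site_quants: List[SiteQuant] = []
    for (parent_id, pos), code in sorted(final_sites.items()):
        obs = site_obs.get((parent_id, pos))
        if obs:
            site_quants.append(
                aggregate(
                    parent_id,
                    pos,
                    code,
                    obs,
                    evidence=tuple(dict.fromkeys(site_evidence[(parent_id, pos)])),
                )
            )
        else:
            # fall back to the directly observed modified-species fraction
            f = _modified_species_fraction(parent_id, pos, all_pairs, localized)
            if f is None:
                f = max(
                    0.0,
                    min(
                        1.0,
                        _mean(
                            [
                                fragment_fractions[i]
                                for i in fragment_fractions
                                if i[0] == parent_id and i[1] <= pos <= i[2]
                            ]
                            or [0.0]
                        ),
                    ),
                )
                resolved = False
            else:
                resolved = True
            site_quants.append(
                SiteQuant(
                    parent_id=parent_id,
                    position=pos,
                    mod_code=code,
                    f=f,
                    sd=0.0,
                    n_observations=1,
                    evidence=("modified-species",),
                    resolved=resolved,
                )
            )
    # unresolved multi-site fragments: exported with shared evidence flag
    for ident, keys in sorted(multi_site_idents.items(), key=str):
        for parent_id, pos in keys:
            if any(q.position == pos and q.parent_id == parent_id for q in site_quants):
                continue
            f = _modified_species_fraction(parent_id, pos, all_pairs, localized)
            site_quants.append(
                SiteQuant(
                    parent_id=parent_id,
                    position=pos,
                    mod_code=final_sites[(parent_id, pos)],
                    f=f if f is not None else fragment_fractions.get(ident, 0.0),
                    sd=0.0,
                    n_observations=1,
                    evidence=(f"shared:{ident[1]}-{ident[2]}",),
                    resolved=False,
                    interval=(ident[1], ident[2]),
                )
            )

    coverage = assemble_coverage(all_pairs, parents, digests)
    interval_calls = [
        c for c in psi_calls if c.called and c.position is None
    ]
    ptm_map = build_ptm_map(coverage, site_quants, interval_calls)
    return PipelineResult(
        ptm_map=ptm_map,
        coverage=coverage,
        site_quants=site_quants,
        psi_calls=psi_calls,
        localized=localized,
        pairing=pairing_by_enzyme,
        fragment_fractions=fragment_fractions,
        ambiguous_identities=ambiguous_idents,
        fragment_observations={k: list(v) for k, v in plain_obs.items()},
    )


def _modified_species_fraction(
    parent_id: str,
    pos: int,
    pairs: Sequence[FeaturePair],
    localized: Sequence[LocalizedMod],
) -> Optional[float]:
    """Consistency estimator: intensity share of light species carrying the
    site among all light species of fragments containing it.

    Exact when species of one fragment ionize equally; used when the
    unmodified-vs-heavy route is unavailable (fully modified sites,
    multi-site fragments).
    """
    carrying = {
        loc.identity
        for loc in localized
        if loc.identity[0] == parent_id
        and any(p == pos for p, _ in loc.sites)
    }
    if not carrying:
        return None
    ident = sorted(carrying)[0]
    # which variable-mod states of this fragment carry the site
    carrying_states = {
        loc.state
        for loc in localized
        if loc.identity == ident and any(p == pos for p, _ in loc.sites)
    }
    with_site = 0.0
    total = 0.0
    for pair in pairs:
        if pair.identity != ident:
            continue
        total += pair.light.intensity
        entry = pair.light_entry
        if entry.is_plain:
            continue
        if (entry.n_methyl, entry.var_mods, entry.n_ce) in carrying_states:
            with_site += pair.light.intensity
    if total <= 0:
        return None
    return max(0.0, min(1.0, with_site / total))
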