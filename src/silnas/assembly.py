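"""Sequence-coverage bookkeeping and final PTM-map assembly.

A modification map is complete only when every position of the parent is
covered by at least one matched fragment, which in practice requires
complementary digests (RNase T1 plus RNase A of differently labeled
references) and, for repeated subsequences, RNase-H segmentation.  This
module tallies that evidence and merges localized site quantifications and
pseudouridine calls into one per-position map.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .digestion import AnnotatedSequence, Fragment, find_redundant_fragments
from .matching import FeaturePair
from .quantification import PsiCall, SiteQuant

__all__ = [
    "PtmSite",
    "PtmMap",
    "CoverageReport",
    "assemble_coverage",
    "build_ptm_map",
]


@dataclass(frozen=True)
class PtmSite:
    parent_id: str
    position: int  # 1-based
    mod_code: str
    f: float
    sd: float = 0.0
    n_observations: int = 1
    evidence: Tuple[str, ...] = ()
    resolved: bool = True
    interval: Optional[Tuple[int, int]] = None


@dataclass
class Conflict:
    parent_id: str
    position: int
    codes: Tuple[str, ...]
    detail: str = ""


@dataclass
class PtmMap:
    """Per-position modification calls for one or more parent molecules."""

    sites: List[PtmSite] = field(default_factory=list)
    conflicts: List[Conflict] = field(default_factory=list)

    def for_parent(self, parent_id: str) -> List[PtmSite]:
        return sorted(
            (s for s in self.sites if s.parent_id == parent_id),
            key=lambda s: s.position,
        )

    def summary_counts(self) -> Dict[str, int]:
        """Tally of sites by modification class."""
        from .chemistry import MODIFICATIONS

        counts: Counter = Counter()
        for site in self.sites:
            mod = MODIFICATIONS.get(site.mod_code)
            counts[mod.mod_class if mod else "unknown"] += 1
        return dict(counts)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class CoverageReport:
    """Per-position evidence depth by (enzyme, label) combination."""

    parent_lengths: Dict[str, int]
    depth: Dict[str, Dict[Tuple[str, str], List[int]]]  # parent -> combo -> depths
    #: MS-indistinguishable (redundant) fragment placements per parent
    ambiguous_intervals: Optional[Dict[str, List[Tuple[int, int]]]] = None

    def total_depth(self, parent_id: str) -> List[int]:
        n = self.parent_lengths[parent_id]
        total = [0] * n
        for depths in self.depth.get(parent_id, {}).values():
            for i, d in enumerate(depths):
                total[i] += d
        return total

    def uncovered_intervals(self, parent_id: str) -> List[Tuple[int, int]]:
        total = self.total_depth(parent_id)
        intervals: List[Tuple[int, int]] = []
        start = None
        for i, d in enumerate(total, start=1):
            if d == 0 and start is None:
                start = i
            elif d > 0 and start is not None:
                intervals.append((start, i - 1))
                start = None
        if start is not None:
            intervals.append((start, len(total)))
        return intervals


def assemble_coverage(
    pairs: Sequence[FeaturePair],
    parents: Sequence[AnnotatedSequence],
    digests: Optional[Dict[Tuple[str, str], Sequence[Fragment]]] = None,
) -> CoverageReport:
    """Per-position depth from matched light/heavy pairs.

    Depth at a position counts distinct (fragment identity, run, replicate,
    enzyme/label combination) observations covering it; charge states of
    one species do not inflate depth.  ``digests`` (keyed by
    (enzyme, label) as recorded in the pair's run id, or any labeling the
    caller chooses) are used to flag redundant (MS-indistinguishable)
    placements.
    """
    lengths = {p.id: len(p) for p in parents}
    depth: Dict[str, Dict[Tuple[str, str], List[int]]] = {
        p.id: {} for p in parents
    }
    seen = set()
    for pair in pairs:
        parent_id, start, end = pair.identity
        if parent_id not in lengths:
            continue
        combo = (pair.light.run_id, pair.light_entry.label_name)
        key = (pair.identity, combo, pair.light.replicate)
        if key in seen:
            continue
        seen.add(key)
        depths = depth[parent_id].setdefault(combo, [0] * lengths[parent_id])
        for pos in range(start, end + 1):
            depths[pos - 1] += 1
    report = CoverageReport(parent_lengths=lengths, depth=depth)
    ambiguous: Dict[str, List[Tuple[int, int]]] = {p.id: [] for p in parents}
    if digests:
        for (enzyme, _label), frags in digests.items():
            by_parent: Dict[str, List[Fragment]] = {}
            for f in frags:
                by_parent.setdefault(f.parent_id, []).append(f)
            for parent_id, plist in by_parent.items():
                if parent_id not in ambiguous:
                    continue
                for group in find_redundant_fragments(plist):
                    for start, end in group.placements:
                        if (start, end) not in ambiguous[parent_id]:
                            ambiguous[parent_id].append((start, end))
    for v in ambiguous.values():
        v.sort()
    report.ambiguous_intervals = ambiguous
    return report


def build_ptm_map(
    coverage: CoverageReport,
    site_quants: Sequence[SiteQuant],
    psi_calls: Sequence[PsiCall] = (),
) -> PtmMap:
    """Merge localized quantifications and psi calls into one PTM map.

    One site per (parent, position); conflicting modification codes at a
    position are recorded as conflicts, never silently overwritten.
    Fragment-level psi calls that could not be resolved to a single
    position are exported as interval sites (``resolved=False``).
    """
    ptm = PtmMap()
    by_pos: Dict[Tuple[str, int], PtmSite] = {}

    def _add(site: PtmSite) -> None:
        key = (site.parent_id, site.position)
        existing = by_pos.get(key)
        if existing is None:
            by_pos[key] = site
            return
        if existing.mod_code != site.mod_code:
            ptm.conflicts.append(
                Conflict(
                    parent_id=site.parent_id,
                    position=site.position,
                    codes=(existing.mod_code, site.mod_code),
                    detail="conflicting modification codes at one position",
                )
            )
            return
        # same code observed twice (e.g. two enzymes): pool observations
        n = existing.n_observations + site.n_observations
        f = (
            existing.f * existing.n_observations + site.f * site.n_observations
        ) / n
        by_pos[key] = PtmSite(
            parent_id=site.parent_id,
            position=site.position,
            mod_code=site.mod_code,
            f=f,
            sd=max(existing.sd, site.sd),
            n_observations=n,
            evidence=existing.evidence + site.evidence,
            resolved=existing.resolved and site.resolved,
        )

    for q in site_quants:
        _add(
            PtmSite(
                parent_id=q.parent_id,
                position=q.position,
                mod_code=q.mod_code,
                f=q.f,
                sd=q.sd,
                n_observations=q.n_observations,
                evidence=q.evidence,
                resolved=q.resolved,
                interval=q.interval,
            )
        )
    for call in psi_calls:
        if not call.called:
            continue
        if call.position is not None:
            _add(
                PtmSite(
                    parent_id=call.parent_id,
                    position=call.position,
                    mod_code="Y",
                    f=call.f_modified,
                    evidence=(f"CE:{call.identity}",),
                )
            )
        else:
            start, end = call.identity[1], call.identity[2]
            ptm.sites.append(
                PtmSite(
                    parent_id=call.parent_id,
                    position=start,
                    mod_code="Y",
                    f=call.f_modified,
                    evidence=(f"CE:{call.identity}",),
                    resolved=False,
                    interval=(start, end),
                )
            )
    ptm.sites.extend(
        sorted(by_pos.values(), key=lambda s: (s.parent_id, s.position))
    )
    ptm.sites.sort(key=lambda s: (s.parent_id, s.position))
    return ptm
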