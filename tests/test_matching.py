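"""Theoretical index construction, ppm matching, light/heavy pairing and
MS/MS localization."""

import json

import pytest

from silnas.chemistry import LABEL_SCHEMES
from silnas.digestion import AnnotatedSequence, DigestParams, Fragment, digest
from silnas.mass_model import mz, neutral_mass
from silnas.matching import (
    Feature,
    SearchParams,
    build_index,
    candidates_for_entry,
    localize_msms,
    match_features,
    pair_light_heavy,
)
from silnas.simulator import _msms_payload

HEAVY_G = LABEL_SCHEMES["heavy-g"]
NONE = LABEL_SCHEMES["none"]


def single_fragment_digest(sequence="AAUUG", three="p"):
    return [
        Fragment("p1", 1, len(sequence), sequence, five_prime="OH", three_prime=three)
    ]


def feature_for(entry, rt=600.0, intensity=1e6, ppm_offset=0.0, msms=None, rep=0):
    return Feature(
        mz=entry.mz * (1 + ppm_offset * 1e-6),
        charge=entry.charge,
        rt=rt,
        intensity=intensity,
        msms=msms,
        replicate=rep,
    )


class TestBuildIndex:
    def test_unlabeled_unmodifiable_enumeration(self):
        frags = single_fragment_digest("AAAAG")  # no U: no CE states
        params = SearchParams(max_variable_methyl=0)
        index = build_index(frags, NONE, params)
        # light channel only (null label), one entry per charge
        n_charges = len(list(params.charges_for(neutral_mass(frags[0]))))
        assert len(index) == n_charges

    def test_light_and_heavy_channels(self):
        frags = single_fragment_digest("AAAAG")
        params = SearchParams(max_variable_methyl=0)
        index = build_index(frags, HEAVY_G, params)
        n_charges = len(list(params.charges_for(neutral_mass(frags[0]))))
        assert len(index) == 2 * n_charges
        assert {e.is_heavy for e in index.entries} == {False, True}

    def test_variable_methyl_grid(self):
        frags = single_fragment_digest()
        index = build_index(frags, NONE, SearchParams(max_variable_methyl=2))
        masses = sorted(
            {round(e.neutral - neutral_mass(frags[0]), 4) for e in index.entries}
        )
        assert masses == [0.0, 14.0157, 28.0313]

    def test_heavy_reference_carries_no_variable_mods(self):
        frags = single_fragment_digest()
        index = build_index(frags, HEAVY_G, SearchParams(max_variable_methyl=2))
        assert all(e.n_methyl == 0 for e in index.entries if e.is_heavy)

    def test_sorted_and_unique(self):
        parent = AnnotatedSequence("p", "AAUGCCGUAAG", three_prime="p")
        frags = digest(parent, DigestParams("T1", 1))
        index = build_index(frags, HEAVY_G, SearchParams())
        mzs = [e.mz for e in index.entries]
        assert mzs == sorted(mzs)
        keys = [
            (e.identity, e.is_heavy, e.n_methyl, e.var_mods, e.n_ce, e.charge)
            for e in index.entries
        ]
        assert len(keys) == len(set(keys))

    def test_empty_digest_rejected(self):
        with pytest.raises(ValueError):
            build_index([], NONE, SearchParams())


class TestMatchFeatures:
    def setup_method(self):
        self.frags = single_fragment_digest()
        self.params = SearchParams(max_variable_methyl=0)
        self.index = build_index(self.frags, HEAVY_G, self.params)
        self.light = [e for e in self.index.entries if not e.is_heavy][0]

    def test_exact_feature_matches(self):
        matches = match_features([feature_for(self.light)], self.index, self.params)
        assert len(matches) == 1
        assert matches[0].ppm == pytest.approx(0.0, abs=1e-9)

    def test_mass_silent_matches_are_isomer_ambiguous(self):
        matches = match_features([feature_for(self.light)], self.index, self.params)
        assert matches[0].isomer_ambiguous  # AAUUG contains U: could be psi

    def test_offset_beyond_tolerance_is_not_matched(self):
        off = feature_for(self.light, ppm_offset=100.0)
        assert match_features([off], self.index, self.params) == []

    def test_match_count_monotone_in_tolerance(self):
        feats = [
            feature_for(self.light, ppm_offset=delta)
            for delta in (-30, -15, -5, 0, 5, 15, 30)
        ]
        counts = [
            len(match_features(feats, self.index, SearchParams(ms1_tol_ppm=tol)))
            for tol in (1, 5, 10, 20, 40, 100)
        ]
        assert counts == sorted(counts)


class TestPairing:
    def setup_method(self):
        self.frags = single_fragment_digest()
        self.params = SearchParams(max_variable_methyl=1)
        self.index = build_index(self.frags, HEAVY_G, self.params)
        entries = [e for e in self.index.entries if e.charge == 2]
        self.light = next(e for e in entries if not e.is_heavy and e.is_plain)
        self.heavy = next(e for e in entries if e.is_heavy)
        self.methyl = next(
            e for e in entries if not e.is_heavy and e.n_methyl == 1
        )

    def test_unmodified_pair_co_elutes_at_ratio_one(self):
        feats = [
            feature_for(self.light, rt=600.0, intensity=5e5),
            feature_for(self.heavy, rt=601.0, intensity=5e5),
        ]
        res = pair_light_heavy(
            match_features(feats, self.index, self.params), self.params
        )
        assert len(res.pairs) == 1
        pair = res.pairs[0]
        assert pair.co_eluting
        assert pair.ratio == pytest.approx(1.0)
        assert pair.expected_delta == pytest.approx(10.033548, abs=1e-6)

    def test_shifted_mass_silent_species_pairs_without_co_elution(self):
        feats = [
            feature_for(self.light, rt=540.0, intensity=4e5),  # psi isomer, early
            feature_for(self.heavy, rt=600.0, intensity=1e6),
        ]
        res = pair_light_heavy(
            match_features(feats, self.index, self.params), self.params
        )
        assert len(res.pairs) == 1
        assert not res.pairs[0].co_eluting
        assert res.pairs[0].rt_shift == pytest.approx(-60.0)

    def test_methylated_species_pairs_with_plain_heavy(self):
        feats = [
            feature_for(self.methyl, rt=690.0, intensity=3e5),
            feature_for(self.heavy, rt=600.0, intensity=1e6),
        ]
        res = pair_light_heavy(
            match_features(feats, self.index, self.params), self.params
        )
        assert len(res.pairs) == 1
        assert res.pairs[0].light_entry.n_methyl == 1
        assert res.pairs[0].heavy_entry.is_plain

    def test_orphans_are_reported_not_dropped(self):
        only_heavy = [feature_for(self.heavy)]
        res = pair_light_heavy(
            match_features(only_heavy, self.index, self.params), self.params
        )
        assert res.pairs == [] and len(res.orphan_heavy) == 1
        only_light = [feature_for(self.light)]
        res = pair_light_heavy(
            match_features(only_light, self.index, self.params), self.params
        )
        assert res.pairs == [] and len(res.orphan_light) == 1


class TestLocalization:
    def setup_method(self):
        self.params = SearchParams(max_variable_methyl=1)
        self.plain = Fragment("p", 1, 8, "AAUCGCAG", five_prime="OH", three_prime="p")
        index = build_index([self.plain], NONE, self.params)
        self.entry = next(
            e for e in index.entries if e.n_methyl == 1 and e.charge == 2
        )

    def _feature_with_msms(self, species: Fragment):
        payload = json.loads(_msms_payload(species, NONE, 2))
        return Feature(
            mz=mz(neutral_mass(species), 2),
            charge=2,
            rt=600.0,
            intensity=1e6,
            msms=tuple((m, i) for m, i in payload),
        )

    def test_perfect_ladder_ranks_true_ribose_site_first(self):
        species = self.plain.with_mods({4: ("Cm",)})
        ranked = localize_msms(
            self._feature_with_msms(species),
            candidates_for_entry(self.entry),
            self.params,
        )
        assert ranked[0].candidate.sites == ((4, "Cm"),)
        assert ranked[0].matched_fraction == 1.0

    def test_base_loss_separates_base_from_ribose_methyl(self):
        # same position, same ladder masses: only the methylated-base loss
        # from the precursor distinguishes m5C from Cm
        species = self.plain.with_mods({4: ("m5C",)})
        ranked = localize_msms(
            self._feature_with_msms(species),
            candidates_for_entry(self.entry),
            self.params,
        )
        scores = {r.candidate.sites: r.score for r in ranked}
        assert ranked[0].candidate.sites == ((4, "m5C"),)
        assert scores[((4, "m5C"),)] > scores[((4, "Cm"),)]

    def test_ranking_is_permutation_invariant(self):
        species = self.plain.with_mods({4: ("Cm",)})
        feature = self._feature_with_msms(species)
        cands = candidates_for_entry(self.entry)
        fwd = localize_msms(feature, cands, self.params)
        rev = localize_msms(feature, list(reversed(cands)), self.params)
        assert [r.candidate.sites for r in fwd] == [
            r.candidate.sites for r in rev
        ]

    def test_empty_msms_is_an_error(self):
        bare = Feature(mz=500.0, charge=1, rt=1.0, intensity=1.0)
        with pytest.raises(ValueError):
            localize_msms(bare, candidates_for_entry(self.entry), self.params)

    def test_empty_candidate_set_yields_empty_ranking(self):
        species = self.plain.with_mods({4: ("Cm",)})
        assert localize_msms(
            self._feature_with_msms(species), [], self.params
        ) == []
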