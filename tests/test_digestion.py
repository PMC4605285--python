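"""Modification-aware digestion against a brute-force string-split oracle,
RNase-H segmentation, and redundancy analysis."""

from collections import Counter

import numpy as np
import pytest

from silnas.chemistry import MODIFICATIONS
from silnas.digestion import (
    AnnotatedSequence,
    DigestParams,
    Fragment,
    digest,
    find_redundant_fragments,
    rnase_h_segment,
)
from silnas.chemistry import WATER as WATER_COMP
from silnas.mass_model import neutral_mass

from conftest import random_annotated

WATER = WATER_COMP.mass  # 18.010565 to the printed precision


def oracle_digest(seq: AnnotatedSequence, enzyme: str, max_missed: int,
                  product_3p: str = "p"):
    """Independent string-split digestion: scan characters, cut after every
    unblocked target residue, then join m+1 consecutive pieces for missed
    cleavages.  Returns a multiset of fragment tuples."""
    targets = "G" if enzyme == "T1" else "CU"
    pieces = []
    current_start = 1
    for i, base in enumerate(seq.residues, start=1):
        blocked = any(
            MODIFICATIONS[c].blocks_cleavage_3prime
            for c in seq.mods.get(i, ())
        )
        if base in targets and not blocked and i < len(seq.residues):
            pieces.append((current_start, i))
            current_start = i + 1
    pieces.append((current_start, len(seq.residues)))
    out = []
    n = len(seq.residues)
    for m in range(max_missed + 1):
        for k in range(len(pieces) - m):
            start, end = pieces[k][0], pieces[k + m][1]
            five = seq.five_prime if start == 1 else "OH"
            three = seq.three_prime if end == n else product_3p
            mods = tuple(
                sorted(
                    (p, seq.mods[p]) for p in seq.mods if start <= p <= end
                )
            )
            out.append((start, end, seq.residues[start - 1 : end], m, five, three, mods))
    return Counter(out)


def as_multiset(fragments):
    return Counter(
        (
            f.start,
            f.end,
            f.sequence,
            f.missed_cleavages,
            f.five_prime,
            f.three_prime,
            f.mods,
        )
        for f in fragments
    )


class TestDigest:
    def test_t1_releases_psi_site_fragment(self):
        # a 5.8S-like context: G just before the AAUUG span at 74-78
        residues = "A" * 60 + "CCCCCCCCCCCCG" + "AAUUG" + "CCAG" + "A" * 20
        seq = AnnotatedSequence(
            "5.8S-like", residues, mods={76: "Y"}, three_prime="OH"
        )
        frags = {
            (f.start, f.end): f for f in digest(seq, DigestParams("T1", 0))
        }
        frag = frags[(74, 78)]
        assert frag.sequence == "AAUUG"
        assert frag.three_prime == "p" and frag.five_prime == "OH"
        assert frag.mods == ((76, ("Y",)),)

    def test_ribose_methyl_blocks_cleavage(self):
        # human-5.8S-like: Gm at 75 merges the products around it
        residues = "C" * 69 + "G" + "AAUUGCAG" + "C" * 10
        seq = AnnotatedSequence("h5.8S-like", residues, mods={75: "Gm"})
        sequences = {
            f.sequence for f in digest(seq, DigestParams("T1", 0))
        }
        assert "AAUUGCAG" in sequences
        assert "AAUUG" not in sequences

    def test_blocking_merges_exactly_two_fragments(self):
        plain = AnnotatedSequence("x", "AAUUGCCAGAA")
        blocked = AnnotatedSequence("x", "AAUUGCCAGAA", mods={5: "Gm"})
        n_plain = sum(1 for f in digest(plain, DigestParams("T1", 0)))
        n_blocked = sum(1 for f in digest(blocked, DigestParams("T1", 0)))
        assert n_blocked == n_plain - 1

    def test_ggg_yields_single_residue_products(self):
        seq = AnnotatedSequence("g3", "GGG", three_prime="p")
        frags = digest(seq, DigestParams("T1", 0))
        assert [(f.sequence, f.three_prime) for f in frags] == [
            ("G", "p"),
            ("G", "p"),
            ("G", "p"),
        ]

    def test_rnase_a_cleaves_pyrimidines_including_psi(self):
        seq = AnnotatedSequence("a", "AAUAACAG", mods={3: "Y"})
        frags = digest(seq, DigestParams("A", 0))
        # psi is still a pyrimidine for RNase A: cut after position 3
        assert {(f.start, f.end) for f in frags} == {(1, 3), (4, 6), (7, 8)}

    def test_concatenation_reproduces_parent(self, rng):
        for _ in range(25):
            seq = random_annotated(rng, 50)
            for enzyme in ("T1", "A"):
                frags = [
                    f
                    for f in digest(seq, DigestParams(enzyme, 0))
                    if f.missed_cleavages == 0
                ]
                frags.sort(key=lambda f: f.start)
                assert "".join(f.sequence for f in frags) == seq.residues

    @pytest.mark.parametrize("enzyme", ["T1", "A"])
    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    def test_matches_string_split_oracle(self, rng, enzyme, max_missed):
        for _ in range(30):
            seq = random_annotated(rng, int(rng.integers(20, 120)), with_mods=True)
            got = as_multiset(digest(seq, DigestParams(enzyme, max_missed)))
            assert got == oracle_digest(seq, enzyme, max_missed)

    def test_missed_one_is_superset_of_missed_zero(self, rng):
        seq = random_annotated(rng, 80)
        m0 = as_multiset(digest(seq, DigestParams("T1", 0)))
        m1 = as_multiset(digest(seq, DigestParams("T1", 1)))
        assert all(m1[k] >= v for k, v in m0.items())

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            digest(AnnotatedSequence("e", ""), DigestParams("T1", 0))


class TestMassConservation:
    def test_linear_products_gain_one_water_per_cut(self, rng):
        for _ in range(20):
            seq = random_annotated(rng, int(rng.integers(20, 80)), three_prime="p")
            frags = [
                f
                for f in digest(seq, DigestParams("T1", 0, "p"))
                if f.missed_cleavages == 0
            ]
            cuts = len(frags) - 1
            parent = Fragment(
                seq.id, 1, len(seq), seq.residues,
                five_prime=seq.five_prime, three_prime=seq.three_prime,
            )
            total = sum(neutral_mass(f) for f in frags)
            assert total == pytest.approx(
                neutral_mass(parent) + cuts * WATER, abs=1e-6
            )

    def test_cyclic_products_conserve_parent_mass_exactly(self, rng):
        for _ in range(20):
            seq = random_annotated(rng, int(rng.integers(20, 80)), three_prime="p")
            frags = [
                f
                for f in digest(seq, DigestParams("A", 0, "cp"))
                if f.missed_cleavages == 0
            ]
            parent = Fragment(
                seq.id, 1, len(seq), seq.residues,
                five_prime=seq.five_prime, three_prime=seq.three_prime,
            )
            total = sum(neutral_mass(f) for f in frags)
            assert total == pytest.approx(neutral_mass(parent), abs=1e-6)


class TestRNaseH:
    def test_no_cut_points_is_identity(self):
        seq = AnnotatedSequence("s", "ACGUACGU", mods={4: "Y"})
        segments = rnase_h_segment(seq, [])
        assert len(segments) == 1
        assert segments[0].residues == seq.residues
        assert segments[0].mods == {4: ("Y",)}

    def test_partition_and_offset_recovery(self):
        seq = AnnotatedSequence("s", "ACGU" * 25, mods={76: "Um"})
        left, right = rnase_h_segment(seq, [40])
        assert len(left) == 40 and len(right) == 60
        assert right.origin_offset == 40
        # the mod at global 76 is local 36 in the right segment
        assert right.mods == {36: ("Um",)}
        assert 36 + right.origin_offset == 76

    def test_out_of_range_cut_point_is_an_error(self):
        seq = AnnotatedSequence("s", "ACGU")
        with pytest.raises(ValueError):
            rnase_h_segment(seq, [4])

    def test_segments_redigest_to_parent_coverage(self):
        seq = AnnotatedSequence("s", "AAGAAGCCGUUG")
        segments = rnase_h_segment(seq, [6])
        spans = []
        for seg in segments:
            for f in digest(seg, DigestParams("T1", 0)):
                if f.missed_cleavages == 0:
                    spans.append(
                        (f.start + seg.origin_offset, f.end + seg.origin_offset)
                    )
        covered = sorted(p for s, e in spans for p in range(s, e + 1))
        assert covered == list(range(1, len(seq) + 1))


class TestRedundancy:
    def test_duplicate_placements_and_cut_window(self):
        seq = AnnotatedSequence("r", "AAGAAG", three_prime="p")
        frags = [
            f for f in digest(seq, DigestParams("T1", 0)) if f.missed_cleavages == 0
        ]
        groups = find_redundant_fragments(frags)
        assert len(groups) == 1
        assert groups[0].placements == ((1, 3), (4, 6))
        # cutting after position 3 separates the two placements
        assert groups[0].cut_windows == ((3, 3),)

    def test_unique_fragments_yield_no_groups(self):
        seq = AnnotatedSequence("u", "AAGCCGUUUG", three_prime="p")
        frags = digest(seq, DigestParams("T1", 0))
        assert find_redundant_fragments(frags) == []

    def test_group_count_matches_hash_count_oracle(self, rng):
        for _ in range(20):
            seq = random_annotated(rng, 60, three_prime="p")
            frags = [
                f
                for f in digest(seq, DigestParams("T1", 0))
                if f.missed_cleavages == 0
            ]
            counts = Counter(f.species_key for f in frags)
            expected = sum(1 for v in counts.values() if v > 1)
            assert len(find_redundant_fragments(frags)) == expected

    def test_mixed_parents_rejected(self):
        f1 = Fragment("a", 1, 2, "AG")
        f2 = Fragment("b", 1, 2, "AG")
        with pytest.raises(ValueError):
            find_redundant_fragments([f1, f2])
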