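"""Structure handling and 2-nt 3' overhang duplex inference."""

from functools import lru_cache

import numpy as np
import pytest

from paremodes.hairpin_geometry import (
    UNPAIRED,
    CannotInfer,
    InsufficientEvidence,
    dominant_arm,
    fold_nussinov,
    infer_mir3p,
    infer_mir5p,
    loop_midpoint,
    overhang_lengths,
    overhang_lengths_from,
    pairing_map,
)
from paremodes.io_formats import HairpinRecord, Interval, SrnaTagTable

from conftest import make_perfect_stem

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_oracle(seq: str, min_loop: int = 3) -> int:
    """Independent maximum-base-pair count: plain recursive Nussinov
    recursion with memoization (no traceback, different formulation)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        b = best(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in _PAIRS:
                b = max(b, best(i, k - 1) + 1 + best(k + 1, j - 1) if k > i
                        else 1 + best(k + 1, j - 1))
        return b

    return best(0, len(seq) - 1)


class TestFold:
    def test_unique_maximum_pairing(self):
        assert fold_nussinov("GGGAAACCC") == "(((...)))"

    def test_nothing_pairs(self):
        assert fold_nussinov("AAAA") == "...."

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fold_nussinov("")

    def test_n_never_pairs(self):
        assert fold_nussinov("NNNAAANNN") == "........."

    def test_pair_count_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(10, 41))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            db = fold_nussinov(seq)
            assert db.count("(") == max_pairs_oracle(seq)

    def test_structure_is_valid_and_respects_min_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=30))
            pm = pairing_map(fold_nussinov(seq))  # parses => balanced
            for i, j in enumerate(pm.partner):
                if j != UNPAIRED and j > i:
                    assert j - i > 3
                    assert (seq[i], seq[j]) in _PAIRS


class TestPairingMap:
    def test_simple_hairpin(self):
        pm = pairing_map("(((...)))")
        assert list(pm.partner) == [8, 7, 6, 3, 4, 5, 2, 1, 0] or (
            pm.partner[0] == 8 and pm.partner[1] == 7 and pm.partner[2] == 6
        )
        assert pm.partner[3] == UNPAIRED

    def test_parser_permissive_about_loop_size(self):
        pm = pairing_map("()")
        assert pm.partner[0] == 1

    @pytest.mark.parametrize("bad", ["((.)", ".)(", "(((", "(x)"])
    def test_unbalanced_or_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            pairing_map(bad)

    def test_symmetry_property(self):
        pm = pairing_map(fold_nussinov("GGCGAAAGCGCCAAAGGC"))
        for i, j in enumerate(pm.partner):
            if j != UNPAIRED:
                assert pm.partner[j] == i
                assert j != i


class TestDominantArm:
    def _hairpin(self):
        return make_perfect_stem(stem_len=30, loop_len=6, mir5p=(2, 23), seed=3)

    def test_argmax_species_on_5p_arm(self):
        hp = self._hairpin()
        tags = SrnaTagTable("s")
        tags.add(hp.precursor_id, 10, "+", 21, 500)
        tags.add(hp.precursor_id, 40, "+", 21, 30)
        arm, iv = dominant_arm(tags, hp)
        assert (arm, iv) == ("5p", Interval(10, 31))

    def test_majority_on_3p_arm(self):
        hp = self._hairpin()
        tags = SrnaTagTable("s")
        tags.add(hp.precursor_id, 40, "+", 21, 500)
        tags.add(hp.precursor_id, 10, "+", 21, 30)
        arm, iv = dominant_arm(tags, hp)
        assert arm == "3p" and iv.start == 40

    def test_tie_breaks_to_smaller_position(self):
        hp = self._hairpin()
        tags = SrnaTagTable("s")
        tags.add(hp.precursor_id, 12, "+", 21, 100)
        tags.add(hp.precursor_id, 10, "+", 21, 100)
        _, iv = dominant_arm(tags, hp)
        assert iv.start == 10

    def test_reads_outside_length_range_ignored(self):
        hp = self._hairpin()
        tags = SrnaTagTable("s")
        tags.add(hp.precursor_id, 10, "+", 16, 1000)
        tags.add(hp.precursor_id, 10, "+", 27, 1000)
        with pytest.raises(InsufficientEvidence):
            dominant_arm(tags, hp)

    def test_no_reads_is_insufficient_evidence(self):
        hp = self._hairpin()
        with pytest.raises(InsufficientEvidence):
            dominant_arm(SrnaTagTable("s"), hp)

    def test_loop_midpoint_of_stem(self):
        hp = make_perfect_stem(stem_len=10, loop_len=6, mir5p=(0, 8))
        # unpaired run is positions 10..15 -> midpoint 13
        assert loop_midpoint(pairing_map(hp.structure)) == 13


class TestInferMir3p:
    def test_perfect_stem_reference_geometry(self, perfect_stem):
        # 25-bp stem, 4-nt loop (54 nt), miR-5p [2,23):
        # partner(2)=51 -> 3' end 53 inclusive; partner(20)=33 -> start 33
        geom = infer_mir3p(perfect_stem)
        assert geom.mir3p == Interval(33, 54)
        assert (geom.overhang_3p_side, geom.overhang_5p_side) == (2, 2)
        assert not geom.clipped

    def test_clipped_at_sequence_end(self, perfect_stem):
        geom = infer_mir3p(perfect_stem, Interval(0, 21))
        assert geom.mir3p == Interval(35, 54)
        assert geom.clipped
        # two overhang bases lost to the boundary leaves a blunt 3' side
        assert geom.overhang_3p_side == 0

    def test_involution_on_bulge_free_stem(self, perfect_stem):
        geom = infer_mir3p(perfect_stem)
        back = infer_mir5p(perfect_stem, geom.mir3p)
        assert back.mir5p == perfect_stem.mir5p

    def test_involution_across_offsets(self):
        for start in (2, 4, 6, 8):
            hp = make_perfect_stem(stem_len=30, loop_len=5, mir5p=(start, start + 21), seed=start)
            geom = infer_mir3p(hp)
            assert (geom.overhang_3p_side, geom.overhang_5p_side) == (2, 2)
            assert infer_mir5p(hp, geom.mir3p).mir5p == hp.mir5p

    def test_bulged_anchor_compensation(self, perfect_stem):
        # unpair the miR-5p start base: nearest paired anchor is 1 nt away
        # and the compensated geometry matches the bulge-free inference
        s = list(perfect_stem.structure)
        pm = pairing_map(perfect_stem.structure)
        j = pm.partner[2]
        s[2] = "."
        s[j] = "."
        bulged = HairpinRecord(
            "stem", perfect_stem.sequence, structure="".join(s), mir5p=perfect_stem.mir5p
        )
        assert infer_mir3p(bulged).mir3p == infer_mir3p(perfect_stem).mir3p

    def test_no_paired_anchor_cannot_infer(self):
        hp = HairpinRecord("x", "A" * 40, structure="." * 40, mir5p=Interval(5, 26))
        with pytest.raises(CannotInfer):
            infer_mir3p(hp)


class TestOverhangs:
    def test_inferred_duplex_has_two_nt_overhangs(self, perfect_stem):
        geom = infer_mir3p(perfect_stem)
        assert overhang_lengths(geom, pairing_map(perfect_stem.structure)) == (2, 2)

    def test_blunt_duplex(self):
        # miR-5p [0,21) with miR-3p exactly spanning its partner region
        hp = make_perfect_stem(stem_len=25, loop_len=4, mir5p=(0, 21))
        pm = pairing_map(hp.structure)
        mir3p = Interval(int(pm.partner[20]), int(pm.partner[0]) + 1)
        assert overhang_lengths_from(pm, Interval(0, 21), mir3p) == (0, 0)

    def test_constructed_three_nt_overhang(self):
        hp = make_perfect_stem(stem_len=25, loop_len=4, mir5p=(3, 24))
        pm = pairing_map(hp.structure)
        # extend the miR-3p 3' end one base past the 2-nt rule position
        rule = infer_mir3p(hp).mir3p
        longer = Interval(rule.start, rule.end + 1)
        ov3, _ = overhang_lengths_from(pm, hp.mir5p, longer)
        assert ov3 == 3
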