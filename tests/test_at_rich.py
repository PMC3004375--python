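"""Control-region element detectors against planted truth and naive oracles."""

import itertools

import numpy as np
import pytest

from mitocomp.at_rich import (
    IUPAC,
    dyad_symmetry,
    find_stem_loops,
    find_t_stretch,
    find_tandem_repeats,
    reverse_complement,
    scan_motif,
    unit_identity,
)
from mitocomp.synthetic import random_sequence


class TestTandemRepeats:
    def test_planted_unit8_x6(self):
        rng = np.random.default_rng(42)
        bg = random_sequence(rng, 100, at_fraction=0.5)
        seq = bg[:50] + "ACGTTGCA" * 6 + bg[50:]
        hits = find_tandem_repeats(seq, min_unit=8)
        assert len(hits) == 1
        (h,) = hits
        assert h.unit_length == 8
        assert h.copies == 6
        assert abs(h.start - 51) < 8  # start within one unit

    def test_seeded_random_sequence_has_no_array(self):
        seq = random_sequence(np.random.default_rng(0), 500)
        assert find_tandem_repeats(seq, min_unit=20, min_identity=90.0) == []

    def test_divergent_copy_identity_reported(self):
        """A 155-bp unit duplicated with ~13% substitution divergence is
        found with the divergence visible in the per-copy identity."""
        from mitocomp.synthetic import ControlRegionSpec, RepeatSpec, SyntheticSpec, simulate_control_region

        spec = SyntheticSpec(
            seed=7,
            control_region=ControlRegionSpec(
                length=800,
                elements=(RepeatSpec(unit_length=155, copies=2, divergence=0.13, position=100),),
            ),
        )
        seq, truth = simulate_control_region(spec)
        hits = find_tandem_repeats(seq, min_unit=100)
        assert len(hits) == 1
        (h,) = hits
        assert (h.unit_length, h.copies, h.start) == (155, 2, 100)
        assert h.identities[0] == 100.0
        assert h.identities[1] == pytest.approx(87.0, abs=2.0)

    def test_too_short_sequence_returns_empty(self):
        assert find_tandem_repeats("ACGTACG", min_unit=10) == []


class TestUnitIdentity:
    def test_identical_units(self):
        assert unit_identity("ACGT" * 25, "ACGT" * 25) == 100.0

    def test_two_substitutions_in_100(self):
        u = random_sequence(np.random.default_rng(3), 100, at_fraction=0.5)
        v = list(u)
        v[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[v[10]]
        v[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[v[50]]
        assert unit_identity(u, "".join(v)) == 98.00

    def test_symmetry(self):
        a = "ACGTTACGGA"
        b = "ACGTACGGA"
        assert unit_identity(a, b) == unit_identity(b, a)

    def test_100_iff_identical(self):
        assert unit_identity("ACGT", "ACGA") < 100.0

    def test_matches_exhaustive_alignment_oracle_on_short_strings(self):
        """Optimal global-alignment score equals a brute-force recursion
        (match +1, mismatch -1, gap -2) on strings of length <= 12, including
        a 3-nt indel pair."""
        from functools import lru_cache

        def brute(a, b):
            @lru_cache(maxsize=None)
            def f(i, j):
                if i == len(a) and j == len(b):
                    return 0
                best = -10**9
                if i < len(a) and j < len(b):
                    best = max(best, (1 if a[i] == b[j] else -1) + f(i + 1, j + 1))
                if i < len(a):
                    best = max(best, -2 + f(i + 1, j))
                if j < len(b):
                    best = max(best, -2 + f(i, j + 1))
                return best

            return f(0, 0)

        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(11)
        cases = [("ACGTTACGGTAC", "ACGTACGGT")]  # one 3-nt indel
        for _ in range(15):
            a = random_sequence(rng, int(rng.integers(4, 13)), 0.5)
            b = random_sequence(rng, int(rng.integers(4, 13)), 0.5)
            cases.append((a, b))
        for a, b in cases:
            assert aligner.score(a, b) == brute(a, b)


class TestStemLoops:
    ARM = "GACGTACGCATGCAGT"  # 16 bp, non-palindromic

    def _planted(self, loop="AATAA"):
        return "TTTTT" + self.ARM + loop + reverse_complement(self.ARM) + "TTTTT"

    def test_planted_perfect_16bp(self):
        hits = find_stem_loops(self._planted(), min_stem=16)
        assert len(hits) == 1
        (h,) = hits
        assert (h.stem, h.loop, h.mismatches) == (16, 5, 0)
        assert h.arm5 == (6, 21)
        assert h.arm3 == (27, 42)

    def test_poly_a_has_no_hits(self):
        assert find_stem_loops("A" * 100, min_stem=16) == []

    def test_reverse_complement_mirrors_coordinates(self):
        seq = self._planted()
        fwd = find_stem_loops(seq, min_stem=16, allow_wobble=False)
        rev = find_stem_loops(reverse_complement(seq), min_stem=16, allow_wobble=False)
        n = len(seq)
        mirrored = {
            (n - h.arm3[1] + 1, n - h.arm3[0] + 1, n - h.arm5[1] + 1, n - h.arm5[0] + 1, h.stem, h.loop)
            for h in rev
        }
        assert {
            (h.arm5[0], h.arm5[1], h.arm3[0], h.arm3[1], h.stem, h.loop) for h in fwd
        } == mirrored

    def test_mismatch_budget(self):
        arm = self.ARM
        arm3 = list(reverse_complement(arm))
        arm3[7] = "A" if arm3[7] != "A" else "C"
        broken = "TT" + arm + "AATAA" + "".join(arm3) + "TT"
        assert find_stem_loops(broken, min_stem=16, max_mismatch=0) == []
        hits = find_stem_loops(broken, min_stem=16, max_mismatch=1)
        assert hits and hits[0].mismatches <= 1

    def test_wobble_counted(self):
        arm5 = "GGGGAAAAGGGGAAAA"
        arm3 = reverse_complement(arm5)
        arm3 = arm3.replace("CCCC", "CCCT", 1)  # one G:T wobble
        seq = "AA" + arm5 + "CACAC" + arm3 + "AA"
        hits = find_stem_loops(seq, min_stem=16, allow_wobble=True)
        assert hits and hits[0].wobbles >= 1


class TestTStretch:
    def test_rule_instantiation(self):
        hits = find_t_stretch("A" + "T" * 18 + "G", min_len=18, require_purine_bounds=True)
        assert len(hits) == 1
        assert hits[0].run_length == 18
        assert (hits[0].flank5, hits[0].flank3) == ("A", "G")

    def test_below_threshold(self):
        assert find_t_stretch("T" * 16, min_len=18) == []

    def test_interrupted_stretch(self):
        hits = find_t_stretch("T" * 9 + "C" + "T" * 9, min_len=18, max_interruptions=1)
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.run_length) == (1, 19, 18)
        assert h.interruptions == (10,)

    def test_purine_bound_rejects_pyrimidine_flank(self):
        assert (
            find_t_stretch("C" + "T" * 20 + "G", min_len=18, require_purine_bounds=True)
            == []
        )

    def test_matches_sliding_window_oracle(self, rng):
        """Maximal interrupted T-runs equal an exhaustive interval scan."""
        for _ in range(20):
            seq = "".join(rng.choice(list("TTTAC"), 60))
            for max_int in (0, 1, 2):
                got = {
                    (h.start, h.end)
                    for h in find_t_stretch(seq, min_len=5, max_interruptions=max_int)
                }
                # oracle: all [i, j] windows bounded by T, with <= max_int
                # non-T inside, >= 5 T's, and maximal under inclusion
                wins = set()
                n = len(seq)
                for i in range(n):
                    for j in range(i, n):
                        w = seq[i : j + 1]
                        if w[0] == "T" and w[-1] == "T":
                            non_t = sum(c != "T" for c in w)
                            if non_t <= max_int and len(w) - non_t >= 5:
                                wins.add((i + 1, j + 1))
                maximal = {
                    (a, b)
                    for a, b in wins
                    if not any(
                        (c <= a and b <= d) and (c, d) != (a, b) for c, d in wins
                    )
                }
                assert got == maximal, (seq, max_int)


class TestMotifScan:
    def test_degenerate_motif_match(self):
        hits = scan_motif("TATTTAATACACAAA", "TATTTwATryAyAAA")
        assert len(hits) == 1
        assert hits[0].match == "TATTTAATACACAAA"

    def test_run_quantifier(self):
        hits = scan_motif("GAAAAT", "G(A)nT")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 6)

    def test_invalid_symbol_errors(self):
        with pytest.raises(ValueError):
            scan_motif("ACGT", "AXG")

    def test_both_strands_coordinates(self):
        seq = "CCCCTATACCCC"
        hits = scan_motif(seq, "TATA", both_strands=True)
        plus = [h for h in hits if h.strand == "+"]
        minus = [h for h in hits if h.strand == "-"]
        assert [(h.start, h.end) for h in plus] == [(5, 8)]
        assert [(h.start, h.end) for h in minus] == [(5, 8)]  # TATA is palindromic

    def test_hits_revalidate_and_match_naive_oracle(self, rng):
        """Every hit satisfies the pattern position-by-position, and the hit
        set equals a naive scan, over seeded random sequences."""
        patterns = ["TATA", "TATTTwATryAyAAA", "G(A)nT", "RYN"]
        for k in range(50):
            seq = random_sequence(np.random.default_rng(k), 200)
            for pat in patterns:
                hits = scan_motif(seq, pat)
                for h in hits:
                    assert _naive_match(h.match, pat), (h, pat)
                naive_starts = {
                    i + 1
                    for i in range(len(seq))
                    if _naive_match_at(seq, i, pat)
                }
                assert {h.start for h in hits} == naive_starts, (pat, k)


def _naive_match_at(seq, i, pat):
    """Position-by-position IUPAC check, expanding (X)n by trying all run
    lengths — independent of the scanner's implementation."""
    if "(" in pat:
        head, rest = pat.split("(", 1)
        sym, tail = rest.split(")n", 1)
        for run in range(1, len(seq) - i + 1):
            if _naive_match_at(seq, i, head + sym * run + tail):
                return True
        return False
    if i + len(pat) > len(seq):
        return False
    return all(seq[i + k] in IUPAC[p.upper()] for k, p in enumerate(pat))


def _naive_match(s, pat):
    """True when the pattern matches ``s`` exactly (some expansion of any
    (X)n quantifier has total length len(s))."""
    if "(" in pat:
        head, rest = pat.split("(", 1)
        sym, tail = rest.split(")n", 1)
        run = len(s) - len(head) - len(tail)
        return run >= 1 and _naive_match(s, head + sym * run + tail)
    return len(s) == len(pat) and all(
        s[k] in IUPAC[p.upper()] for k, p in enumerate(pat)
    )


class TestDyadSymmetry:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGGGCATGCCCCC", True),
            ("ACGT", True),
            ("AAAA", False),
            ("ACGCGT", True),
            ("ACA", False),
            ("ACT", True),  # odd length, central base ignored
        ],
    )
    def test_palindromes(self, seq, expected):
        flag, axis = dyad_symmetry(seq)
        assert flag is expected
        assert axis == (len(seq) + 1) / 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dyad_symmetry("")
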