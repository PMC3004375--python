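"""Control-region (A+T-rich region) element detection.

The insect mitochondrial control region is the major noncoding region,
implicated in replication and transcription control. Across Orthoptera it
carries a recurring cast of elements: tandem-repeat arrays next to rrnS
(units of roughly 120-780 bp, with the 3'-terminal copy typically degenerate),
a replication-origin-associated stem-loop of 16 bp or longer flanked by a
"TATA" box and a "G(A)nT" motif, long interrupted T-stretches bounded by
purines, degenerate conserved motifs such as TATTTwATryAyAAA, and
palindromic (dyad-symmetric) segments like GGGGGCATGCCCCC.

All detectors report 1-based inclusive coordinates on the given strand and
return deterministically ordered hit lists (by start, then length, then
label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "RepeatArray",
    "StemLoop",
    "TStretch",
    "MotifHit",
    "find_tandem_repeats",
    "unit_identity",
    "find_stem_loops",
    "find_t_stretch",
    "scan_motif",
    "dyad_symmetry",
    "reverse_complement",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "TU", "U": "TU",
    "R": "AG", "Y": "CTU", "S": "CG", "W": "ATU", "K": "GTU", "M": "AC",
    "B": "CGTU", "D": "AGTU", "H": "ACTU", "V": "ACG", "N": "ACGTU",
}

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _round2(x: float) -> float:
    return math.floor(x * 100 + 0.5) / 100


def _pairs(b1: str, b2: str, allow_wobble: bool) -> bool:
    x, y = b1.upper().replace("U", "T"), b2.upper().replace("U", "T")
    if (x, y) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return True
    return allow_wobble and (x, y) in (("G", "T"), ("T", "G"))


# ---------------------------------------------------------------------------
# Tandem repeats


@dataclass(frozen=True)
class RepeatArray:
    """A tandem array: ``copies`` units of ``unit_length`` bp tiling
    [start, end] (1-based inclusive); the last copy may be partial."""

    start: int
    end: int
    unit_length: int
    copies: int
    consensus: str
    identities: tuple[float, ...]  # per copy, % identity to the first copy
    partial_last: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def unit_identity(u1: str, u2: str) -> float:
    """Percent identity between two repeat units under global alignment.

    Needleman-Wunsch with match +1, mismatch -1, gap -2 (linear); identity is
    matched columns over all alignment columns (gaps included), as a
    percentage rounded half-up to 2 decimals.
    """
    if not u1 or not u2:
        raise ValueError("repeat units must be nonempty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    a, b = u1.upper().replace("U", "T"), u2.upper().replace("U", "T")
    if b < a:
        a, b = b, a  # symmetric by construction: alignment tie-breaks depend on order
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return _round2(100.0 * matches / len(ga))


def find_tandem_repeats(
    sequence: str,
    min_unit: int = 10,
    min_copies: int = 2,
    min_identity: float = 80.0,
    max_unit: int | None = None,
) -> list[RepeatArray]:
    """Detect tandem-repeat arrays by periodic self-match.

    For every candidate period p, positions where the sequence matches
    itself p bp downstream are found; a run of p-wide windows with identity
    >= ``min_identity`` seeds an array covering the run plus one trailing
    period. Copies are then tiled from the array start and edge copies whose
    identity to their neighbour falls below ``min_identity`` are trimmed, so
    copy numbers are not inflated by chance matches in the flanks. A
    trailing partial copy (>= half a unit, identity >= min_identity - 10,
    never below 50) is counted and flagged. Overlapping candidates are
    merged preferring the longer total array, then the smaller unit.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n < 2 * min_unit:
        return []
    max_unit = min(max_unit or n // min_copies, n // 2)
    thr = min_identity / 100.0
    candidates: list[RepeatArray] = []
    for p in range(min_unit, max_unit + 1):
        eq = [seq[i] == seq[i + p] for i in range(n - p)]
        if len(eq) < p:
            continue
        # identity of the p-window starting at i vs the next period
        window = sum(eq[:p])
        w_ok = [window / p >= thr]
        for i in range(1, len(eq) - p + 1):
            window += eq[i + p - 1] - eq[i - 1]
            w_ok.append(window / p >= thr)
        i = 0
        while i < len(w_ok):
            if not w_ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(w_ok) and w_ok[j + 1]:
                j += 1
            arr = _build_array(seq, i, j + 2 * p, p, min_copies, min_identity)
            if arr is not None:
                candidates.append(arr)
            i = j + 1
    return _merge_candidates(candidates)


def _hamming_pct(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def _build_array(
    seq: str, start: int, end: int, p: int, min_copies: int, min_identity: float
) -> RepeatArray | None:
    """Refine a seeded candidate [start, end) of period p into an array.

    The window run that seeds a candidate can start up to a period early (or
    late) when flanking background chance-matches, so the tiling phase is
    re-estimated: anchoring on a middle tile, every phase offset is tried and
    tiles are extended outward while consecutive tiles agree at
    ``min_identity`` (ungapped identity — tiles have equal length, and a
    gapped alignment is too permissive for boundary decisions). The phase
    yielding the most copies wins.
    """
    end = min(end, len(seq))
    n_tiles = (end - start) // p
    if n_tiles < 2:
        return None
    mid = start + (n_tiles // 2) * p
    best: tuple[tuple[int, int], int, int] | None = None
    for delta in range(-p + 1, p):
        s0 = mid + delta
        if s0 < 0 or s0 + p > len(seq):
            continue
        left = s0
        while left - p >= 0 and _hamming_pct(seq[left - p : left], seq[left : left + p]) >= min_identity:
            left -= p
        right = s0 + p
        while right + p <= len(seq) and _hamming_pct(seq[right : right + p], seq[right - p : right]) >= min_identity:
            right += p
        copies = (right - left) // p
        matches = sum(
            seq[i] == seq[i + p] for i in range(left, right - p)
        )
        key = (copies, matches, -abs(delta))
        if best is None or key > best[0]:
            best = (key, left, right)
    (n_copies, _, _), left, right = best
    if n_copies < min_copies:
        return None
    copies = [seq[s : s + p] for s in range(left, right, p)]
    # trailing degenerate/partial copy at a relaxed identity threshold
    partial = False
    relaxed = max(50.0, min_identity - 10.0)
    rest = seq[right : right + p - 1]
    if len(rest) >= p / 2:
        r = len(rest)
        if _hamming_pct(seq[right : right + r], seq[right - p : right - p + r]) >= relaxed:
            copies.append(rest)
            right += r
            partial = True
    idents = tuple(unit_identity(copies[0], c) for c in copies)
    return RepeatArray(
        start=left + 1,
        end=right,
        unit_length=p,
        copies=len(copies),
        consensus=copies[0],
        identities=idents,
        partial_last=partial,
    )


def _merge_candidates(candidates: list[RepeatArray]) -> list[RepeatArray]:
    # Rank overlapping candidates by copy number first: a harmonic of the true
    # period (unit 2p seen as half the copies) can absorb flanking sequence
    # and win on raw span, so the smallest period explaining the array ranks
    # above it; span and unit length break ties.
    ranked = sorted(candidates, key=lambda a: (-a.copies, -a.length, a.unit_length, a.start))
    accepted: list[RepeatArray] = []
    for cand in ranked:
        overlap_frac = 0.0
        for acc in accepted:
            lo, hi = max(cand.start, acc.start), min(cand.end, acc.end)
            if hi >= lo:
                overlap_frac = max(overlap_frac, (hi - lo + 1) / cand.length)
        if overlap_frac < 0.5:
            accepted.append(cand)
    return sorted(accepted, key=lambda a: (a.start, a.length, a.unit_length))


# ---------------------------------------------------------------------------
# Stem-loops


@dataclass(frozen=True)
class StemLoop:
    """An inverted repeat: 5' and 3' arms pairing antiparallel around a loop."""

    arm5: tuple[int, int]  # 1-based inclusive
    arm3: tuple[int, int]
    stem: int
    loop: int
    mismatches: int
    wobbles: int

    @property
    def start(self) -> int:
        return self.arm5[0]

    @property
    def end(self) -> int:
        return self.arm3[1]


def find_stem_loops(
    sequence: str,
    min_stem: int = 16,
    min_loop: int = 3,
    max_loop: int = 30,
    max_mismatch: int = 0,
    allow_wobble: bool = True,
) -> list[StemLoop]:
    """Scan all arm placements for stem-loops (hairpins) of ``min_stem`` bp
    or longer.

    For every loop placement the stem is grown outward from the loop,
    tolerating up to ``max_mismatch`` internal mismatches; terminal couplets
    must pair, so reported stems are maximal. Hits whose span lies inside a
    longer reported hit are suppressed; output is ordered by start, then
    stem length (leftmost-longest).
    """
    seq = sequence.upper()
    n = len(seq)
    hits: dict[tuple[int, int], StemLoop] = {}
    for loop_len in range(min_loop, max_loop + 1):
        for l0 in range(1, n - loop_len):  # 0-based loop start, needs >=1 nt on each side
            best = None
            mism = wob = 0
            k = 0
            last_pair = -1
            pair_states: list[tuple[bool, bool]] = []
            while l0 - 1 - k >= 0 and l0 + loop_len + k < n:
                b5, b3 = seq[l0 - 1 - k], seq[l0 + loop_len + k]
                if _pairs(b5, b3, allow_wobble):
                    pair_states.append((True, _pairs(b5, b3, False) is False))
                    last_pair = k
                else:
                    pair_states.append((False, False))
                    if sum(1 for ok, _ in pair_states if not ok) > max_mismatch:
                        break
                k += 1
            stem = last_pair + 1
            if stem >= min_stem:
                used = pair_states[:stem]
                mism = sum(1 for ok, _ in used if not ok)
                wob = sum(1 for ok, w in used if ok and w)
                sl = StemLoop(
                    arm5=(l0 - stem + 1, l0),
                    arm3=(l0 + loop_len + 1, l0 + loop_len + stem),
                    stem=stem,
                    loop=loop_len,
                    mismatches=mism,
                    wobbles=wob,
                )
                key = (sl.start, sl.end)
                if key not in hits or hits[key].stem < stem:
                    hits[key] = sl
    out = sorted(hits.values(), key=lambda h: (h.start, -(h.end - h.start), h.loop))
    kept: list[StemLoop] = []
    for h in out:
        if not any(k.start <= h.start and h.end <= k.end and k != h for k in out):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end - h.start + 1, h.loop))


# ---------------------------------------------------------------------------
# T-stretches


@dataclass(frozen=True)
class TStretch:
    """A run of thymines, optionally interrupted, with its flanking bases."""

    start: int  # 1-based inclusive, first T
    end: int  # last T
    run_length: int  # number of T positions (interruptions not counted)
    interruptions: tuple[int, ...]  # 1-based positions of non-T bases inside
    flank5: str | None
    flank3: str | None


def find_t_stretch(
    sequence: str,
    min_len: int = 18,
    max_interruptions: int = 0,
    require_purine_bounds: bool = False,
) -> list[TStretch]:
    """Find maximal T-stretches with at most ``max_interruptions`` non-T
    positions inside.

    ``min_len`` counts T positions only (a ">17 bp" stretch is min_len 18).
    With ``require_purine_bounds`` the bases immediately flanking the
    stretch must exist and be purines (A/G). Stretches contained within a
    reported longer stretch are suppressed.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    runs: list[tuple[int, int]] = []  # 0-based [start, end] of pure T runs
    i = 0
    while i < n:
        if seq[i] == "T":
            j = i
            while j + 1 < n and seq[j + 1] == "T":
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    hits: list[TStretch] = []
    for a in range(len(runs)):
        total = 0
        b = a
        while b + 1 < len(runs):
            g = runs[b + 1][0] - runs[b][1] - 1
            if total + g > max_interruptions:
                break
            total += g
            b += 1
        start, end = runs[a][0], runs[b][1]
        t_count = sum(r[1] - r[0] + 1 for r in runs[a : b + 1])
        if t_count < min_len:
            continue
        flank5 = seq[start - 1] if start > 0 else None
        flank3 = seq[end + 1] if end + 1 < n else None
        if require_purine_bounds and not (
            flank5 in ("A", "G") and flank3 in ("A", "G")
        ):
            continue
        interruptions = tuple(
            p + 1 for p in range(start, end + 1) if seq[p] != "T"
        )
        hits.append(
            TStretch(start + 1, end + 1, t_count, interruptions, flank5, flank3)
        )
    kept = [
        h
        for h in hits
        if not any(
            k.start <= h.start and h.end <= k.end and k != h for k in hits
        )
    ]
    return sorted(kept, key=lambda h: (h.start, h.end))


# ---------------------------------------------------------------------------
# Degenerate motifs


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    start: int  # 1-based inclusive on the given strand's coordinates
    end: int
    strand: str  # "+" or "-"
    match: str


def _compile_motif(pattern: str):
    """Tokenise an IUPAC pattern with optional '(X)n' run quantifiers into a
    list of (character-set, min_repeat, max_repeat) items."""
    import re

    tokens: list[tuple[str, int, int | None]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            m = re.match(r"\(([A-Za-z])\)n", pattern[i:])
            if not m:
                raise ValueError(f"malformed quantifier at position {i + 1} in {pattern!r}")
            sym = m.group(1).upper()
            if sym not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {sym!r} in {pattern!r}")
            tokens.append((IUPAC[sym], 1, None))  # one or more
            i += len(m.group(0))
        else:
            sym = ch.upper()
            if sym not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {sym!r} in {pattern!r}")
            tokens.append((IUPAC[sym], 1, 1))
            i += 1
    return tokens


def scan_motif(
    sequence: str, pattern: str, both_strands: bool = False
) -> list[MotifHit]:
    """All (possibly overlapping) matches of a degenerate IUPAC pattern.

    IUPAC codes follow the standard semantics (w={A,T}, r={A,G}, y={C,T},
    n=any...); a parenthesised symbol with an ``n`` quantifier, as in
    "G(A)nT", matches one or more copies of that symbol, longest first. One
    hit is reported per start position per strand; minus-strand coordinates
    are mapped back to the input sequence.
    """
    tokens = _compile_motif(pattern)
    seq = sequence.upper().replace("U", "T")

    def scan(s: str) -> list[tuple[int, int]]:
        out = []
        for start in range(len(s)):
            end = _match_at(s, start, tokens, 0)
            if end is not None:
                out.append((start, end))
        return out

    hits = [
        MotifHit(pattern, a + 1, b, "+", seq[a:b]) for a, b in scan(seq)
    ]
    if both_strands:
        rc = reverse_complement(seq)
        n = len(seq)
        for a, b in scan(rc):
            hits.append(MotifHit(pattern, n - b + 1, n - a, "-", rc[a:b]))
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


def _match_at(s: str, pos: int, tokens, ti: int) -> int | None:
    """Greedy-with-backtracking match; returns the end (exclusive) or None."""
    if ti == len(tokens):
        return pos
    charset, lo, hi = tokens[ti]
    limit = len(s) - pos if hi is None else min(hi, len(s) - pos)
    count = 0
    while count < limit and s[pos + count] in charset:
        count += 1
    for take in range(count, lo - 1, -1):
        end = _match_at(s, pos + take, tokens, ti + 1)
        if end is not None:
            return end
    return None


# ---------------------------------------------------------------------------
# Dyad symmetry


def dyad_symmetry(sequence: str) -> tuple[bool, float]:
    """Whether a sequence is its own reverse complement (a DNA palindrome).

    Odd-length sequences ignore the central base. Returns the flag and the
    symmetry axis as a (possibly half-integer) 1-based position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    axis = (n + 1) / 2
    half = n // 2
    left, right = seq[:half], seq[n - half :]
    return reverse_complement(right) == left, axis
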