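"""Comparative validation of RNA secondary structure.

Helix models for tRNA/rRNA genes are validated against multiple alignments
by the classical comparative criterion: a pair-position at which two or more
distinct Watson-Crick (or wobble G·U) pairings are observed across taxa has
undergone consistent and compensatory substitutions (CCS) and is positive
evidence for the helix, while a position showing a single canonical state in
all taxa is conserved but uninformative about pairing. No phylogeny is
required: the criterion is a statement about the set of pair states observed
across taxa at one position.

The module also computes descriptive alignment statistics used in structure
logos (per-column nucleotide frequencies, information content, and mutual
information between paired columns, all plug-in estimates without
pseudocounts) and checks tRNA sequences against the canonical cloverleaf
schema (7-bp acceptor stem, 5-bp anticodon stem with 7-nt loop, 3-4 bp DHU
stem, 3-6 bp TPsiC stem, "UR" connector, single nucleotide between the DHU
and anticodon stems, conserved U before the anticodon).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PairClass",
    "Verdict",
    "AlignedBlock",
    "HelixModel",
    "PairPosition",
    "CcsReport",
    "TrnaSchema",
    "CloverleafResult",
    "classify_pair",
    "helix_support",
    "conservation_percent",
    "column_frequencies",
    "column_information",
    "pair_mutual_information",
    "validate_cloverleaf",
]

_NUCS = set("ACGU")
_SYMBOLS = _NUCS | {"T", "-", "N", "."}

#: canonical Watson-Crick pairs plus the wobble pair treated as canonical in stems
WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


class PairClass(Enum):
    WATSON_CRICK = "WatsonCrick"
    WOBBLE_GU = "WobbleGU"
    AG_PAIR = "AGpair"
    OTHER_NONCANONICAL = "OtherNoncanonical"
    MISMATCH = "Mismatch"
    GAPPED = "Gapped"


class Verdict(Enum):
    COVARYING = "covarying-supported"
    CONSERVED = "conserved"
    UNSUPPORTED = "unsupported"
    NO_DATA = "no data"


def _norm(symbol: str) -> str:
    s = symbol.upper()
    if s == "T":
        return "U"
    if s == ".":
        return "-"
    return s


def classify_pair(b1: str, b2: str) -> PairClass:
    """Classify a base pair; total on {A,C,G,U,T,-,N} (case-insensitive)."""
    x, y = _norm(b1), _norm(b2)
    for s in (x, y):
        if s not in (_NUCS | {"-", "N"}):
            raise ValueError(f"unknown symbol {s!r} in pair ({b1!r}, {b2!r})")
    if "-" in (x, y):
        return PairClass.GAPPED
    if "N" in (x, y):
        return PairClass.MISMATCH
    if (x, y) in WATSON_CRICK:
        return PairClass.WATSON_CRICK
    if (x, y) in WOBBLE:
        return PairClass.WOBBLE_GU
    if {x, y} == {"A", "G"}:
        return PairClass.AG_PAIR
    return PairClass.OTHER_NONCANONICAL


def is_canonical(b1: str, b2: str) -> bool:
    """True for Watson-Crick and wobble G·U pairs."""
    return classify_pair(b1, b2) in (PairClass.WATSON_CRICK, PairClass.WOBBLE_GU)


# ---------------------------------------------------------------------------
# Alignment container and helix models


@dataclass(frozen=True)
class AlignedBlock:
    """A multiple alignment of RNA sequences (U/T and case normalised)."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        rows = tuple("".join(_norm(c) for c in r) for r in self.rows)
        object.__setattr__(self, "rows", rows)
        if len({len(r) for r in rows}) > 1:
            raise ValueError("alignment rows differ in length")
        bad = set("".join(rows)) - _NUCS - {"-", "N"}
        if bad:
            raise ValueError(f"unknown alignment symbols {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        """Column ``i`` (1-based) as a string, one symbol per row."""
        if not 1 <= i <= self.n_cols:
            raise IndexError(f"column {i} outside alignment of width {self.n_cols}")
        return "".join(r[i - 1] for r in self.rows)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignedBlock":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "fasta")
        return cls(tuple(r.id for r in aln), tuple(str(r.seq) for r in aln))

    @classmethod
    def from_stockholm(cls, path: str | Path) -> tuple["AlignedBlock", "HelixModel | None"]:
        """Read a Stockholm alignment; a ``#=GC SS_cons`` line, if present,
        is returned as a helix model parsed from its bracket notation."""
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "stockholm")
        block = cls(tuple(r.id for r in aln), tuple(str(r.seq) for r in aln))
        ss = aln.column_annotations.get("secondary_structure") if hasattr(aln, "column_annotations") else None
        if ss is None:
            ss_parts = []
            with open(path) as fh:
                for line in fh:
                    if line.startswith("#=GC SS_cons"):
                        ss_parts.append(line.split(None, 2)[2].strip())
            ss = "".join(ss_parts) or None
        helix = HelixModel.from_brackets("SS_cons", ss) if ss else None
        return block, helix


@dataclass(frozen=True)
class HelixModel:
    """Paired alignment columns (1-based, i < j) forming one helix."""

    helix_id: str
    pairs: tuple[tuple[int, int], ...]
    long_distance: bool = False

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for i, j in pairs:
            if not i < j:
                raise ValueError(f"helix {self.helix_id}: pair ({i},{j}) must have i < j")
        cols = [c for p in pairs for c in p]
        if len(cols) != len(set(cols)):
            raise ValueError(f"helix {self.helix_id}: a column is reused across pairs")
        if not self.long_distance:
            # nested check: sorted by i, the j's must be strictly decreasing
            js = [j for _, j in sorted(pairs)]
            if js != sorted(js, reverse=True):
                raise ValueError(
                    f"helix {self.helix_id}: pairs are not nested; "
                    "flag long_distance=True for pseudoknotted/long-range helices"
                )

    @classmethod
    def from_brackets(cls, helix_id: str, structure: str) -> "HelixModel":
        """Parse dot-bracket/WUSS notation ``(<[{`` into column pairs."""
        opens = {"(": ")", "<": ">", "[": "]", "{": "}"}
        closes = {v: k for k, v in opens.items()}
        stacks: dict[str, list[int]] = {k: [] for k in opens}
        pairs = []
        for col, ch in enumerate(structure, start=1):
            if ch in opens:
                stacks[ch].append(col)
            elif ch in closes:
                stack = stacks[closes[ch]]
                if not stack:
                    raise ValueError(f"unbalanced {ch!r} at column {col}")
                pairs.append((stack.pop(), col))
        dangling = [s for s in stacks.values() if s]
        if dangling:
            raise ValueError("unbalanced opening bracket(s) in structure line")
        return cls(helix_id, tuple(sorted(pairs)), long_distance=True)


# ---------------------------------------------------------------------------
# CCS helix support


@dataclass(frozen=True)
class PairPosition:
    """Observed pair states at one helix position across taxa."""

    columns: tuple[int, int]
    states: Counter  # (b1, b2) -> count, gapped rows excluded
    canonical_states: frozenset
    usable_rows: int
    verdict: Verdict


@dataclass(frozen=True)
class CcsReport:
    """Per-position verdicts and a helix-level summary."""

    helix_id: str
    positions: tuple[PairPosition, ...]

    def count(self, verdict: Verdict) -> int:
        return sum(p.verdict is verdict for p in self.positions)

    @property
    def supported(self) -> bool:
        """A helix is comparatively supported if any position covaries."""
        return self.count(Verdict.COVARYING) > 0

    def summary(self) -> dict[str, int]:
        return {v.value: self.count(v) for v in Verdict}


def helix_support(
    block: AlignedBlock,
    helix: HelixModel,
    conserved_fraction: float = 1.0,
) -> CcsReport:
    """Verdict per pair-position of a helix model against an alignment.

    A position is *covarying-supported* when >= 2 distinct canonical
    (Watson-Crick or wobble) pair states occur across taxa — the CCS
    criterion; *conserved* when exactly one canonical state is observed and
    it occurs in at least ``conserved_fraction`` of the non-gapped rows
    (default: all of them); otherwise *unsupported*. Rows gapped at either
    column are excluded; a position with no usable rows is flagged *no data*.
    """
    if block.n_rows < 2:
        raise ValueError("comparative support needs at least two rows")
    positions = []
    for i, j in helix.pairs:
        ci, cj = block.column(i), block.column(j)
        states: Counter = Counter()
        for b1, b2 in zip(ci, cj):
            if classify_pair(b1, b2) is not PairClass.GAPPED:
                states[(b1, b2)] += 1
        canonical = frozenset(s for s in states if is_canonical(*s))
        usable = sum(states.values())
        if usable == 0:
            verdict = Verdict.NO_DATA
        elif len(canonical) >= 2:
            verdict = Verdict.COVARYING
        elif len(canonical) == 1:
            (state,) = canonical
            verdict = (
                Verdict.CONSERVED
                if states[state] >= conserved_fraction * usable
                else Verdict.UNSUPPORTED
            )
        else:
            verdict = Verdict.UNSUPPORTED
        positions.append(PairPosition((i, j), states, canonical, usable, verdict))
    return CcsReport(helix.helix_id, tuple(positions))


def conservation_percent(block: AlignedBlock, exclude_all_gap: bool = True) -> float:
    """Percent of columns where all rows share one non-gap symbol.

    All-gap columns are excluded from the denominator by default. A column
    containing any gap is not conserved.
    """
    if block.n_rows < 2:
        raise ValueError("conservation needs at least two rows")
    usable = conserved = 0
    for i in range(1, block.n_cols + 1):
        col = block.column(i)
        if exclude_all_gap and set(col) == {"-"}:
            continue
        usable += 1
        if "-" not in col and len(set(col)) == 1:
            conserved += 1
    if usable == 0:
        raise ValueError("no usable columns")
    return 100.0 * conserved / usable


# ---------------------------------------------------------------------------
# Structure-logo statistics


def column_frequencies(block: AlignedBlock, i: int) -> dict[str, float]:
    """Nucleotide frequencies in column ``i`` (1-based), gaps/N excluded."""
    col = [b for b in block.column(i) if b in _NUCS]
    if not col:
        raise ValueError(f"column {i}: no nucleotide symbols")
    n = len(col)
    return {b: col.count(b) / n for b in "ACGU" if col.count(b)}


def column_information(block: AlignedBlock, i: int) -> float:
    """Information content 2 - H(column) in bits (plug-in, no correction)."""
    freqs = column_frequencies(block, i)
    h = -sum(f * math.log2(f) for f in freqs.values())
    return 2.0 - h


def pair_mutual_information(block: AlignedBlock, i: int, j: int) -> float:
    """Mutual information between columns ``i`` and ``j`` in bits.

    M = sum_{x,y} f(x,y) log2[f(x,y) / (f(x) f(y))] over rows carrying a
    nucleotide at both columns (plug-in frequencies, no pseudocounts).
    Non-negative, symmetric, and bounded by 2 bits on a 4-letter alphabet.
    """
    pairs = [
        (x, y)
        for x, y in zip(block.column(i), block.column(j))
        if x in _NUCS and y in _NUCS
    ]
    if len(pairs) < 2:
        raise ValueError(f"columns {i},{j}: fewer than two usable rows")
    n = len(pairs)
    joint = Counter(pairs)
    fx = Counter(x for x, _ in pairs)
    fy = Counter(y for _, y in pairs)
    m = 0.0
    for (x, y), c in joint.items():
        fxy = c / n
        m += fxy * math.log2(fxy / ((fx[x] / n) * (fy[y] / n)))
    return max(m, 0.0)


# ---------------------------------------------------------------------------
# tRNA cloverleaf


@dataclass(frozen=True)
class TrnaSchema:
    """Arm-length constraints of the mitochondrial tRNA cloverleaf.

    Defaults encode the canonical schema: a 7-bp acceptor stem, a DHU stem of
    3-4 bp, a 5-bp anticodon stem with a 7-nt loop, a TPsiC stem of 3-6 bp,
    the 2-nt "UR" connector between acceptor and DHU arms, a single
    nucleotide between the DHU and anticodon stems, and a conserved U
    immediately 5' of the anticodon.
    """

    acceptor_stem: int = 7
    dhu_stem_lengths: tuple[int, ...] = (3, 4)
    dhu_loop_range: tuple[int, int] = (3, 12)
    anticodon_stem: int = 5
    anticodon_loop: int = 7
    variable_loop_range: tuple[int, int] = (2, 12)
    tpsic_stem_range: tuple[int, int] = (3, 6)
    tpsic_loop_range: tuple[int, int] = (3, 9)
    trailing_range: tuple[int, int] = (0, 4)
    min_length: int = 55
    max_length: int = 95
    min_acceptor_pairs: int = 5  # noncanonical 5th/6th couplets are tolerated
    max_stem_mismatches: int = 1  # per DHU/AC/TPsiC stem


@dataclass(frozen=True)
class CloverleafResult:
    """Best-scoring arm assignment plus any unsatisfied schema constraints."""

    cloverleaf: bool
    arms: dict[str, tuple[int, int]] = field(default_factory=dict)
    stem_lengths: dict[str, int] = field(default_factory=dict)
    canonical_pairs: int = 0
    stem_mismatches: int = 0
    violations: tuple[str, ...] = ()


def _stem_pairs(seq: str, a: int, b_end: int, length: int) -> int:
    """Canonical+wobble pairs between seq[a:a+length] and the reverse arm
    ending at b_end (exclusive), paired antiparallel."""
    n = 0
    for k in range(length):
        if is_canonical(seq[a + k], seq[b_end - 1 - k]):
            n += 1
    return n


def validate_cloverleaf(sequence: str, schema: TrnaSchema | None = None) -> CloverleafResult:
    """Search arm placements consistent with the cloverleaf schema.

    Enumerates every segmentation of the (ungapped) sequence into
    acceptor/DHU/anticodon/TPsiC arms allowed by the schema, including the
    DHU-less variant seen in metazoan mitochondrial trnS(agn), scores each by
    the number of canonical+wobble pairs in stems, and returns the best with
    a list of violated constraints. Ties prefer more canonical pairs, then a
    longer TPsiC stem, then the leftmost acceptor placement, then smaller
    remaining segment parameters — fully deterministic. If no segmentation
    reaches ``min_acceptor_pairs`` in the acceptor stem, the result has
    ``cloverleaf=False`` (no exception).
    """
    schema = schema or TrnaSchema()
    seq = sequence.upper().replace("T", "U").replace("-", "")
    if not set(seq) <= _NUCS:
        raise ValueError(f"non-nucleotide symbols in tRNA sequence: {sorted(set(seq) - _NUCS)}")
    n = len(seq)
    if not schema.min_length <= n <= schema.max_length:
        raise ValueError(
            f"sequence length {n} outside plausible tRNA range "
            f"[{schema.min_length}, {schema.max_length}]"
        )
    acc, ac, acl = schema.acceptor_stem, schema.anticodon_stem, schema.anticodon_loop
    best_key = None
    best: CloverleafResult | None = None
    for trail in range(schema.trailing_range[0], schema.trailing_range[1] + 1):
        for d in (0, *schema.dhu_stem_lengths):
            for t in range(schema.tpsic_stem_range[0], schema.tpsic_stem_range[1] + 1):
                for tl in range(schema.tpsic_loop_range[0], schema.tpsic_loop_range[1] + 1):
                    for dl in range(schema.dhu_loop_range[0], schema.dhu_loop_range[1] + 1):
                        v = (
                            n - trail - 2 * acc - 2 - 2 * d - dl - 1
                            - 2 * ac - acl - 2 * t - tl
                        )
                        if not schema.variable_loop_range[0] <= v <= schema.variable_loop_range[1]:
                            continue
                        cand = _assemble(seq, schema, d, dl, v, t, tl, trail)
                        if cand is None:
                            continue
                        key = (
                            -cand.canonical_pairs,
                            cand.stem_mismatches,  # a mismatched couplet is not more pairing
                            -cand.stem_lengths["tpsic"],
                            trail,
                            -d,  # prefer the full cloverleaf over the DHU-less variant
                            dl,
                            v,
                            tl,
                        )
                        if best_key is None or key < best_key:
                            best_key, best = key, cand
    if best is None:
        return CloverleafResult(
            cloverleaf=False,
            violations=("no arm placement satisfies the acceptor-stem constraint",),
        )
    return best


def _assemble(
    seq: str, schema: TrnaSchema, d: int, dl: int, v: int, t: int, tl: int, trail: int
) -> CloverleafResult | None:
    acc, ac, acl = schema.acceptor_stem, schema.anticodon_stem, schema.anticodon_loop
    n = len(seq)
    pos = 0
    acc5 = (pos, pos + acc); pos += acc
    conn1 = (pos, pos + 2); pos += 2
    dhu5 = (pos, pos + d); pos += d
    dloop = (pos, pos + dl); pos += dl
    dhu3 = (pos, pos + d); pos += d
    conn2 = (pos, pos + 1); pos += 1
    ac5 = (pos, pos + ac); pos += ac
    aloop = (pos, pos + acl); pos += acl
    ac3 = (pos, pos + ac); pos += ac
    vloop = (pos, pos + v); pos += v
    t5 = (pos, pos + t); pos += t
    tloop = (pos, pos + tl); pos += tl
    t3 = (pos, pos + t); pos += t
    acc3 = (pos, pos + acc); pos += acc
    if pos + trail != n:
        return None

    acc_pairs = _stem_pairs(seq, acc5[0], acc3[1], acc)
    if acc_pairs < schema.min_acceptor_pairs:
        return None
    d_pairs = _stem_pairs(seq, dhu5[0], dhu3[1], d) if d else 0
    ac_pairs = _stem_pairs(seq, ac5[0], ac3[1], ac)
    t_pairs = _stem_pairs(seq, t5[0], t3[1], t)

    violations = []
    if d == 0:
        violations.append("DHU stem absent")
    elif d - d_pairs > schema.max_stem_mismatches:
        violations.append(f"DHU stem has {d - d_pairs} mismatched couplets")
    if ac - ac_pairs > schema.max_stem_mismatches:
        violations.append(f"anticodon stem has {ac - ac_pairs} mismatched couplets")
    if t - t_pairs > schema.max_stem_mismatches:
        violations.append(f"TPsiC stem has {t - t_pairs} mismatched couplets")
    connector = seq[conn1[0] : conn1[1]]
    if not (connector[0] == "U" and connector[1] in "AG"):
        violations.append(f"acceptor-DHU connector {connector!r} is not 'UR'")
    if seq[aloop[0] + 1] != "U":
        violations.append("no conserved U before the anticodon")

    def iv(span: tuple[int, int]) -> tuple[int, int]:
        return (span[0] + 1, span[1])  # 1-based inclusive

    arms = {
        "acceptor_5p": iv(acc5),
        "connector": iv(conn1),
        "dhu_5p": iv(dhu5),
        "dhu_loop": iv(dloop),
        "dhu_3p": iv(dhu3),
        "dhu_ac_link": iv(conn2),
        "anticodon_5p": iv(ac5),
        "anticodon_loop": iv(aloop),
        "anticodon_3p": iv(ac3),
        "variable_loop": iv(vloop),
        "tpsic_5p": iv(t5),
        "tpsic_loop": iv(tloop),
        "tpsic_3p": iv(t3),
        "acceptor_3p": iv(acc3),
    }
    if d == 0:
        for k in ("dhu_5p", "dhu_3p"):
            arms.pop(k)
    return CloverleafResult(
        cloverleaf=True,
        arms=arms,
        stem_lengths={"acceptor": acc, "dhu": d, "anticodon": ac, "tpsic": t},
        canonical_pairs=acc_pairs + d_pairs + ac_pairs + t_pairs,
        stem_mismatches=(acc - acc_pairs)
        + (d - d_pairs if d else 0)
        + (ac - ac_pairs)
        + (t - t_pairs),
        violations=tuple(violations),
    )
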