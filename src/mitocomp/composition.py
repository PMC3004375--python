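"""Nucleotide composition and codon-usage statistics for mitochondrial PCGs.

Codon usage is counted under the invertebrate mitochondrial genetic code
(NCBI translation table 5: AGA/AGG encode serine, UGA tryptophan, AUA
methionine). Relative synonymous codon usage (RSCU) for codon *i* in a
synonymous family of size *k* is

    RSCU_i = n_i * k / sum_j n_j,

i.e. the observed count over the count expected were all synonyms used
equally. Families are pooled by encoded amino acid, so the two leucine
half-families form one 6-codon family (UUR + CUN) and serine one 8-codon
family (UCN + AGN). Amino-acid frequencies are percentages of total codons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "CompositionProfile",
    "InternalStopError",
    "invertebrate_mito_code",
    "at_content",
    "composition_profile",
    "codon_usage",
    "rscu",
    "aa_frequency",
]

_UNAMBIGUOUS = set("ACGU")


class InternalStopError(ValueError):
    """An in-frame stop codon inside a coding sequence."""


def _round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map over RNA codons; stops map to '*'."""

    name: str
    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must cover 64 codons, got {len(self.table)}")

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == "*"

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous codon families keyed by amino acid, stops under '*'."""
        fams: dict[str, list[str]] = {}
        for codon, aa in self.table.items():
            fams.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(codons)) for aa, codons in fams.items()}


def invertebrate_mito_code() -> GeneticCode:
    """NCBI translation table 5 (invertebrate mitochondrial)."""
    bio = CodonTable.unambiguous_rna_by_id[5]
    table = dict(bio.forward_table)
    for codon in bio.stop_codons:
        table[codon] = "*"
    return GeneticCode("invertebrate mitochondrial (transl_table=5)", table)


@dataclass(frozen=True)
class CompositionProfile:
    """Base composition of a region, with optional per-codon-position A+T."""

    region: str
    length: int
    fraction: Mapping[str, float]
    at: float
    at_by_codon_position: tuple[float, float, float] | None = None


@dataclass
class CodonUsageTable:
    """Per-codon counts and RSCU values with pooled synonymous families."""

    counts: dict[str, int]
    code: GeneticCode
    rscu: dict[str, float] = field(default_factory=dict)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def count(self, codon: str) -> int:
        return self.counts.get(_normalize(codon)[:3], 0)

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        """Codon / amino acid / n / RSCU table, RSCU rounded half-up for display."""
        rows = []
        for codon in sorted(self.code.table):
            rows.append(
                {
                    "codon": codon,
                    "aa": self.code.table[codon],
                    "n": self.counts.get(codon, 0),
                    "RSCU": _round_half_up(self.rscu.get(codon, 0.0), ndigits)
                    if self.rscu
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def _normalize(sequence: str) -> str:
    return sequence.upper().replace("T", "U")


def at_content(sequence: str, positions: int | None = None) -> float:
    """Fraction of unambiguous bases that are A or T(U).

    ``positions`` restricts counting to one codon phase (1, 2 or 3) of an
    in-frame sequence. Ambiguous symbols are excluded from numerator and
    denominator alike; gaps ('-') are ignored.
    """
    seq = _normalize(sequence)
    if positions is not None:
        if positions not in (1, 2, 3):
            raise ValueError("codon position filter must be 1, 2 or 3")
        seq = seq[positions - 1 :: 3]
    counted = [b for b in seq if b in _UNAMBIGUOUS]
    if not counted:
        raise ValueError("no unambiguous bases to count")
    return sum(b in "AU" for b in counted) / len(counted)


def composition_profile(
    sequence: str, region: str = "", codon_positions: bool = False
) -> CompositionProfile:
    """Per-base fractions and A+T content, optionally split by codon phase."""
    seq = _normalize(sequence)
    counted = [b for b in seq if b in _UNAMBIGUOUS]
    if not counted:
        raise ValueError("no unambiguous bases to count")
    n = len(counted)
    frac = {b: counted.count(b) / n for b in "ACGU"}
    by_pos = (
        tuple(at_content(sequence, positions=p) for p in (1, 2, 3))
        if codon_positions
        else None
    )
    return CompositionProfile(region, len(seq), frac, frac["A"] + frac["U"], by_pos)


def _trim_cds(name: str, seq: str, code: GeneticCode) -> str:
    """Strip the trailing (possibly partial) stop codon from an in-frame CDS."""
    rem = len(seq) % 3
    if rem == 1 and seq.endswith("U"):
        seq = seq[:-1]
    elif rem == 2 and seq.endswith("UA"):
        seq = seq[:-2]
    elif rem:
        raise ValueError(
            f"{name}: length {len(seq)} not in frame and trailing bases are not a partial stop"
        )
    if len(seq) >= 3 and code.is_stop(seq[-3:]):
        seq = seq[:-3]
    return seq


def codon_usage(
    cds_list: Iterable[tuple[str, str] | str],
    code: GeneticCode | None = None,
) -> CodonUsageTable:
    """Count codons across a set of in-frame coding sequences.

    Accepts plain sequences or (name, sequence) pairs; DNA and RNA alphabets
    are equivalent. Complete and annotated-partial stop codons are trimmed;
    every remaining codon, including the initiation codon whatever it is, is
    counted. An internal stop raises :class:`InternalStopError` naming the
    gene and offset; codons containing ambiguous bases are dropped with a
    warning.
    """
    code = code or invertebrate_mito_code()
    counts: dict[str, int] = {}
    for item in cds_list:
        name, seq = item if isinstance(item, tuple) else ("CDS", item)
        seq = _trim_cds(name, _normalize(seq), code)
        for off in range(0, len(seq), 3):
            codon = seq[off : off + 3]
            if not set(codon) <= _UNAMBIGUOUS:
                warnings.warn(f"{name}: dropping ambiguous codon {codon!r} at {off + 1}")
                continue
            if code.is_stop(codon):
                raise InternalStopError(
                    f"{name}: internal stop codon {codon} at nucleotide offset {off + 1}"
                )
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(counts, code)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill RSCU values; a family with zero total gets RSCU 0.0 throughout."""
    values: dict[str, float] = {}
    for aa, codons in table.code.families().items():
        if aa == "*":
            for codon in codons:
                values[codon] = 0.0
            continue
        total = sum(table.counts.get(c, 0) for c in codons)
        k = len(codons)
        for codon in codons:
            values[codon] = (
                table.counts.get(codon, 0) * k / total if total else 0.0
            )
    table.rscu = values
    return table


def aa_frequency(table: CodonUsageTable, ndigits: int = 2) -> dict[str, float]:
    """Percent of total codons per amino acid, rounded half-up for reporting."""
    total = table.total_codons
    if total == 0:
        raise ValueError("empty codon table")
    out: dict[str, float] = {}
    for aa, codons in table.code.families().items():
        if aa == "*":
            continue
        n = sum(table.counts.get(c, 0) for c in codons)
        out[aa] = _round_half_up(100.0 * n / total, ndigits)
    return out
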