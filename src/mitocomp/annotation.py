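"""Mitogenome feature tables: parsing, validation, and interval arithmetic.

Insect mitogenomes are circular molecules of roughly 15-16 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs, and one large noncoding
control region (the A+T-rich region). Annotations use 1-based inclusive
coordinates throughout, with strands spelled ``Plus``/``Minus`` (the H- and
L-strand of mtDNA). Several PCGs end on a 3'-truncated stop codon ("T-" or
"TA-") completed by polyadenylation of the transcript; coding lengths are
conventionally reported without the stop codon.

This module computes gene lengths, intergenic spacers and overlaps on the
circle, noncoding summaries, and adjacency-based gene-order comparisons
(e.g. the trnK/trnD translocation diagnostic for Caelifera).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneFeature",
    "MitogenomeAnnotation",
    "SpacerRecord",
    "GeneOrderSignature",
    "OrderDifference",
    "AnnotationError",
    "FeatureTableParseError",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "gene_length",
    "spacers",
    "noncoding_summary",
    "overlap_summary",
    "gene_order_signature",
    "compare_gene_order",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "control")
STRANDS = ("Plus", "Minus")

#: bp removed from the raw span of a PCG for each stop annotation.
_STOP_TRIM = {"TAA": 3, "TAG": 3, "T-": 1, "TA-": 2}


class AnnotationError(ValueError):
    """Raised when an annotation violates a structural invariant."""


class FeatureTableParseError(AnnotationError):
    """Raised on a malformed feature-table row; carries the line number."""


@dataclass(frozen=True)
class GeneFeature:
    """A named, stranded, 1-based inclusive interval on the mitogenome.

    ``stop_annotation`` is one of the complete codons "TAA"/"TAG" or the
    partial codons "T-"/"TA-" for PCGs; tRNA/rRNA/control features carry no
    codon annotations.
    """

    name: str
    category: str
    start: int
    end: int
    strand: str
    start_codon: str | None = None
    stop_annotation: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"{self.name}: unknown category {self.category!r} (expected one of {CATEGORIES})"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"{self.name}: unknown strand {self.strand!r} (expected Plus/Minus)"
            )
        if self.start < 1:
            raise AnnotationError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise AnnotationError(
                f"{self.name}: start {self.start} > end {self.end} (features may not span the origin)"
            )
        if self.category != "PCG" and (self.start_codon or self.stop_annotation):
            raise AnnotationError(
                f"{self.name}: codon annotations are only valid on PCG features"
            )
        if self.stop_annotation is not None and self.stop_annotation not in _STOP_TRIM:
            raise AnnotationError(
                f"{self.name}: stop annotation must be one of {sorted(_STOP_TRIM)}, "
                f"got {self.stop_annotation!r}"
            )

    @property
    def span(self) -> int:
        """Raw interval length in bp (stop codon included)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class MitogenomeAnnotation:
    """An ordered, validated set of features on a circular genome."""

    features: tuple[GeneFeature, ...]
    genome_length: int
    circular: bool = True

    def __post_init__(self) -> None:
        feats = tuple(self.features)
        object.__setattr__(self, "features", feats)
        if any(f.end > self.genome_length for f in feats):
            bad = next(f for f in feats if f.end > self.genome_length)
            raise AnnotationError(
                f"{bad.name}: end {bad.end} exceeds genome length {self.genome_length}"
            )
        starts = [f.start for f in feats]
        if starts != sorted(starts):
            raise AnnotationError("features must be sorted ascending by start")
        names = [f.name for f in feats]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(
                f"duplicate feature names {sorted(dupes)}; disambiguate duplicated "
                "tRNAs with anticodon-class suffixes, e.g. trnL(uur)/trnL(cun)"
            )

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @classmethod
    def from_features(
        cls, features: Iterable[GeneFeature], genome_length: int | None = None
    ) -> "MitogenomeAnnotation":
        feats = tuple(sorted(features, key=lambda f: (f.start, f.end)))
        if genome_length is None:
            genome_length = max(f.end for f in feats)
        return cls(feats, genome_length)


@dataclass(frozen=True)
class SpacerRecord:
    """Signed intergenic gap between a feature and its successor on the circle.

    ``gap = downstream.start - upstream.end - 1`` (modulo genome length for
    the wrap pair); negative values are overlaps.
    """

    upstream: str
    downstream: str
    gap: int


@dataclass(frozen=True)
class GeneOrderSignature:
    """Rotation-normalised gene order: (name, strand) tokens from an anchor."""

    tokens: tuple[tuple[str, str], ...]
    anchor: str = "trnI"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.tokens)


@dataclass(frozen=True)
class OrderDifference:
    """Adjacency differences between two gene orders.

    ``broken`` are reference adjacencies absent from the query, ``created``
    the converse. When the two orders differ only by the exchange of two
    blocks of genes, the exchange is named in ``swapped_blocks``.
    """

    broken: tuple[tuple[str, str], ...]
    created: tuple[tuple[str, str], ...]
    swapped_blocks: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = ()

    def __bool__(self) -> bool:
        return bool(self.broken or self.created)


# ---------------------------------------------------------------------------
# I/O


_COLUMNS = ("name", "category", "start", "end", "strand", "start_codon", "stop_annotation")


def read_feature_table(path: str | Path) -> MitogenomeAnnotation:
    """Read a tab-separated feature table into a validated annotation.

    The dialect has a header row with columns name/category/start/end/strand
    and optional start_codon/stop_annotation; ``#``-prefixed lines are
    comments, and a ``# genome_length=N`` pragma fixes the circle length
    (otherwise the maximum feature end is used). Empty cells and ``.`` mean
    "no annotation".
    """
    path = Path(path)
    genome_length: int | None = None
    rows: list[GeneFeature] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                pragma = line.lstrip("#").strip()
                if pragma.startswith("genome_length"):
                    genome_length = int(pragma.split("=", 1)[1])
                continue
            if not line.strip():
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in _COLUMNS[:5] if c not in header]
                if missing:
                    raise FeatureTableParseError(
                        f"{path}:{lineno}: header missing required columns {missing}"
                    )
                continue
            if len(cells) < len([c for c in header if c in _COLUMNS[:5]]):
                raise FeatureTableParseError(
                    f"{path}:{lineno}: expected at least 5 columns, got {len(cells)}"
                )
            rec = dict(zip(header, (c.strip() for c in cells)))
            try:
                rows.append(
                    GeneFeature(
                        name=rec["name"],
                        category=rec["category"],
                        start=int(rec["start"]),
                        end=int(rec["end"]),
                        strand=rec["strand"],
                        start_codon=rec.get("start_codon") or None if rec.get("start_codon") not in ("", ".", None) else None,
                        stop_annotation=rec.get("stop_annotation") or None if rec.get("stop_annotation") not in ("", ".", None) else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, AnnotationError):
                    raise FeatureTableParseError(f"{path}:{lineno}: {exc}") from exc
                raise FeatureTableParseError(
                    f"{path}:{lineno}: malformed row {line!r}: {exc}"
                ) from exc
    if header is None or not rows:
        raise FeatureTableParseError(f"{path}: no feature rows found")
    return MitogenomeAnnotation.from_features(rows, genome_length)


def write_feature_table(annotation: MitogenomeAnnotation, path: str | Path) -> None:
    """Write an annotation in the tab-separated dialect ``read_feature_table`` reads."""
    with open(path, "w") as fh:
        fh.write(f"# genome_length={annotation.genome_length}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for f in annotation:
            fh.write(
                "\t".join(
                    [
                        f.name,
                        f.category,
                        str(f.start),
                        str(f.end),
                        f.strand,
                        f.start_codon or ".",
                        f.stop_annotation or ".",
                    ]
                )
                + "\n"
            )


_GENBANK_TYPES = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "misc_feature": "control",
    "D-loop": "control",
}


def read_genbank(path: str | Path) -> MitogenomeAnnotation:
    """Read CDS/tRNA/rRNA/misc_feature records from a GenBank flat file.

    Coordinates are converted from Biopython's 0-based half-open locations
    back to 1-based inclusive at this boundary. Joined (origin-spanning)
    locations are rejected, matching the single-interval table dialect.
    """
    from Bio import SeqIO

    record = SeqIO.read(str(path), "genbank")
    feats: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for feat in record.features:
        category = _GENBANK_TYPES.get(feat.type)
        if category is None:
            continue
        if len(feat.location.parts) != 1:
            raise AnnotationError(
                f"feature {feat.type} at {feat.location}: origin-spanning/join "
                "locations are not supported"
            )
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        if category == "control":
            name = "A+T-rich region"
        n = seen.get(name, 0)
        seen[name] = n + 1
        if n:
            name = f"{name}.{n + 1}"
        feats.append(
            GeneFeature(
                name=name,
                category=category,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="Plus" if feat.location.strand != -1 else "Minus",
            )
        )
    return MitogenomeAnnotation.from_features(feats, genome_length=len(record.seq))


# ---------------------------------------------------------------------------
# Interval arithmetic


def gene_length(feature: GeneFeature) -> int:
    """Length in bp; for PCGs the (possibly partial) stop codon is excluded.

    Complete stops remove 3 bp, the partial stops "TA-" and "T-" remove 2 and
    1 bp. tRNA/rRNA/control features return the raw span. A PCG whose coding
    length is not a multiple of 3 triggers a warning (annotation slips are
    common in deposited tables) but is not fatal.
    """
    if feature.category != "PCG":
        return feature.span
    length = feature.span - _STOP_TRIM.get(feature.stop_annotation or "", 0)
    if length % 3:
        warnings.warn(
            f"{feature.name}: coding length {length} not divisible by 3",
            stacklevel=2,
        )
    return length


def spacers(annotation: MitogenomeAnnotation) -> list[SpacerRecord]:
    """Signed gaps between adjacent features, including the wrap pair.

    One record per (feature, successor) pair in genomic order; the last
    feature wraps to the first across the origin of the circle.
    """
    feats = annotation.features
    if len(feats) < 2:
        raise AnnotationError("need at least two features to compute spacers")
    out = []
    for up, down in zip(feats, feats[1:]):
        out.append(SpacerRecord(up.name, down.name, down.start - up.end - 1))
    last, first = feats[-1], feats[0]
    wrap = first.start + annotation.genome_length - last.end - 1
    out.append(SpacerRecord(last.name, first.name, wrap))
    return out


def noncoding_summary(annotation: MitogenomeAnnotation) -> tuple[int, int]:
    """(number of positive intergenic gaps, total gap bp), control region excluded.

    The A+T-rich region is the major noncoding region and is reported
    separately, so spacers flanking it do not count here.
    """
    control = {f.name for f in annotation if f.category == "control"}
    recs = [
        s
        for s in spacers(annotation)
        if s.gap > 0 and s.upstream not in control and s.downstream not in control
    ]
    return len(recs), sum(s.gap for s in recs)


def overlap_summary(
    annotation: MitogenomeAnnotation,
) -> tuple[int, int | None, int | None]:
    """(number of overlapping pairs, min overlap bp, max overlap bp).

    Overlaps are spacers with negative gap; the extrema are reported as
    positive magnitudes, or ``None`` when there is no overlap.
    """
    sizes = [-s.gap for s in spacers(annotation) if s.gap < 0]
    if not sizes:
        return 0, None, None
    return len(sizes), min(sizes), max(sizes)


# ---------------------------------------------------------------------------
# Gene order


def gene_order_signature(
    annotation: MitogenomeAnnotation,
    anchor: str = "trnI",
    include_control: bool = False,
) -> GeneOrderSignature:
    """Rotation-normalised (name, strand) token list starting from ``anchor``."""
    feats = [
        f for f in annotation if include_control or f.category != "control"
    ]
    names = [f.name for f in feats]
    if anchor not in names:
        raise AnnotationError(f"anchor {anchor!r} not present in annotation")
    k = names.index(anchor)
    rotated = feats[k:] + feats[:k]
    return GeneOrderSignature(tuple((f.name, f.strand) for f in rotated), anchor)


def _adjacencies(names: Sequence[str]) -> set[tuple[str, str]]:
    return {
        (names[i], names[(i + 1) % len(names)]) for i in range(len(names))
    }


def compare_gene_order(
    sig: GeneOrderSignature, ref: GeneOrderSignature
) -> OrderDifference:
    """Adjacency-set difference between two circular gene orders.

    Reports reference adjacencies broken in the query and novel adjacencies
    created, and names exchanged blocks when the orders differ by a single
    swap of two contiguous blocks (the common tRNA-translocation signature,
    e.g. ancestral trnK/trnD vs the derived trnD/trnK of Caelifera).
    """
    if set(sig.names) != set(ref.names):
        only_sig = sorted(set(sig.names) - set(ref.names))
        only_ref = sorted(set(ref.names) - set(sig.names))
        raise AnnotationError(
            f"token sets differ: only in query {only_sig}, only in reference {only_ref}"
        )
    broken = tuple(sorted(_adjacencies(ref.names) - _adjacencies(sig.names)))
    created = tuple(sorted(_adjacencies(sig.names) - _adjacencies(ref.names)))
    swaps: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    # Name the exchange when the orders differ on one contiguous window whose
    # content is two blocks in swapped order: ref ...A B..., query ...B A...
    a, b = list(ref.names), list(sig.names)
    diff = [i for i in range(len(a)) if a[i] != b[i]]
    if diff:
        lo, hi = diff[0], diff[-1] + 1
        ra, rb = a[lo:hi], b[lo:hi]
        for cut in range(1, len(ra)):
            if rb == ra[cut:] + ra[:cut]:
                swaps.append((tuple(ra[:cut]), tuple(ra[cut:])))
                break
    return OrderDifference(broken, created, tuple(swaps))
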