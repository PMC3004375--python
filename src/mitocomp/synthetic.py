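"""Seeded synthetic fixtures with known ground truth.

Every detector and statistic in the package can be exercised without any
downloaded genome: this module generates annotated circular genomes with a
chosen feature layout (planted gaps and overlaps), alignments with planted
covarying helix columns, in-frame coding sequences of chosen lengths, and
control regions with planted tandem-repeat arrays, stem-loops, degenerate
motifs, and purine-bounded T-stretches. A seed is a required field of every
spec; the same spec and seed reproduce byte-identical output.

Background composition defaults to 75% A+T, the regime of the insect
mitochondrial control region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import GeneFeature, MitogenomeAnnotation
from .composition import GeneticCode, invertebrate_mito_code
from .rna_structure import AlignedBlock, HelixModel, Verdict, is_canonical
from .at_rich import reverse_complement

__all__ = [
    "FeatureSpec",
    "GenomeSpec",
    "AlignmentSpec",
    "RepeatSpec",
    "StemLoopSpec",
    "TStretchSpec",
    "MotifSpec",
    "ControlRegionSpec",
    "SyntheticSpec",
    "PlantedElement",
    "simulate_genome",
    "simulate_ccs_alignment",
    "simulate_control_region",
    "random_cds",
    "random_sequence",
]


# ---------------------------------------------------------------------------
# Spec types


@dataclass(frozen=True)
class FeatureSpec:
    """One feature of a planted genome layout.

    ``gap_before`` is the signed intergenic gap to the previous feature
    (negative = overlap); it is ignored for the first feature, which always
    starts at position 1.
    """

    name: str
    category: str
    length: int
    strand: str = "Plus"
    gap_before: int = 0
    start_codon: str | None = None
    stop_annotation: str | None = None


@dataclass(frozen=True)
class GenomeSpec:
    features: tuple[FeatureSpec, ...]
    terminal_gap: int = 0  # unannotated bp between the last feature and the origin
    at_fraction: float = 0.75


@dataclass(frozen=True)
class AlignmentSpec:
    """Rows over planted helix columns with per-position pair-state menus.

    ``helix_states`` maps a 1-based column pair (i, j) to the menu of pair
    states planted there; rows cycle through the menu so every listed state
    is realised (requires n_rows >= menu size). Unpaired columns are filled
    with a random conserved-or-variable background.
    """

    n_rows: int
    n_cols: int
    helix_states: dict[tuple[int, int], tuple[tuple[str, str], ...]]
    helix_id: str = "planted"


@dataclass(frozen=True)
class RepeatSpec:
    unit_length: int
    copies: int
    divergence: float = 0.0  # per-copy substitution fraction vs the first copy
    position: int | None = None  # 1-based start; auto-placed when None


@dataclass(frozen=True)
class StemLoopSpec:
    stem: int = 16
    loop: int = 5
    position: int | None = None


@dataclass(frozen=True)
class TStretchSpec:
    length: int = 18
    interruptions: int = 0
    position: int | None = None  # position of the 5' purine flank


@dataclass(frozen=True)
class MotifSpec:
    sequence: str = "TATTTAATACACAAA"
    position: int | None = None


@dataclass(frozen=True)
class ControlRegionSpec:
    length: int = 800
    elements: tuple = ()
    at_fraction: float = 0.75


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of planted features plus a required seed."""

    seed: int
    genome: GenomeSpec | None = None
    alignment: AlignmentSpec | None = None
    control_region: ControlRegionSpec | None = None


@dataclass(frozen=True)
class PlantedElement:
    kind: str  # repeat / stem_loop / t_stretch / motif
    start: int  # 1-based inclusive
    end: int
    spec: object


# ---------------------------------------------------------------------------
# Sequence helpers

_BASES = np.array(list("ATGC"))


def random_sequence(rng: np.random.Generator, length: int, at_fraction: float = 0.75) -> str:
    p = np.array([at_fraction / 2, at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def random_cds(
    rng: np.random.Generator,
    coding_length: int,
    code: GeneticCode | None = None,
    start_codon: str = "ATG",
    stop_annotation: str | None = None,
) -> str:
    """A random in-frame CDS of ``coding_length`` bp with no internal stop.

    The coding length excludes the stop codon; if ``stop_annotation`` is
    given the corresponding complete or partial stop is appended, as in an
    annotated gene.
    """
    if coding_length % 3:
        raise ValueError("coding length must be a multiple of 3")
    code = code or invertebrate_mito_code()
    sense = [c.replace("U", "T") for c in sorted(code.table) if code.table[c] != "*"]
    n_codons = coding_length // 3 - 1
    body = "".join(rng.choice(sense) for _ in range(n_codons))
    tail = {"TAA": "TAA", "TAG": "TAG", "T-": "T", "TA-": "TA", None: ""}[stop_annotation]
    return start_codon.replace("U", "T") + body + tail


# ---------------------------------------------------------------------------
# Genome simulation


def simulate_genome(
    spec: SyntheticSpec,
) -> tuple[str, MitogenomeAnnotation, dict]:
    """Generate (sequence, annotation, truth) for a planted feature layout.

    The truth dict records the planted noncoding summary (count and bp of
    positive gaps between non-control features, wrap included) and overlap
    summary, computed from the layout before any sequence is generated.
    """
    if spec.genome is None:
        raise ValueError("spec.genome is required")
    g = spec.genome
    rng = np.random.default_rng(spec.seed)
    feats: list[GeneFeature] = []
    pos = 1
    for k, fs in enumerate(g.features):
        start = pos if k == 0 else pos + fs.gap_before
        if start < 1:
            raise ValueError(f"{fs.name}: layout places start at {start} (< 1)")
        if feats and start <= feats[-1].start:
            raise ValueError(
                f"{fs.name}: over-committed layout, start {start} does not advance"
            )
        end = start + fs.length - 1
        feats.append(
            GeneFeature(fs.name, fs.category, start, end, fs.strand, fs.start_codon, fs.stop_annotation)
        )
        pos = end + 1
    genome_length = feats[-1].end + g.terminal_gap
    annotation = MitogenomeAnnotation.from_features(feats, genome_length)

    # planted summaries from the layout itself
    control = {f.name for f in feats if f.category == "control"}
    gaps = []
    for up, down in zip(feats, feats[1:]):
        gaps.append((up.name, down.name, down.start - up.end - 1))
    gaps.append((feats[-1].name, feats[0].name, g.terminal_gap))
    pos_gaps = [
        gp for u, d, gp in gaps if gp > 0 and u not in control and d not in control
    ]
    overlaps = [-gp for _, _, gp in gaps if gp < 0]
    truth = {
        "noncoding": (len(pos_gaps), sum(pos_gaps)),
        "overlaps": (
            len(overlaps),
            min(overlaps) if overlaps else None,
            max(overlaps) if overlaps else None,
        ),
    }
    sequence = random_sequence(rng, genome_length, g.at_fraction)
    return sequence, annotation, truth


# ---------------------------------------------------------------------------
# CCS alignment simulation


def simulate_ccs_alignment(
    spec: SyntheticSpec,
) -> tuple[AlignedBlock, HelixModel, dict[tuple[int, int], Verdict]]:
    """Alignment with planted pair-state menus and its true helix model.

    Rows cycle deterministically through each position's menu, so the
    planted verdict (covarying when the menu holds >= 2 canonical states,
    conserved for a single canonical state, unsupported otherwise) is
    realised exactly.
    """
    if spec.alignment is None:
        raise ValueError("spec.alignment is required")
    a = spec.alignment
    if a.n_rows < 2:
        raise ValueError("need at least two rows")
    rng = np.random.default_rng(spec.seed)
    paired_cols = set()
    for (i, j), menu in a.helix_states.items():
        for c in (i, j):
            if not 1 <= c <= a.n_cols:
                raise ValueError(f"helix column {c} outside alignment of width {a.n_cols}")
            paired_cols.add(c)
        if len(menu) > a.n_rows:
            raise ValueError(f"menu at ({i},{j}) larger than the number of rows")
    cols: dict[int, list[str]] = {}
    for c in range(1, a.n_cols + 1):
        if c not in paired_cols:
            base = rng.choice(list("ACGU"))
            cols[c] = [str(base)] * a.n_rows
    for (i, j), menu in a.helix_states.items():
        ci, cj = [], []
        for r in range(a.n_rows):
            b1, b2 = menu[r % len(menu)]
            ci.append(b1.upper().replace("T", "U"))
            cj.append(b2.upper().replace("T", "U"))
        cols[i], cols[j] = ci, cj
    rows = tuple(
        "".join(cols[c][r] for c in range(1, a.n_cols + 1)) for r in range(a.n_rows)
    )
    labels = tuple(f"taxon{r + 1}" for r in range(a.n_rows))
    block = AlignedBlock(labels, rows)
    helix = HelixModel(a.helix_id, tuple(sorted(a.helix_states)), long_distance=True)
    truth: dict[tuple[int, int], Verdict] = {}
    for pair, menu in a.helix_states.items():
        canon = {s for s in menu if is_canonical(*s)}
        if len(canon) >= 2:
            truth[pair] = Verdict.COVARYING
        elif len(canon) == 1 and len(set(menu)) == 1:
            truth[pair] = Verdict.CONSERVED
        else:
            truth[pair] = Verdict.UNSUPPORTED
    return block, helix, truth


# ---------------------------------------------------------------------------
# Control-region simulation


def _mutate(rng: np.random.Generator, seq: str, fraction: float) -> str:
    n_mut = int(round(fraction * len(seq)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _render_element(rng: np.random.Generator, el, at_fraction: float) -> str:
    if isinstance(el, RepeatSpec):
        unit = random_sequence(rng, el.unit_length, at_fraction)
        copies = [unit] + [
            _mutate(rng, unit, el.divergence) for _ in range(el.copies - 1)
        ]
        return "".join(copies)
    if isinstance(el, StemLoopSpec):
        arm5 = random_sequence(rng, el.stem, at_fraction)
        loop = list(random_sequence(rng, el.loop, at_fraction))
        if el.loop >= 2:
            # keep the loop ends unpaired so the planted stem length is exact
            from .at_rich import _pairs

            if _pairs(loop[0], loop[-1], True):
                loop[-1] = loop[0]  # identical bases never pair
        return arm5 + "".join(loop) + reverse_complement(arm5)
    if isinstance(el, TStretchSpec):
        body = list("T" * el.length)
        if el.interruptions:
            interior = rng.choice(
                np.arange(1, el.length - 1), size=el.interruptions, replace=False
            )
            for p in sorted(interior, reverse=True):
                body.insert(int(p), "C")
        return "A" + "".join(body) + "G"
    if isinstance(el, MotifSpec):
        return el.sequence.upper().replace("U", "T")
    raise TypeError(f"unknown element spec {type(el).__name__}")


def simulate_control_region(
    spec: SyntheticSpec,
) -> tuple[str, list[PlantedElement]]:
    """Control-region sequence with planted elements and their ground truth.

    Elements without an explicit position are placed left to right with a
    guard band of 5 bp; explicit positions are honoured, and any overlap
    between placements raises before generation. Bases flanking a planted
    stem-loop are forced non-pairing so the planted stem length is maximal.
    """
    if spec.control_region is None:
        raise ValueError("spec.control_region is required")
    cr = spec.control_region
    rng = np.random.default_rng(spec.seed)
    background = list(random_sequence(rng, cr.length, cr.at_fraction))

    rendered = [(el, _render_element(rng, el, cr.at_fraction)) for el in cr.elements]
    placements: list[tuple[int, int, object, str]] = []  # 0-based [start, end)
    cursor = 5
    for el, body in rendered:
        if getattr(el, "position", None) is not None:
            start0 = el.position - 1
        else:
            start0 = cursor
        end0 = start0 + len(body)
        if start0 < 0 or end0 > cr.length:
            raise ValueError(
                f"{type(el).__name__} at {start0 + 1} does not fit in length {cr.length}"
            )
        for s, e, other, _ in placements:
            if start0 < e and s < end0:
                raise ValueError(
                    f"conflicting placements: {type(el).__name__} at {start0 + 1} "
                    f"overlaps {type(other).__name__} at {s + 1}"
                )
        placements.append((start0, end0, el, body))
        cursor = max(cursor, end0) + 5 + rng.integers(0, 10)

    truth: list[PlantedElement] = []
    for start0, end0, el, body in sorted(placements):
        background[start0:end0] = body
        if isinstance(el, StemLoopSpec):
            # prevent chance stem extension beyond the planted arms
            if start0 > 0:
                background[start0 - 1] = "A"
            if end0 < cr.length:
                background[end0] = "A"
        if isinstance(el, TStretchSpec):
            # the purine flanks are part of the rendered body; the T-run itself
            # starts one base in
            truth.append(PlantedElement("t_stretch", start0 + 2, end0 - 1, el))
        else:
            kind = {
                RepeatSpec: "repeat",
                StemLoopSpec: "stem_loop",
                MotifSpec: "motif",
            }[type(el)]
            truth.append(PlantedElement(kind, start0 + 1, end0, el))
    return "".join(background), truth
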