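"""Bundled published tables for the *Acrida cinerea* mitogenome (GU344100).

Two small tab-separated tables ship with the package: the genome
organisation (gene coordinates, strands, start/stop annotations) and the
codon-usage counts of the 13 protein-coding genes. They let the annotation
arithmetic and codon-usage statistics be recomputed and checked against the
published values without any download.
"""

from __future__ import annotations

from importlib.resources import files

from .annotation import MitogenomeAnnotation, read_feature_table
from .composition import CodonUsageTable, invertebrate_mito_code

__all__ = ["load_acrida_annotation", "load_acrida_codon_counts"]


def _data(name: str):
    return files("mitocomp").joinpath("data", name)


def load_acrida_annotation() -> MitogenomeAnnotation:
    """The 37-gene + control-region annotation of the A. cinerea mitogenome."""
    return read_feature_table(str(_data("acrida_cinerea_features.tsv")))


def load_acrida_codon_counts() -> CodonUsageTable:
    """Published per-codon counts (3720 codons, stops excluded) as a
    :class:`~mitocomp.composition.CodonUsageTable` without RSCU filled."""
    counts: dict[str, int] = {}
    with open(str(_data("acrida_cinerea_codon_counts.tsv"))) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.split()
                continue
            codon, _aa, n = line.split()
            if int(n):
                counts[codon] = int(n)
    return CodonUsageTable(counts, invertebrate_mito_code())
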