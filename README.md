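# mitocomp

Comparative analysis of insect mitochondrial genomes, built around the
*Acrida cinerea* (Orthoptera: Acrididae) mitogenome (GenBank GU344100) and
its comparison against other orthopteran mitogenomes. The package is for
researchers doing descriptive comparative mitogenomics: annotation
arithmetic, codon-usage statistics, comparative (covariation-based)
validation of RNA secondary structure, and control-region element
characterisation — without any gene prediction, folding, or tree inference.

## What it computes

**Annotation arithmetic** (`mitocomp.annotation`). Feature tables use
1-based inclusive coordinates on a circular genome, strands `Plus`/`Minus`.
Coding lengths exclude the stop codon: a complete `TAA`/`TAG` removes 3 bp,
the polyadenylation-completed partial stops `TA-` and `T-` remove 2 and
1 bp. Signed intergenic spacers (negative = overlap) are computed for every
adjacent pair including the wrap across the origin; noncoding summaries
exclude the control region, which is reported separately. Gene orders are
compared as circular adjacency sets from a fixed anchor (`trnI`), which
names translocations such as the caeliferan `trnK`/`trnD` → `trnD`/`trnK`
swap directly.

**Codon usage** (`mitocomp.composition`). Counting runs under the
invertebrate mitochondrial code (translation table 5: AGR = Ser, UGA = Trp,
AUA = Met). Relative synonymous codon usage for codon *i* in a synonymous
family *F* of size *k* is

    RSCU_i = k · n_i / Σ_{j∈F} n_j

with families pooled by encoded amino acid, so leucine is one 6-codon
family (UUR + CUN) and serine one 8-codon family (UCN + AGN). Amino-acid
frequencies are percentages of total codons.

**RNA structure validation** (`mitocomp.rna_structure`). A helix model
(paired alignment columns) is supported at a position when two or more
distinct canonical pair states — Watson–Crick or wobble G·U — are observed
across taxa: consistent and compensatory substitutions (CCS). Positions
with a single canonical state in all taxa are *conserved*; everything else
is *unsupported*. No phylogeny is needed. The module also computes
per-column information content and the mutual information between paired
columns (plug-in estimates, in bits), and checks tRNA sequences against the
cloverleaf schema (7-bp acceptor stem, 3–4 bp DHU stem, 5-bp anticodon stem
with 7-nt loop, 3–6 bp TΨC stem, "UR" connector, conserved U before the
anticodon) by exhaustive segmentation search.

**Control-region elements** (`mitocomp.at_rich`). Tandem-repeat arrays
(periodic self-match seeding with phase-refined tile extension, per-copy
percent identity by global alignment), stem-loops of configurable minimum
stem (default 16 bp), long T-stretches (default >17 bp, i.e. ≥18 T's,
optionally purine-bounded), degenerate IUPAC motif scanning with run
quantifiers (`G(A)nT`), and dyad-symmetry (palindrome) testing.

**Synthetic data** (`mitocomp.synthetic`). Seeded generators that plant
each of the above with known ground truth — genome layouts with chosen
gaps/overlaps, alignments with chosen pair-state menus, control regions
with repeat arrays, stem-loops, T-stretches and motifs — for
parameter-recovery testing.

## Worked example

The bundled *A. cinerea* tables reproduce the published descriptive
statistics exactly. Genome organisation:

```
$ mitocomp annotate-summary src/mitocomp/data/acrida_cinerea_features.tsv
...
# noncoding_regions=17 noncoding_bp=80 overlaps=4 overlap_range=7-8 pcg_codons=3720
```

Seventeen intergenic spacers totalling 80 bp, four gene overlaps of 7–8 bp,
and 3720 codons across the 13 protein-coding genes (11160 bp / 3). Codon
usage:

```
$ mitocomp rscu --bundled-counts
codon	aa	n	RSCU
...
UUA	L	356	4.25
UUU	F	296	1.68
...
# total_codons=3720
```

UUA is used 4.25× its uniform-usage expectation within the pooled 6-codon
leucine family — the extreme A+T bias typical of insect mtDNA third
positions. The same library calls are available programmatically:

```python
from mitocomp.datasets import load_acrida_codon_counts
from mitocomp.composition import rscu, aa_frequency

table = rscu(load_acrida_codon_counts())
round(table.rscu["UCU"], 2)   # 2.38 (8-codon serine family)
aa_frequency(table)["L"]      # 13.52 (% leucine)
```

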