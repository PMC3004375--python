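import numpy as np
import pytest

from mitocomp.datasets import load_acrida_annotation, load_acrida_codon_counts


@pytest.fixture(scope="session")
def acrida_annotation():
    return load_acrida_annotation()


@pytest.fixture(scope="session")
def acrida_codons():
    return load_acrida_codon_counts()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_circular_annotation(rng, n_features=12, allow_overlaps=False):
    """A random valid annotation: features with random lengths and random
    non-negative gaps (or small overlaps when allowed)."""
    from mitocomp.annotation import GeneFeature, MitogenomeAnnotation

    feats = []
    pos = 1
    for k in range(n_features):
        if k > 0:
            if allow_overlaps and rng.random() < 0.3:
                gap = -int(rng.integers(1, min(8, feats[-1].span)))
            else:
                gap = int(rng.integers(0, 30))
            pos = feats[-1].end + 1 + gap
        length = int(rng.integers(50, 400))
        feats.append(
            GeneFeature(f"g{k}", "tRNA", pos, pos + length - 1, "Plus")
        )
    genome_length = feats[-1].end + int(rng.integers(0, 50))
    return MitogenomeAnnotation.from_features(feats, genome_length)


def occupancy_noncoding_oracle(annotation):
    """Brute-force: paint every feature interval on a circular array and
    count the unpainted runs and their total length."""
    n = annotation.genome_length
    painted = np.zeros(n, dtype=bool)
    for f in annotation:
        painted[f.start - 1 : f.end] = True
    free = ~painted
    if not free.any():
        return 0, 0
    if free.all():
        return 1, n
    # rotate so position 0 is painted, then count maximal free runs
    first_painted = int(np.argmax(painted))
    rolled = np.roll(free, -first_painted)
    runs = 0
    in_run = False
    for v in rolled:
        if v and not in_run:
            runs += 1
        in_run = bool(v)
    return runs, int(free.sum())
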