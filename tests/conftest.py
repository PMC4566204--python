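import numpy as np
import pytest

from synterna.annotate import GeneFeature, GenomeAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_annotation(species="spA", chrom="chr1", length=100_000, genes=()):
    """Terse helper: genes as (gene_id, start, end, strand[, kind])."""
    feats = [g if isinstance(g, GeneFeature)
             else GeneFeature(g[0], chrom, *g[1:])
             for g in genes]
    return GenomeAnnotation(species, [(chrom, length)], feats)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
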