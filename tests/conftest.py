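import numpy as np
import pytest

from derepress.core import GeneAnnotationSet, GenomicInterval


def make_annotation(starts, chrom="chrX", length=None, gene_len=100, prefix="g"):
    """Annotation with genes at the given start coordinates."""
    starts = sorted(starts)
    length = length or (max(starts) + gene_len + 1 if starts else 1000)
    genes = [
        (f"{prefix}{i + 1}", GenomicInterval(chrom, s, s + gene_len))
        for i, s in enumerate(starts)
    ]
    return GeneAnnotationSet(genes=genes, chrom_lengths={chrom: length})


@pytest.fixture
def tiny_annotation():
    return make_annotation([0, 100, 300, 1000, 5000], length=10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
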