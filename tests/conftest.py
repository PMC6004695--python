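import numpy as np
import pandas as pd
import pytest

from cavescan.popgen_stats import GeneAnnotation, GenotypeDataset


def make_dataset(rows, populations=("surface", "cave")):
    """Build a GenotypeDataset from (chrom, pos, n1, ac1, n2, ac2) tuples."""
    return GenotypeDataset(
        pd.DataFrame(rows, columns=["chrom", "pos", "n1", "ac1", "n2", "ac2"]),
        populations,
    )


def make_annotation(genes, masks=None, indels=None):
    """Build a GeneAnnotation from (chrom, start, end, gene_id) tuples and
    optional (chrom, start, end) interval tuples."""
    kwargs = {"genes": pd.DataFrame(genes, columns=["chrom", "start", "end", "gene_id"])}
    if masks is not None:
        kwargs["masks"] = pd.DataFrame(masks, columns=["chrom", "start", "end"])
    if indels is not None:
        kwargs["indels"] = pd.DataFrame(indels, columns=["chrom", "start", "end"])
    return GeneAnnotation(**kwargs)


@pytest.fixture
def one_gene_annotation():
    """A single gene spanning the whole of chr1 positions 1..1000 (1-based)."""
    return make_annotation([("chr1", 0, 1000, "geneA")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
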