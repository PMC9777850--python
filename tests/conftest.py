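from __future__ import annotations

import numpy as np
import pytest

from yakcnv.annotation import Gene, GeneModel
from yakcnv.rd_caller import CNVCall, DepthProfile
from yakcnv.synthetic import make_genes, make_genome


@pytest.fixture(scope="session")
def genome():
    return make_genome(n_chrom=2, chrom_length=200_000, seed=11)


@pytest.fixture(scope="session")
def gene_model(genome):
    return make_genes(genome, n_genes=8, exons_per_gene=3, seed=12)


@pytest.fixture
def tiny_gene_model():
    """Hand-built two-gene model with known exon layout (0-based half-open)."""
    genes = [
        Gene(gene_id="gA", name="GA", chrom="chr1", start=1_000, end=5_000),
        Gene(gene_id="gB", name="GB", chrom="chr1", start=8_000, end=12_000),
    ]
    exons = {
        "gA": [(1_200, 1_500), (3_000, 3_300), (4_500, 4_800)],
        "gB": [(8_100, 8_400), (11_000, 11_400)],
    }
    return GeneModel(genes=genes, exons=exons)


@pytest.fixture
def flat_profile():
    """A diploid profile: constant depth 40, uniform GC."""
    n = 400
    return DepthProfile(
        sample_id="s1",
        chrom="chr1",
        bin_size=500,
        counts=np.full(n, 40.0),
        gc=np.full(n, 0.45),
    )


def make_call(
    sample="s1", chrom="chr1", start=0, end=1_000, svtype="DEL", ratio=None
):
    if ratio is None:
        ratio = 0.4 if svtype == "DEL" else 1.8
    return CNVCall(
        sample_id=sample, chrom=chrom, start=start, end=end,
        svtype=svtype, rd_ratio=ratio,
    )


@pytest.fixture
def call_factory():
    return make_call
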