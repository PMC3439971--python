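"""Shared fixtures: gene/read factories and a small simulated dataset."""

from __future__ import annotations

import pytest

from natsirna.genome_io import GeneModel, MappedRead
from natsirna.nat_discovery import make_pair


def gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str = "+",
    chrom: str = "chr1",
    exons=None,
    biotype: str = "protein_coding",
) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        span=(start, end),
        exons=exons or [(start, end)],
        biotype=biotype,
    )


def read(
    start: int,
    length: int = 21,
    strand: str = "+",
    seq: str | None = None,
    copies: int = 1,
    lib: str = "L1",
    chrom: str = "chr1",
) -> MappedRead:
    return MappedRead(
        sequence=seq or ("A" * length),
        chrom=chrom,
        start=start,
        strand=strand,
        copies=copies,
        library_id=lib,
        length=length,
    )


@pytest.fixture
def convergent_pair():
    """+ gene [0,1000) / - gene [900,1800): overlap [900,1000)."""
    pair = make_pair(gene("GA", 0, 1000, "+"), gene("GB", 900, 1800, "-"))
    assert pair is not None
    return pair


@pytest.fixture
def intron_pair():
    """Convergent pair whose + gene has an intron [400,600) inside the overlap
    [300,1000)."""
    ga = gene("GA", 0, 1000, "+", exons=[(0, 400), (600, 1000)])
    gb = gene("GB", 300, 1800, "-")
    pair = make_pair(ga, gb)
    assert pair is not None
    return pair
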